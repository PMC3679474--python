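"""Inferential layer for the 2x2 factorial study design.

Diet (CD vs VDD) and smoke exposure (NS vs CSE) are crossed between-
subjects factors.  Continuous endpoints go through a two-way ANOVA
(textbook partition when balanced; Type III sums of squares with
sum-to-zero contrasts when unbalanced) followed by pre-planned pairwise
comparisons with Bonferroni-adjusted Welch t tests.  Binary/ordinal
pathology endpoints use the tie-corrected Kruskal-Wallis test.  All
descriptive output is mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Pre-planned contrasts: each treated group vs the control group, plus the
#: combined-insult group vs each single-insult group.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("CD-CSE", "CD-NS"),
    ("VDD-NS", "CD-NS"),
    ("VDD-CSE", "CD-NS"),
    ("VDD-CSE", "CD-CSE"),
    ("VDD-CSE", "VDD-NS"),
)


class StatsError(Exception):
    pass


class EmptyCellError(StatsError):
    """A factorial cell has too few observations for the ANOVA."""


@dataclass(frozen=True)
class EffectResult:
    ss: float
    df: float
    F: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    diet: EffectResult
    smoke: EffectResult
    interaction: EffectResult
    residual_ss: float
    residual_df: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("diet", "smoke", "interaction"):
            e: EffectResult = getattr(self, name)
            rows.append({"effect": name, "ss": e.ss, "df": e.df, "F": e.F, "p": e.p})
        rows.append({"effect": "residual", "ss": self.residual_ss,
                     "df": self.residual_df, "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


def _check_cells(df: pd.DataFrame) -> None:
    for diet in ("CD", "VDD"):
        for smoke in ("NS", "CSE"):
            n = int(((df["diet"] == diet) & (df["smoke"] == smoke)).sum())
            if n < 2:
                raise EmptyCellError(
                    f"cell (diet={diet}, smoke={smoke}) has {n} observations; need >= 2"
                )


def two_way_anova(sample: pd.DataFrame, value_col: str = "value") -> AnovaResult:
    """Between-subjects 2x2 ANOVA on ``value`` with factors diet and smoke.

    Sum-to-zero contrasts with Type III sums of squares, which coincides
    with the textbook balanced partition SS_total = SS_diet + SS_smoke +
    SS_interaction + SS_error when cell sizes are equal.  If every
    observation is identical all SS are zero and the convention F = 0,
    p = 1 is reported; if the residual is exactly zero but an effect is
    not, F is infinite and p = 0.
    """
    df = sample.rename(columns={value_col: "value"}).copy()
    for col in ("value", "diet", "smoke"):
        if col not in df.columns:
            raise ValueError(f"sample must have a '{col}' column")
    _check_cells(df)

    values = df["value"].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        zero = EffectResult(ss=0.0, df=1.0, F=0.0, p=1.0)
        n = len(values)
        return AnovaResult(diet=zero, smoke=zero, interaction=zero,
                           residual_ss=0.0, residual_df=float(n - 4))

    model = smf.ols("value ~ C(diet, Sum) * C(smoke, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = float(table.loc["Residual", "df"])

    def effect(row_name: str) -> EffectResult:
        ss = float(table.loc[row_name, "sum_sq"])
        dfe = float(table.loc[row_name, "df"])
        if resid_ss <= 1e-12 * max(ss, 1.0):
            if ss <= 0.0:
                return EffectResult(ss=max(ss, 0.0), df=dfe, F=0.0, p=1.0)
            return EffectResult(ss=ss, df=dfe, F=np.inf, p=0.0)
        F = (ss / dfe) / (resid_ss / resid_df)
        p = float(sps.f.sf(F, dfe, resid_df))
        return EffectResult(ss=ss, df=dfe, F=float(F), p=p)

    return AnovaResult(
        diet=effect("C(diet, Sum)"),
        smoke=effect("C(smoke, Sum)"),
        interaction=effect("C(diet, Sum):C(smoke, Sum)"),
        residual_ss=resid_ss,
        residual_df=resid_df,
    )


def planned_comparisons(
    sample: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
    family_size: int | None = None,
    value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Welch two-sample t for each planned pair, Bonferroni-adjusted.

    The adjusted p is min(1, m * p_raw) with family size m defaulting to
    the number of pairs.  Each named group must contain >= 2 animals.
    """
    m = family_size if family_size is not None else len(pairs)
    if m < 1:
        raise ValueError("family size must be >= 1")
    rows = []
    for a, b in pairs:
        xa = sample.loc[sample[group_col] == a, value_col].to_numpy(dtype=float)
        xb = sample.loc[sample[group_col] == b, value_col].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise StatsError(f"group {a if len(xa) < 2 else b!r} has < 2 animals")
        if np.ptp(np.concatenate([xa, xb])) == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({
            "group_a": a, "group_b": b,
            "mean_a": xa.mean(), "mean_b": xb.mean(),
            "t": float(t), "p_raw": float(p),
            "p_bonferroni": float(min(1.0, m * p)),
        })
    return pd.DataFrame(rows)


def kruskal_wallis(
    scores: pd.DataFrame,
    feature: str | None = None,
    value_col: str = "presence",
    group_col: str = "group",
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across groups; returns (H, p).

    Intended for the binarised presence/absence pathology scale (``
    value_col='presence'``; pass ``value_col='score'`` for the raw 0-3
    ordinal scale).  All-identical values yield H = 0, p = 1 by
    convention.  p comes from the chi-square with k-1 df.
    """
    df = scores
    if feature is not None:
        df = df[df["feature"] == feature]
    groups = [g.to_numpy(dtype=float) for _, g in df.groupby(group_col)[value_col]]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise StatsError("need >= 2 groups with >= 1 observation each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def binarize_scores(scores: pd.DataFrame, score_col: str = "score") -> pd.DataFrame:
    """Add/refresh the presence column: 1 iff the ordinal score exceeds 0."""
    out = scores.copy()
    out["presence"] = (out[score_col] > 0).astype(int)
    return out


def group_summary(
    sample: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> pd.DataFrame:
    """Mean, SEM (sample SD / sqrt(n)) and n per group.

    A single-observation group reports SEM as NaN (undefined, not zero).
    """
    if sample.empty:
        raise ValueError("empty sample")
    grp = sample.groupby(group_col)[value_col]
    out = pd.DataFrame({
        "mean": grp.mean(),
        "sem": grp.apply(lambda v: float(v.std(ddof=1) / np.sqrt(len(v)))
                         if len(v) > 1 else np.nan),
        "n": grp.count(),
    }).reset_index()
    if (out["n"] < 1).any():
        raise ValueError("empty group")
    return out
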