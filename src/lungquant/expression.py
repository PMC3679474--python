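"""Housekeeping-normalised qPCR expression and the MMP-9:TIMP-1 ratio.

Relative expression uses the delta-Ct method against the RPL13a
housekeeping gene: rel = E**-(Ct_gene - Ct_RPL13a), with amplification
efficiency E = 2 (perfect doubling) by default and an optional per-gene
efficiency.  The protease/antiprotease balance is summarised per animal
as rel(MMP9)/rel(TIMP1); algebraically the housekeeping gene cancels, so
the ratio equals E**-(Ct_MMP9 - Ct_TIMP1).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOUSEKEEPING_GENE = "RPL13a"


def _validate_table(table: pd.DataFrame) -> None:
    required = {"animal_id", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    dup = table.duplicated(subset=["animal_id", "gene"])
    if dup.any():
        raise ValueError("expression table has duplicate animal x gene entries")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("all Ct values must be finite and positive")


def relative_expression(
    table: pd.DataFrame,
    housekeeping: str = HOUSEKEEPING_GENE,
    efficiency: float | Mapping[str, float] = 2.0,
) -> pd.DataFrame:
    """Per-animal, per-gene relative expression rel = E**-(Ct - Ct_hk).

    ``table`` is long-format with columns animal_id, gene, ct (a group
    column, if present, is carried through).  Animals missing the
    housekeeping gene are excluded with a logged warning.  The
    housekeeping gene itself always maps to rel = 1.
    """
    _validate_table(table)
    hk = table[table["gene"] == housekeeping].set_index("animal_id")["ct"]
    missing = set(table["animal_id"]) - set(hk.index)
    if missing:
        logger.warning("excluding animals without %s Ct: %s",
                       housekeeping, sorted(missing))
    out = table[table["animal_id"].isin(hk.index)].copy()
    delta = out["ct"].to_numpy() - hk.loc[out["animal_id"]].to_numpy()
    if isinstance(efficiency, Mapping):
        eff = out["gene"].map(lambda g: efficiency.get(g, 2.0)).to_numpy()
    else:
        eff = float(efficiency)
    out["rel"] = np.power(eff, -delta)
    return out


def mmp9_timp1_ratio(
    rel: pd.DataFrame,
    protease: str = "MMP9",
    inhibitor: str = "TIMP1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal protease:inhibitor expression ratio and group summaries.

    Returns ``(per_animal, per_group)``.  Animals with a missing or zero
    inhibitor value are excluded with a warning.  Group summaries give the
    arithmetic mean +/- SEM of the ratio (matching the conventional
    "ratio +/- SEM" display) alongside a log2-scale summary, since ratios
    are log-normal.
    """
    cols = ["animal_id"] + (["group"] if "group" in rel.columns else [])
    wide = rel.pivot_table(index=cols, columns="gene", values="rel").reset_index()
    for gene in (protease, inhibitor):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from relative-expression table")
    bad = wide[inhibitor].isna() | (wide[inhibitor] == 0) | wide[protease].isna()
    if bad.any():
        logger.warning("excluding %d animals with missing/zero %s",
                       int(bad.sum()), inhibitor)
        wide = wide[~bad]
    wide = wide.copy()
    wide["ratio"] = wide[protease] / wide[inhibitor]
    per_animal = wide[cols + ["ratio"]]

    if "group" in per_animal.columns:
        grp = per_animal.groupby("group")["ratio"]
        per_group = pd.DataFrame({
            "mean": grp.mean(),
            "sem": grp.sem(ddof=1),
            "n": grp.count(),
            "log2_mean": per_animal.groupby("group")["ratio"].apply(
                lambda r: float(np.log2(r).mean())),
            "log2_sem": per_animal.groupby("group")["ratio"].apply(
                lambda r: float(np.log2(r).std(ddof=1) / np.sqrt(len(r)))
                if len(r) > 1 else np.nan),
        }).reset_index()
    else:
        per_group = pd.DataFrame()
    return per_animal, per_group
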