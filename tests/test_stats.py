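"""Factorial ANOVA, planned comparisons, Kruskal-Wallis, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lungquant.stats import (
    DEFAULT_COMPARISONS,
    EmptyCellError,
    StatsError,
    binarize_scores,
    group_summary,
    kruskal_wallis,
    planned_comparisons,
    two_way_anova,
)
from conftest import kruskal_oracle


def balanced_partition_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Textbook SS partition for a balanced 2x2 design (cell-mean formulas)."""
    cells = df.groupby(["diet", "smoke"])["value"]
    n = cells.count().iloc[0]
    assert (cells.count() == n).all()
    grand = df["value"].mean()
    diet_means = df.groupby("diet")["value"].mean()
    smoke_means = df.groupby("smoke")["value"].mean()
    cell_means = cells.mean()
    ss_diet = 2 * n * ((diet_means - grand) ** 2).sum()
    ss_smoke = 2 * n * ((smoke_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_diet - ss_smoke
    ss_total = ((df["value"] - grand) ** 2).sum()
    return {"diet": ss_diet, "smoke": ss_smoke, "interaction": ss_inter,
            "residual": ss_total - ss_cells, "total": ss_total}


class TestTwoWayAnova:
    def test_all_equal_uses_zero_variance_convention(self, factorial_frame):
        df = factorial_frame({(d, s): 5.0 for d in ("CD", "VDD")
                              for s in ("NS", "CSE")}, n=4, noise_sd=0.0, seed=0)
        res = two_way_anova(df)
        for eff in (res.diet, res.smoke, res.interaction):
            assert eff.ss == 0.0 and eff.F == 0.0 and eff.p == 1.0

    def test_pure_interaction_closed_form(self, factorial_frame):
        """Cell means (0,0,0,delta), no noise: interaction SS = n*delta^2/4."""
        n, delta = 5, 2.0
        df = factorial_frame({("CD", "NS"): 0, ("CD", "CSE"): 0,
                              ("VDD", "NS"): 0, ("VDD", "CSE"): delta},
                             n=n, noise_sd=0.0, seed=0)
        res = two_way_anova(df)
        assert res.interaction.ss == pytest.approx(n * delta**2 / 4)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-12)
        assert res.interaction.p == 0.0  # zero residual, nonzero effect

    def test_balanced_partition_matches_textbook_oracle(self, factorial_frame):
        df = factorial_frame({("CD", "NS"): 10, ("CD", "CSE"): 12,
                              ("VDD", "NS"): 11, ("VDD", "CSE"): 16},
                             n=8, noise_sd=2.0, seed=42)
        res = two_way_anova(df)
        oracle = balanced_partition_oracle(df)
        assert res.diet.ss == pytest.approx(oracle["diet"], rel=1e-9)
        assert res.smoke.ss == pytest.approx(oracle["smoke"], rel=1e-9)
        assert res.interaction.ss == pytest.approx(oracle["interaction"], rel=1e-9)
        assert res.residual_ss == pytest.approx(oracle["residual"], rel=1e-9)
        # partition sums to SS_total
        total = (res.diet.ss + res.smoke.ss + res.interaction.ss + res.residual_ss)
        assert total == pytest.approx(oracle["total"], rel=1e-9)

    def test_unbalanced_type3_matches_model_comparison_oracle(self):
        """Type III SS via explicit full-vs-reduced regression on sum-coded
        design matrices, independent of the statsmodels formula path."""
        rng = np.random.default_rng(7)
        rows = []
        sizes = {("CD", "NS"): 5, ("CD", "CSE"): 9, ("VDD", "NS"): 7, ("VDD", "CSE"): 4}
        for (d, s), n in sizes.items():
            for _ in range(n):
                rows.append({"diet": d, "smoke": s,
                             "value": rng.normal(2.0 if d == "VDD" else 0.0, 1.0)})
        df = pd.DataFrame(rows)

        a = np.where(df["diet"] == "CD", 1.0, -1.0)
        b = np.where(df["smoke"] == "NS", 1.0, -1.0)  # wait: level order
        # statsmodels Sum coding drops the last sorted level; direction does
        # not matter for SS, only the +-1 coding does.
        X_full = np.column_stack([np.ones(len(df)), a, b, a * b])
        y = df["value"].to_numpy()

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum())

        res = two_way_anova(df)
        full = rss(X_full)
        assert res.diet.ss == pytest.approx(rss(X_full[:, [0, 2, 3]]) - full, rel=1e-8)
        assert res.smoke.ss == pytest.approx(rss(X_full[:, [0, 1, 3]]) - full, rel=1e-8)
        assert res.interaction.ss == pytest.approx(
            rss(X_full[:, [0, 1, 2]]) - full, rel=1e-8)

    def test_main_effect_F_equals_squared_marginal_t(self):
        """Balanced with sample smoke/interaction SS exactly zero: the diet F
        equals the pooled marginal t^2 up to the residual-df ratio."""
        rng = np.random.default_rng(11)
        rows = []
        for diet, mu in (("CD", 10.0), ("VDD", 13.0)):
            cell = rng.normal(mu, 1.5, size=10)
            for smoke in ("NS", "CSE"):  # mirrored cells kill smoke/interaction SS
                rows += [{"diet": diet, "smoke": smoke, "value": v} for v in cell]
        df = pd.DataFrame(rows)
        res = two_way_anova(df)
        assert res.smoke.ss == pytest.approx(0.0, abs=1e-9)
        assert res.interaction.ss == pytest.approx(0.0, abs=1e-9)
        xa = df[df["diet"] == "CD"]["value"]
        xb = df[df["diet"] == "VDD"]["value"]
        t, _ = sps.ttest_ind(xa, xb, equal_var=True)
        n_total = len(df)
        assert res.diet.F == pytest.approx(
            t**2 * (n_total - 4) / (n_total - 2), rel=1e-9)

    def test_empty_cell_is_named(self, factorial_frame):
        df = factorial_frame({("CD", "NS"): 1, ("CD", "CSE"): 1, ("VDD", "NS"): 1},
                             n=3, noise_sd=1.0, seed=0)
        with pytest.raises(EmptyCellError, match="VDD.*CSE"):
            two_way_anova(df)

    def test_null_rejection_rate_calibrated(self, factorial_frame):
        """Type-I error of each effect ~ alpha under the normal null."""
        rng = np.random.default_rng(2025)
        reps = 400
        rejections = np.zeros(3)
        base = factorial_frame({(d, s): 0.0 for d in ("CD", "VDD")
                                for s in ("NS", "CSE")}, n=6, noise_sd=0.0, seed=0)
        for _ in range(reps):
            df = base.copy()
            df["value"] = rng.normal(size=len(df))
            res = two_way_anova(df)
            rejections += [res.diet.p < 0.05, res.smoke.p < 0.05,
                           res.interaction.p < 0.05]
        rates = rejections / reps
        assert np.all(rates > 0.02) and np.all(rates < 0.08)


class TestPlannedComparisons:
    def make(self, shift=0.0, seed=0, n=11):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("CD-NS", "CD-CSE", "VDD-NS", "VDD-CSE"):
            mu = shift if g == "VDD-CSE" else 0.0
            for _ in range(n):
                rows.append({"group": g, "value": rng.normal(mu, 1.0)})
        return pd.DataFrame(rows)

    def test_bonferroni_definition_and_cap(self):
        df = self.make(shift=3.0, seed=1)
        out = planned_comparisons(df, family_size=3)
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, 3 * out["p_raw"]))
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_identical_groups_are_not_significant(self):
        df = pd.DataFrame({"group": ["CD-NS"] * 5 + ["CD-CSE"] * 5,
                           "value": [2.0] * 10})
        out = planned_comparisons(df, pairs=(("CD-CSE", "CD-NS"),))
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)
        assert out["p_bonferroni"].iloc[0] == 1.0

    def test_default_pair_set_contrasts_each_treatment_and_combined(self):
        df = self.make(seed=2)
        out = planned_comparisons(df)
        assert len(out) == len(DEFAULT_COMPARISONS) == 5
        assert ("VDD-CSE", "CD-NS") in set(zip(out["group_a"], out["group_b"]))

    def test_small_group_rejected(self):
        df = pd.DataFrame({"group": ["CD-NS", "CD-CSE", "CD-CSE"],
                           "value": [1.0, 2.0, 3.0]})
        with pytest.raises(StatsError):
            planned_comparisons(df, pairs=(("CD-CSE", "CD-NS"),))

    def test_power_matches_noncentral_t_theory(self):
        """One-pooled-sd shift at n=11/group vs analytic Welch power."""
        n, delta, reps = 11, 1.0, 2000
        rng = np.random.default_rng(99)
        a = rng.normal(0.0, 1.0, size=(reps, n))
        b = rng.normal(delta, 1.0, size=(reps, n))
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        power_mc = float((p < 0.05).mean())
        df_w = 2 * n - 2  # equal variances: Welch df reduces to pooled df
        nc = delta / np.sqrt(2.0 / n)
        tcrit = sps.t.ppf(0.975, df_w)
        power_theory = (1 - sps.nct.cdf(tcrit, df_w, nc)
                        + sps.nct.cdf(-tcrit, df_w, nc))
        se = np.sqrt(power_theory * (1 - power_theory) / reps)
        assert abs(power_mc - power_theory) < 3 * se + 0.01


class TestKruskalWallis:
    def test_perfect_separation_matches_rank_oracle(self):
        df = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3, "feature": ["f"] * 6,
                           "presence": [0, 0, 0, 1, 1, 1]})
        H, p = kruskal_wallis(df, "f")
        oracle = kruskal_oracle([np.zeros(3), np.ones(3)])
        assert H == pytest.approx(oracle)

    def test_all_identical_convention(self):
        df = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3, "feature": ["f"] * 6,
                           "presence": [0] * 6})
        assert kruskal_wallis(df, "f") == (0.0, 1.0)

    def test_matches_oracle_on_fuzzed_binary_tables(self):
        rng = np.random.default_rng(55)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 2, size=rng.integers(3, 12)).astype(float)
                      for _ in range(k)]
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                continue
            df = pd.DataFrame({
                "group": np.repeat([f"g{i}" for i in range(k)],
                                   [len(g) for g in groups]),
                "presence": pooled,
            })
            H, _ = kruskal_wallis(df)
            assert H == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_binarize_presence_iff_positive_score(self):
        df = pd.DataFrame({"score": [0, 1, 2, 3]})
        out = binarize_scores(df)
        assert list(out["presence"]) == [0, 1, 1, 1]

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["A"] * 3, "presence": [0, 1, 0]})
        with pytest.raises(StatsError):
            kruskal_wallis(df)


class TestGroupSummary:
    def test_closed_form(self):
        df = pd.DataFrame({"group": ["g"] * 3, "value": [1.0, 2.0, 3.0]})
        out = group_summary(df)
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "sem"] == pytest.approx(1 / np.sqrt(3))

    def test_constant_group_zero_sem_and_singleton_nan(self):
        df = pd.DataFrame({"group": ["a"] * 4 + ["b"],
                           "value": [7.0] * 4 + [1.0]})
        out = group_summary(df).set_index("group")
        assert out.loc["a", "sem"] == 0.0
        assert np.isnan(out.loc["b", "sem"])

    def test_matches_streaming_oracle_on_fuzz(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.normal(size=rng.integers(2, 30))
            df = pd.DataFrame({"group": ["g"] * len(vals), "value": vals})
            out = group_summary(df)
            # Welford streaming oracle
            mean, m2 = 0.0, 0.0
            for i, x in enumerate(vals, 1):
                d = x - mean
                mean += d / i
                m2 += d * (x - mean)
            sem = np.sqrt(m2 / (len(vals) - 1)) / np.sqrt(len(vals))
            assert out.loc[0, "mean"] == pytest.approx(mean)
            assert out.loc[0, "sem"] == pytest.approx(sem)
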