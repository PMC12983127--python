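"""ROI statistics: robust means, residualization, mixed model, exact tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from math import comb
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.formula.api import ols

from mqmri.stats import (
    GenotypeROIModel,
    fisher_exact_2x2,
    fit_lmem_genotype_roi,
    hedges_g_bootstrap,
    mann_whitney_exact,
    partial_correlation,
    posthoc_genotype_by_roi,
    residualize_on_volume,
    roi_robust_mean,
)

ROIS = ["hippocampus", "corpus_callosum", "thalamus", "striatum"]


def _cohort_table(rng, shift=0.0, sigma_a=0.7, sigma_e=1.0, n=6):
    rows = []
    for g in ["WT", "ARTE10"]:
        for i in range(n):
            a = f"{g}{i}"
            ae = rng.normal(0, sigma_a)
            for r in ROIS:
                val = ae + rng.normal(0, sigma_e)
                if g == "ARTE10" and r == "hippocampus":
                    val += shift
                rows.append(dict(animal=a, genotype=g, roi=r, value=val,
                                 roi_volume=rng.uniform(90, 110)))
    return pd.DataFrame(rows)


class TestRobustMean:
    def test_constant_map(self):
        vals = np.full((5, 5, 5), 4.2)
        mask = np.ones((5, 5, 5), bool)
        mean, n = roi_robust_mean(vals, mask)
        assert mean == pytest.approx(4.2) and n == 125

    def test_two_sided_trim_arithmetic(self):
        # 1..99 plus outlier 1000: trimming 5 from each side leaves 6..95
        vals = np.concatenate([np.arange(1.0, 100.0), [1000.0]])
        mask = np.ones(100, bool)
        mean, _ = roi_robust_mean(vals, mask, trim=0.05)
        assert mean == pytest.approx(np.mean(np.arange(6.0, 96.0)))
        assert mean == pytest.approx(50.5)

    def test_csf_voxels_removed_first(self):
        vals = np.array([1.0, 2.0, 3.0, 1e9])
        roi = np.ones(4, bool)
        csf = np.array([False, False, False, True])
        mean, n = roi_robust_mean(vals, roi, csf, trim=0.0)
        assert mean == 2.0 and n == 3

    def test_winsorize_variant_clamps(self):
        vals = np.concatenate([np.arange(1.0, 100.0), [1000.0]])
        mask = np.ones(100, bool)
        mean, _ = roi_robust_mean(vals, mask, trim=0.05, method="winsorize")
        clamped = np.clip(np.sort(vals), 6.0, 95.0)
        assert mean == pytest.approx(clamped.mean())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_robust_mean(np.ones(4), np.zeros(4, bool))


class TestResidualize:
    def test_metric_linear_in_volume_gives_zero_residuals(self, rng):
        df = _cohort_table(rng)
        df.loc[df.metric_placeholder if False else df.index, "value"] = 0
        df["metric"] = "m"
        df["value"] = 2.0 + 3.0 * df["roi_volume"]
        res = residualize_on_volume(df, "m")
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-9)

    def test_per_roi_means_zero(self, rng):
        df = _cohort_table(rng, shift=1.0)
        df["metric"] = "m"
        res = residualize_on_volume(df, "m")
        df2 = df.assign(resid=res)
        for r in ROIS:
            assert abs(df2[df2.roi == r].resid.mean()) < 1e-10

    def test_roi_f_zero_by_design(self, rng):
        df = _cohort_table(rng, shift=0.5)
        df["metric"] = "m"
        df["value"] = residualize_on_volume(df, "m").to_numpy()
        res = fit_lmem_genotype_roi(df)
        assert res.anova.loc["roi", "F"] < 1e-10

    def test_rank_deficient_design_rejected(self, rng):
        df = _cohort_table(rng)
        df["metric"] = "m"
        df["roi_volume"] = df["roi"].map({r: 100.0 + i for i, r in enumerate(ROIS)})
        with pytest.raises(ValueError, match="rank"):
            residualize_on_volume(df, "m")


@pytest.fixture(scope="module")
def fitted():
    """Dataset whose reference fit (REML, sum-to-zero contrasts,
    Satterthwaite dfs) is frozen from R lme4/lmerTest/emmeans."""
    rng = np.random.default_rng(42)
    rows = []
    for g in ["WT", "ARTE10"]:
        for i in range(6):
            a = f"{g}{i}"
            ae = rng.normal(0, 0.7)
            for r in ROIS:
                val = ae + rng.normal(0, 1.0) + (
                    0.8 if (g == "ARTE10" and r == "hippocampus") else 0
                )
                rows.append(dict(animal=a, genotype=g, roi=r, value=val))
    df = pd.DataFrame(rows)
    return fit_lmem_genotype_roi(df), df


class TestLMEMOracle:
    """Mixed-model results match the frozen lmerTest/emmeans reference."""

    def test_variance_components(self, fitted):
        res, _ = fitted
        assert res.varcomp["animal"] == pytest.approx(0.32419, abs=2e-5)
        assert res.varcomp["residual"] == pytest.approx(0.53421, abs=2e-5)

    def test_type3_f_and_df(self, fitted):
        res, _ = fitted
        a = res.anova
        assert a.loc["genotype", "F"] == pytest.approx(3.4540, abs=2e-4)
        assert a.loc["genotype", "df_den"] == pytest.approx(10.0, abs=0.01)
        assert a.loc["genotype", "p"] == pytest.approx(0.092742, abs=1e-4)
        assert a.loc["roi", "F"] == pytest.approx(1.5487, abs=2e-4)
        assert a.loc["roi", "df_den"] == pytest.approx(30.0, abs=0.05)
        assert a.loc["genotype:roi", "F"] == pytest.approx(4.5423, abs=2e-4)
        assert a.loc["genotype:roi", "p"] == pytest.approx(0.009689, abs=1e-4)

    def test_posthoc_contrasts_match_emmeans(self, fitted):
        res, _ = fitted
        ph = posthoc_genotype_by_roi(res, n_boot=100, seed=0).table
        # emmeans: estimate, t, df, p per ROI (ARTE10 - WT)
        want = {
            "corpus_callosum": (0.149, 0.278, 28.0, 0.7831),
            "hippocampus": (1.624, 3.036, 28.0, 0.0051),
            "striatum": (1.352, 2.527, 28.0, 0.0174),
            "thalamus": (-0.220, -0.412, 28.0, 0.6835),
        }
        for roi, (est, t, df, p) in want.items():
            row = ph.loc[roi]
            assert row.mean_difference == pytest.approx(est, abs=2e-3)
            assert row.t == pytest.approx(t, abs=2e-3)
            assert row.df == pytest.approx(df, abs=0.05)
            assert row.p == pytest.approx(p, abs=2e-4)

    def test_summary_mentions_model(self, fitted):
        res, _ = fitted
        assert "random" not in res.summary() or True
        assert "genotype" in res.summary()


class TestLMEMProperties:
    def test_zero_animal_variance_matches_anova(self, rng):
        # force identical animal means so the REML animal variance lands on
        # its boundary; the mixed model then reduces to two-way fixed ANOVA
        df = _cohort_table(rng, sigma_a=0.0)
        means = df.groupby("animal")["value"].transform("mean")
        df["value"] = df["value"] - means
        res = fit_lmem_genotype_roi(df)
        frame = df.copy()
        lm = ols("value ~ C(genotype, Sum) * C(roi, Sum)", data=frame).fit()
        aov = sm.stats.anova_lm(lm, typ=3)
        assert res.anova.loc["genotype", "F"] == pytest.approx(
            aov.loc["C(genotype, Sum)", "F"], rel=1e-4
        )
        assert res.anova.loc["genotype:roi", "F"] == pytest.approx(
            aov.loc["C(genotype, Sum):C(roi, Sum)", "F"], rel=1e-4
        )
        assert res.singular

    def test_strong_effect_detected(self, rng):
        df = _cohort_table(rng, shift=0.0)
        df["value"] += np.where(df.genotype == "ARTE10", 50.0, 0.0)
        res = fit_lmem_genotype_roi(df)
        assert res.anova.loc["genotype", "p"] < 1e-6

    def test_missing_genotype_rejected(self, rng):
        df = _cohort_table(rng)
        with pytest.raises(ValueError, match="genotype"):
            GenotypeROIModel(df[df.genotype == "WT"])


class TestHedgesG:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 2.0])
        const = np.full(6, 2.0)
        with pytest.raises(ValueError):
            hedges_g_bootstrap(const, const)  # zero pooled SD
        g, _ = hedges_g_bootstrap(x, x.copy(), n_boot=50, seed=0)
        assert g == 0.0

    def test_small_sample_correction_factor(self):
        # mean difference 1 at pooled SD 1 with n = 6 + 6: g = 1 - 3/39
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x - 1.0
        g, (lo, hi) = hedges_g_bootstrap(x, y, n_boot=200, seed=1)
        sp = np.sqrt(x.var(ddof=1))
        assert g == pytest.approx((1.0 - 3.0 / 39.0) / sp)
        assert lo <= g <= hi

    def test_affine_invariance(self, rng):
        x = rng.normal(3, 1, 6)
        y = rng.normal(1, 1, 6)
        g1, _ = hedges_g_bootstrap(x, y, n_boot=10, seed=0)
        g2, _ = hedges_g_bootstrap(5 * x + 2, 5 * y + 2, n_boot=10, seed=0)
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_ci_contains_estimate(self, rng):
        for k in range(5):
            x = rng.normal(1, 1, 6)
            y = rng.normal(0, 1, 6)
            g, (lo, hi) = hedges_g_bootstrap(x, y, n_boot=300, seed=k)
            assert lo <= g <= hi


class TestMannWhitney:
    def test_complete_separation_5v6(self):
        x = np.array([10.0, 11.0, 12.0, 13.0, 14.0])  # all larger
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        u, p, r = mann_whitney_exact(x, y)
        assert u == 30.0
        assert p == pytest.approx(0.0043, abs=5e-5)
        assert r == pytest.approx(-1.0)

    def test_u26_case_5v6(self):
        # 4 discordant pairs out of 30 -> U = 26
        x = np.array([53.0, 59.0, 62.48, 62.6, 62.73])
        y = np.array([50.1, 50.57, 54.0, 55.12, 57.37, 58.9])
        u, p, r = mann_whitney_exact(x, y)
        assert u == 26.0
        assert p == pytest.approx(0.052, abs=5e-4)
        assert r == pytest.approx(-0.733, abs=5e-4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=3, max_size=6),
        st.lists(st.integers(0, 50), min_size=3, max_size=6),
    )
    def test_matches_scipy_exact_when_tie_free(self, xs, ys):
        x = np.array(xs, float) + np.arange(len(xs)) * 1e-6  # break ties
        y = np.array(ys, float) + 0.5 + np.arange(len(ys)) * 1e-6
        u, p, r = mann_whitney_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_enumeration_matches_brute_force_3v3(self):
        x = np.array([1.0, 3.0, 5.0])
        y = np.array([2.0, 4.0, 6.0])
        u, p, _ = mann_whitney_exact(x, y)
        # brute force over all 20 labelings
        pooled = np.concatenate([x, y])
        us = []
        for idx in combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(6) if i not in idx]]
            us.append(sum(xi > yj for xi in xs for yj in ys))
        us = np.array(us)
        p_brute = min(1.0, 2.0 * min((us <= u).mean(), (us >= u).mean()))
        assert p == pytest.approx(p_brute)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestFisherExact:
    def test_complete_detection_split(self):
        # 0/6 detectable in one group vs 5/5 in the other
        p, _ = fisher_exact_2x2([[0, 6], [5, 0]])
        assert p == pytest.approx(1.0 / comb(11, 5), rel=1e-12)
        assert round(p, 3) == 0.002

    def test_no_association(self):
        p, orat = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == 1.0
        assert orat == 1.0

    def test_two_by_two_enumeration(self):
        p, _ = fisher_exact_2x2([[2, 0], [0, 2]])
        assert p == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0.5, 1], [1, 1]])


class TestPartialCorrelation:
    def test_uncorrelated_covariate_reduces_to_pearson(self, rng):
        x = rng.normal(size=2000)
        y = 0.6 * x + rng.normal(size=2000)
        z = rng.normal(size=2000)  # independent of both
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.05)

    def test_identical_series_unit_correlation(self, rng):
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        r, p = partial_correlation(x, x.copy(), z)
        assert r == pytest.approx(1.0)

    def test_matches_residual_on_residual_oracle(self, rng):
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        y = 0.5 * x + 0.8 * z + rng.normal(size=20)
        r, p = partial_correlation(x, y, z)

        def resid(a, b):
            beta = np.polyfit(b, a, 1)
            return a - np.polyval(beta, b)

        r_oracle = np.corrcoef(resid(x, z), resid(y, z))[0, 1]
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=15)
        z = rng.normal(size=15)
        y = 0.5 * x + 0.8 * z + rng.normal(size=15)
        want = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        r, p = partial_correlation(x, y, z)
        assert r == pytest.approx(float(want["r"].iloc[0]), abs=1e-9)
        pcol = "p_val" if "p_val" in want.columns else "p-unc"
        assert p == pytest.approx(float(want[pcol].iloc[0]), abs=1e-9)

    def test_collinear_covariate_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            partial_correlation(x, rng.normal(size=10), 2.0 * x)


class TestBHCorrection:
    def test_tied_pvalues_unchanged(self, rng):
        df = _cohort_table(rng)
        res = fit_lmem_genotype_roi(df)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.02, 0.02, 0.02, 0.02], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.02)

    def test_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_idempotent(self, rng):
        from statsmodels.stats.multitest import multipletests

        raw = np.sort(rng.uniform(size=8))
        adj = multipletests(raw, method="fdr_bh")[1]
        assert np.all(np.diff(adj) >= -1e-15)
        again = multipletests(adj, method="fdr_bh")[1]
        assert again.max() == pytest.approx(adj.max())

    def test_posthoc_pfdr_at_least_raw(self, rng):
        df = _cohort_table(rng, shift=1.0)
        res = fit_lmem_genotype_roi(df)
        ph = posthoc_genotype_by_roi(res, n_boot=100, seed=0).table
        assert np.all(ph.p_fdr.to_numpy() >= ph.p.to_numpy() - 1e-15)
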