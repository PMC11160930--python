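"""Mixed-model EWAS: REML correctness, calibration, inflation factor."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm

from mtewas.ewas import build_design, fit_cpg_lmm, genomic_inflation, run_ewas
from mtewas.synthetic import MARKERS
from tests.conftest import auto_covariates


def _simulate_lmm(rng, n=120, n_chips=6, beta=(0.3, 0.05), chip_sd=0.2, resid_sd=0.4):
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    chips = np.arange(n) % n_chips
    u = rng.normal(0, chip_sd, n_chips)
    y = X @ np.asarray(beta) + u[chips] + rng.normal(0, resid_sd, n)
    return y, X, chips


class TestFitCpgLmm:
    def test_balanced_two_chip_matches_anova_components(self):
        """Balanced one-way layout: REML equals the method-of-moments
        (MSB - MSW)/m estimator for the chip variance."""
        y = np.array([1.0, 1.2, 0.9, 2.1, 2.0, 2.3])
        chip = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_cpg_lmm(y, np.ones((6, 1)), chip)
        gm = y.reshape(2, 3).mean(axis=1)
        msb = 3 * ((gm - y.mean()) ** 2).sum() / 1
        msw = ((y.reshape(2, 3) - gm[:, None]) ** 2).sum() / 4
        assert fit.sigma2_chip == pytest.approx((msb - msw) / 3, rel=1e-6)
        assert fit.sigma2_resid == pytest.approx(msw, rel=1e-6)

    def test_zero_chip_variance_reduces_exactly_to_ols(self):
        """When the REML estimate hits the sigma2_chip = 0 boundary, fixed
        effects and their covariance equal ordinary least squares exactly."""
        rng = np.random.default_rng(8)
        hit_boundary = 0
        for _ in range(20):
            y, X, chips = _simulate_lmm(rng, chip_sd=0.0)
            fit = fit_cpg_lmm(y, X, chips)
            if fit.sigma2_chip == 0.0:
                hit_boundary += 1
                ols_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ ols_coef
                s2 = resid @ resid / (len(y) - X.shape[1])
                ols_cov = s2 * np.linalg.inv(X.T @ X)
                assert np.allclose(fit.coef, ols_coef, atol=1e-10)
                assert np.allclose(fit.cov, ols_cov, atol=1e-10)
        assert hit_boundary >= 5  # boundary is reached on a fair share of null fits

    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        for _ in range(3):
            y, X, chips = _simulate_lmm(rng)
            fit = fit_cpg_lmm(y, X, chips)
            ref = sm.MixedLM(y, X, groups=chips).fit(reml=True)
            assert np.allclose(fit.coef, ref.fe_params, atol=1e-5)
            assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-4)
            assert fit.sigma2_chip == pytest.approx(
                float(np.asarray(ref.cov_re).ravel()[0]), abs=1e-4
            )
            # statsmodels reports SEs from the joint observed information;
            # the GLS covariance agrees to well under a percent
            assert np.allclose(
                np.sqrt(np.diag(fit.cov)), np.asarray(ref.bse_fe), rtol=2e-2
            )

    def test_parameter_recovery_of_planted_slope(self):
        """Mean estimate over replicates is within 2*(mean SE)/sqrt(R) of truth."""
        rng = np.random.default_rng(42)
        gamma = 0.02
        reps, ests, ses = 200, [], []
        for _ in range(reps):
            y, X, chips = _simulate_lmm(rng, n=400, n_chips=12, beta=(0.1, gamma))
            fit = fit_cpg_lmm(y, X, chips)
            ests.append(fit.coef[1])
            ses.append(np.sqrt(fit.cov[1, 1]))
        bias = np.mean(ests) - gamma
        assert abs(bias) < 2 * np.mean(ses) / np.sqrt(reps)

    def test_reml_loglik_at_optimum_beats_ols_boundary(self):
        rng = np.random.default_rng(12)
        y, X, chips = _simulate_lmm(rng, chip_sd=0.5)
        fit = fit_cpg_lmm(y, X, chips)
        assert fit.sigma2_chip > 0
        ols_fit = fit_cpg_lmm(y, X, np.zeros(len(y), dtype=int))  # forces OLS
        assert fit.loglik >= ols_fit.loglik - 1e-8

    def test_rank_deficient_design_raises_with_aliased_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="aliased"):
            fit_cpg_lmm(np.random.default_rng(0).normal(size=20), X, np.arange(20) % 4)

    def test_single_chip_falls_back_to_ols_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        y, X, _ = _simulate_lmm(rng, n=40)
        with caplog.at_level("WARNING"):
            fit = fit_cpg_lmm(y, X, np.zeros(40, dtype=int))
        assert fit.sigma2_chip == 0.0
        assert "fewer than 2 chips" in caplog.text


class TestRunEwas:
    def test_marker_rescaling_covariance(self, small_cohort):
        """Multiplying a marker by c scales beta and SE by 1/c, t and p fixed.

        On the REML path the profiled variance-ratio optimum lies in a flat
        basin, so the invariance holds to the optimizer's effective precision
        (~1e-7); on the direct (zero chip variance) path it holds to 1e-10.
        """
        ph = small_cohort.pheno[small_cohort.pheno["platform"] == "p1"].reset_index(drop=True)
        covs = auto_covariates(ph)
        bm = small_cohort.beta_platform1
        sub = type(bm)(values=bm.values.iloc[:10], annotation=bm.annotation, platform="p1")
        scaled_ph = ph.copy()
        scaled_ph["il6"] = scaled_ph["il6"] * 100.0
        res = run_ewas(sub, ph, "il6", covs)
        res_scaled = run_ewas(sub, scaled_ph, "il6", covs)
        assert np.allclose(res_scaled["beta"], res["beta"] / 100.0, rtol=2e-7)
        assert np.allclose(res_scaled["se"], res["se"] / 100.0, rtol=2e-7)
        assert np.allclose(res_scaled["t"], res["t"], rtol=2e-7)
        assert np.allclose(res_scaled["p"], res["p"], rtol=1e-6)
        # single-chip grouping forces the non-iterative path: exact invariance
        ols_ph = ph.assign(chip_id="one_chip")
        ols_scaled = scaled_ph.assign(chip_id="one_chip")
        r1 = run_ewas(sub, ols_ph, "il6", covs)
        r2 = run_ewas(sub, ols_scaled, "il6", covs)
        assert np.allclose(r2["beta"], r1["beta"] / 100.0, rtol=1e-10)
        assert np.allclose(r2["se"], r1["se"] / 100.0, rtol=1e-10)
        assert np.allclose(r2["t"], r1["t"], rtol=1e-10)

    def test_null_cohort_p_values_are_calibrated(self, null_cohort):
        ph = null_cohort.pheno[null_cohort.pheno["platform"] == "p1"].reset_index(drop=True)
        res = run_ewas(null_cohort.beta_platform1, ph, "il6", auto_covariates(ph))
        frac = float((res["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07  # binomial band around 0.05 for M=1000
        assert 0.85 <= genomic_inflation(res["p"]) <= 1.15

    def test_permuted_marker_gives_unit_inflation(self, null_cohort):
        ph = null_cohort.pheno[null_cohort.pheno["platform"] == "p1"].reset_index(drop=True)
        rng = np.random.default_rng(123)
        ph_perm = ph.copy()
        ph_perm["il6"] = rng.permutation(ph_perm["il6"].to_numpy())
        res = run_ewas(null_cohort.beta_platform1, ph_perm, "il6", auto_covariates(ph))
        assert 0.9 <= genomic_inflation(res["p"]) <= 1.1

    def test_duplicate_cpg_rows_give_identical_results(self, small_cohort):
        ph = small_cohort.pheno[small_cohort.pheno["platform"] == "p1"].reset_index(drop=True)
        bm = small_cohort.beta_platform1
        dup_vals = pd.concat([bm.values.iloc[[0]], bm.values.iloc[[0]]])
        dup_vals.index = pd.Index(["cgA", "cgB"], name="cpg_id")
        ann = pd.DataFrame(
            {"cpg_id": ["cgA", "cgB"], "chr": 1, "pos_1based": [1, 2], "gene": "G"}
        )
        dup = type(bm)(values=dup_vals, annotation=ann, platform="p1")
        res = run_ewas(dup, ph, "scd14", auto_covariates(ph))
        for col in ("beta", "se", "t", "p"):
            assert res[col].iloc[0] == res[col].iloc[1]

    def test_constant_cpg_emits_na_row_with_warning(self, small_cohort):
        ph = small_cohort.pheno[small_cohort.pheno["platform"] == "p1"].reset_index(drop=True)
        bm = small_cohort.beta_platform1
        vals = bm.values.iloc[:3].copy()
        vals.iloc[1] = 0.5
        ann = bm.annotation.iloc[:3]
        const = type(bm)(values=vals, annotation=ann, platform="p1")
        with pytest.warns(UserWarning, match="constant methylation"):
            res = run_ewas(const, ph, "il6", auto_covariates(ph))
        assert res["p"].isna().sum() == 1
        assert np.isnan(res["beta"].iloc[1])

    def test_t_and_gaussian_references_agree_at_cohort_size(self, small_cohort):
        """At n ~ a few hundred the t and normal references are interchangeable."""
        ph = small_cohort.pheno[small_cohort.pheno["platform"] == "p1"].reset_index(drop=True)
        bm = small_cohort.beta_platform1
        sub = type(bm)(values=bm.values.iloc[:20], annotation=bm.annotation, platform="p1")
        res = run_ewas(sub, ph, "ddimer", auto_covariates(ph))
        gauss_p = 2 * norm.sf(np.abs(res["t"]))
        assert np.allclose(res["p"], gauss_p, atol=5e-3)


class TestGenomicInflation:
    def test_uniform_grid_gives_unit_lambda(self):
        n = 5000
        p = (np.arange(n) + 0.5) / n
        assert genomic_inflation(p) == pytest.approx(1.0, abs=1e-3)

    def test_doubled_median_chi2_gives_lambda_two(self):
        p = np.full(99, chi2.sf(2 * chi2.ppf(0.5, 1), 1))
        assert genomic_inflation(p) == pytest.approx(2.0, abs=1e-9)

    def test_all_ones_give_lambda_zero(self):
        assert genomic_inflation(np.ones(10)) == 0.0

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


def test_build_design_expands_categoricals_with_reference_level():
    pheno = pd.DataFrame(
        {
            "sample_id": list("abcdef"),
            "il6": [1.0, 2, 3, 4, 5, 6],
            "race": ["black", "white", "black", "hispanic", "black", "white"],
        }
    )
    X, names = build_design(pheno, "il6", ["race"])
    assert names == ["intercept", "il6", "race[hispanic]", "race[white]"]
    assert X.shape == (6, 4)
    assert X[:, 2].sum() == 1  # one hispanic indicator
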