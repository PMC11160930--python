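"""Cross-phenotype statistics: SHom, ACAT, MinP/P_ACT, GHC, GBJ, OmniTest."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm

from mtewas.meta import SignificanceSet
from mtewas.multitrait import (
    MCConfig,
    acat,
    gbj,
    ghc,
    minp_pact,
    omnitest,
    overlap_summary,
    run_multitrait,
    shom,
    z_from_summary,
)

R_I = np.eye(3)
R_EQ5 = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
MC = MCConfig(n_draws=20_000, seed=7)


def _make_set(label, ids):
    return SignificanceSet(
        label=label,
        m_tests=100,
        alpha_family=0.05,
        threshold=5e-4,
        table=pd.DataFrame({"cpg_id": list(ids), "p": 1e-5}),
    )


class TestZFromSummary:
    def test_values(self):
        assert z_from_summary(0.0, 1.0) == 0.0
        assert z_from_summary(1.0, 0.5) == 2.0
        # an effect of -0.59 with SE 0.09 (a top IL-6 association's scale)
        assert z_from_summary(-0.59, 0.09) == pytest.approx(-6.556, abs=1e-3)

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValueError):
            z_from_summary(1.0, 0.0)


class TestShom:
    def test_zero_vector_gives_zero_statistic(self):
        stat, p = shom([0.0, 0.0, 0.0], R_EQ5)
        assert stat == 0.0 and p == 1.0

    def test_independence_closed_form(self):
        """At R = I with equal z the statistic is (sum z)^2 / K."""
        stat, p = shom([2.0, 2.0, 2.0], R_I)
        assert stat == pytest.approx(12.0, abs=1e-12)
        assert p == pytest.approx(chi2.sf(12.0, 1), rel=1e-12)
        assert p == pytest.approx(5.320e-4, rel=1e-3)

    def test_equicorrelated_closed_form(self):
        """Equicorrelated R: e'R^-1 z = sum z/(1+(K-1)rho), e'R^-1 e = K/(1+(K-1)rho)."""
        stat, p = shom([2.0, 2.0, 2.0], R_EQ5)
        assert stat == pytest.approx(6.0, abs=1e-10)
        assert p == pytest.approx(1.431e-2, rel=1e-3)

    def test_singular_correlation_raises(self):
        bad = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular"):
            shom([1.0, 1.0, 1.0], bad)


class TestAcat:
    def test_all_half_gives_half(self):
        assert acat([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_equal_inputs_are_identity(self):
        assert acat([0.01, 0.01, 0.01]) == pytest.approx(0.01, rel=1e-9)

    def test_direct_tangent_average_oracle(self):
        p_in = np.array([0.001, 0.5, 0.9])
        t = np.tan((0.5 - p_in) * np.pi).mean()
        expected = 0.5 - np.arctan(t) / np.pi
        assert expected == pytest.approx(3.028e-3, rel=2e-3)
        assert acat(p_in) == pytest.approx(expected, rel=1e-10)

    def test_tiny_inputs_use_asymptote_without_overflow(self):
        p = acat([1e-200, 0.5, 0.5])
        assert 0 < p < 1e-195
        assert p == pytest.approx(3e-200, rel=1e-3)

    def test_weights(self):
        assert acat([0.01, 0.99], weights=[1.0, 0.0]) == pytest.approx(0.01, rel=1e-9)
        with pytest.raises(ValueError):
            acat([0.5, 0.5], weights=[0.0, 0.0])


class TestMinpPact:
    def test_k1_identity(self):
        mr, pa = minp_pact([1.5], np.eye(1))
        assert pa == pytest.approx(mr, rel=1e-12)

    @pytest.mark.parametrize("p0", [0.1, 0.01])
    def test_independence_identity(self, p0):
        z = norm.isf(p0 / 2)
        mr, pa = minp_pact([z, 0.0, 0.0], R_I)
        assert mr == pytest.approx(p0, rel=1e-10)
        assert pa == pytest.approx(1 - (1 - p0) ** 3, rel=1e-6)

    def test_monte_carlo_box_oracle(self):
        """pact matches a 10^6-draw MVN simulation within 3 MC standard errors."""
        z = np.array([3.0, 0.2, -0.1])
        mr, pa = minp_pact(z, R_EQ5)
        c = norm.isf(mr / 2)
        rng = np.random.default_rng(2024)
        draws = rng.multivariate_normal(np.zeros(3), R_EQ5, size=1_000_000)
        hits = np.any(np.abs(draws) >= c, axis=1).mean()
        se = np.sqrt(hits * (1 - hits) / 1_000_000)
        assert pa == pytest.approx(hits, abs=3 * se)

    def test_bonferroni_sandwich_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            z = rng.normal(0, 2, 3)
            mr, pa = minp_pact(z, R_EQ5)
            assert mr - 1e-12 <= pa <= 3 * mr + 1e-12


class TestGhcGbj:
    def test_null_vector_degenerates(self):
        stat_h, p_h = ghc([0.0, 0.0, 0.0], R_I, MC)
        stat_b, p_b = gbj([0.0, 0.0, 0.0], R_I, MC)
        assert stat_h <= 0.0 and p_h >= 0.5
        assert stat_b == 0.0 and p_b >= 0.5

    def test_independence_matches_hand_enumerated_hc(self):
        """R = I: the statistic equals classic higher criticism computed by
        direct enumeration over the three observed thresholds."""
        z = np.array([3.0, 1.0, 0.5])
        stat, _ = ghc(z, R_I, MC)
        t = np.sort(np.abs(z))[::-1]
        q = 2 * norm.sf(t)
        j = np.arange(1, 4)
        hand = np.max((j - 3 * q) / np.sqrt(3 * q * (1 - q)))
        assert stat == pytest.approx(hand, rel=1e-12)

    def test_independence_matches_hand_enumerated_bj(self):
        z = np.array([3.0, 1.0, 0.5])
        stat, _ = gbj(z, R_I, MC)
        t = np.sort(np.abs(z))[::-1]
        q = 2 * norm.sf(t)
        terms = []
        for j in (1, 2, 3):
            if j > 3 * q[j - 1]:
                t1 = j * np.log(j / (3 * q[j - 1]))
                t2 = (3 - j) * np.log((3 - j) / (3 * (1 - q[j - 1]))) if j < 3 else 0.0
                terms.append(2 * (t1 + t2))
            else:
                terms.append(0.0)
        assert stat == pytest.approx(max(terms), rel=1e-12)

    def test_mc_p_value_reproducible_across_seeds_within_error(self):
        """Two independent MC seeds agree within 3 combined binomial SEs."""
        z = np.array([2.5, 1.8, 0.3])
        R = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
        mc1 = MCConfig(n_draws=100_000, seed=1)
        mc2 = MCConfig(n_draws=100_000, seed=2)
        for test in (ghc, gbj):
            _, p1 = test(z, R, mc1)
            _, p2 = test(z, R, mc2)
            se = np.sqrt(p1 * (1 - p1) / 1e5 + p2 * (1 - p2) / 1e5)
            assert abs(p1 - p2) <= 3 * se

    def test_p_value_resolution_floor(self):
        _, p = ghc([8.0, 8.0, 8.0], R_I, MCConfig(n_draws=10_000, seed=0))
        assert p == pytest.approx(1 / 10_001)


class TestOmnitest:
    def test_all_components_half_give_half(self):
        assert acat([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_row_fields_and_component_consistency(self):
        row = omnitest([1.0, -0.5, 2.0], R_EQ5, MC)
        assert row["pact_p"] >= row["minp_raw"]
        assert 0 < row["omnitest_p"] <= 1
        assert row["omnitest_p"] == pytest.approx(
            acat([row["pact_p"], row["gbj_p"], row["ghc_p"]]), rel=1e-12
        )
        assert row["mc_draws"] == MC.n_draws

    def test_concordant_extreme_signal(self):
        row = omnitest([6.0, 6.0, 6.0], R_I, MC)
        assert row["omnitest_p"] < 1e-6
        assert row["shom_p"] < 1e-6


class TestInvariances:
    def test_sign_flip_invariance(self):
        z = np.array([1.2, -0.7, 2.3])
        R = np.full((3, 3), 0.3) + 0.7 * np.eye(3)
        assert shom(z, R)[0] == pytest.approx(shom(-z, R)[0], rel=1e-12)
        assert minp_pact(z, R) == pytest.approx(minp_pact(-z, R), rel=1e-12)
        mc = MCConfig(n_draws=10_000, seed=3)
        assert ghc(z, R, mc) == pytest.approx(ghc(-z, R, mc), rel=1e-12)
        assert gbj(z, R, mc) == pytest.approx(gbj(-z, R, mc), rel=1e-12)

    def test_trait_permutation_invariance(self):
        z = np.array([1.2, -0.7, 2.3])
        R = np.array([[1, 0.3, 0.5], [0.3, 1, 0.2], [0.5, 0.2, 1]])
        perm = [2, 0, 1]
        zp, Rp = z[perm], R[np.ix_(perm, perm)]
        assert shom(z, R)[0] == pytest.approx(shom(zp, Rp)[0], rel=1e-12)
        assert minp_pact(z, R)[1] == pytest.approx(minp_pact(zp, Rp)[1], rel=1e-9)
        mc = MCConfig(n_draws=10_000, seed=3)
        # statistics are permutation-invariant exactly; MC p-values are
        # reproducible because the null law of the statistic is unchanged
        assert ghc(z, R, mc)[0] == pytest.approx(ghc(zp, Rp, mc)[0], rel=1e-12)
        assert gbj(z, R, mc)[0] == pytest.approx(gbj(zp, Rp, mc)[0], rel=1e-12)

    def test_tied_magnitudes_are_stable(self):
        z = np.array([1.5, -1.5, 1.5])
        stat1, _ = ghc(z, R_EQ5, MC)
        stat2, _ = ghc(z[[1, 0, 2]], R_EQ5, MC)
        assert stat1 == pytest.approx(stat2, rel=1e-12)


class TestRunMultitrait:
    @staticmethod
    def _tables(Z, cpgs=None):
        cpgs = cpgs or [f"cg{i}" for i in range(Z.shape[0])]
        out = {}
        for k, m in enumerate(("il6", "scd14", "ddimer")):
            out[m] = pd.DataFrame(
                {"cpg_id": cpgs, "beta": Z[:, k], "se": np.ones(Z.shape[0])}
            )
        return out

    def test_single_cpg_gives_single_row_matching_scalar_api(self):
        from mtewas.preprocess import TraitCorr

        Z = np.array([[2.0, 1.0, -0.5]])
        R = TraitCorr(matrix=np.full((3, 3), 0.3) + 0.7 * np.eye(3))
        mc = MCConfig(n_draws=10_000, seed=5)
        res = run_multitrait(self._tables(Z), R, mc)
        assert len(res) == 1
        stat, p = shom(Z[0], R.matrix)
        assert res["shom_stat"].iloc[0] == pytest.approx(stat, rel=1e-12)
        row = omnitest(Z[0], R.matrix, mc)
        assert res["ghc_stat"].iloc[0] == pytest.approx(row["ghc_stat"], rel=1e-12)
        assert res["gbj_p"].iloc[0] == pytest.approx(row["gbj_p"], rel=1e-12)

    def test_null_z_vectors_give_uniform_shom_p(self):
        rng = np.random.default_rng(17)
        from scipy.stats import kstest
        from mtewas.preprocess import TraitCorr

        R = np.full((3, 3), 0.4) + 0.6 * np.eye(3)
        Z = rng.multivariate_normal(np.zeros(3), R, size=2000)
        res = run_multitrait(self._tables(Z), TraitCorr(matrix=R), MCConfig(seed=1))
        assert kstest(res["shom_p"], "uniform").pvalue > 0.01

    def test_empty_join_raises(self):
        from mtewas.preprocess import TraitCorr

        Z = np.array([[1.0, 1.0, 1.0]])
        tables = self._tables(Z)
        tables["ddimer"] = tables["ddimer"].assign(cpg_id=["other"])
        with pytest.raises(ValueError, match="shared"):
            run_multitrait(tables, TraitCorr(matrix=R_EQ5), MCConfig(seed=1))


class TestOverlapSummary:
    def test_disjoint_sets_have_zero_intersections(self):
        out = overlap_summary([_make_set("a", ["x"]), _make_set("b", ["y"])])
        assert out["pairwise"].loc["a", "b"] == 0

    def test_identical_sets_intersect_fully(self):
        out = overlap_summary([_make_set("a", ["x", "y"]), _make_set("b", ["x", "y"])])
        assert out["pairwise"].loc["a", "b"] == 2

    def test_novelty_counts_with_manual_sets(self):
        sets = [
            _make_set("multi1", ["a", "b", "c"]),
            _make_set("multi2", ["b", "c", "d"]),
            _make_set("single", ["a"]),
        ]
        out = overlap_summary(sets, single_trait_labels=["single"])
        assert out["pairwise"].loc["multi1", "multi2"] == 2
        assert out["novel"]["multi1"] == 2  # b, c
        assert out["novel"]["multi2"] == 3  # b, c, d
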