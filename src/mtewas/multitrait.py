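"""Cross-phenotype association statistics on per-CpG z-score vectors.

Given the vector z = (beta_k / se_k) of single-trait association z-scores for
one CpG across K correlated markers, and the marker Pearson correlation
matrix R (the substitute for LD when the correlated units are phenotypes
measured on the same samples), this module provides:

* ``shom`` — the homogeneous-effect cross-phenotype statistic, a
  correlation-adjusted fixed-effect combination
  (e' R^-1 z)^2 / (e' R^-1 e) ~ chi2_1 under the null, with equal trait
  weights (all traits are measured on the same samples, so sample-size
  weights cancel);
* ``minp_pact`` — the minimum two-sided p-value across traits, adjusted to
  the probability that the smallest of K correlated tests is at least that
  small under MVN(0, R) (a deterministic box-probability computation);
* ``ghc`` / ``gbj`` — generalized higher criticism and generalized
  Berk-Jones: maxima over the observed |z| thresholds of standardised
  exceedance counts, with the binomial variance replaced by the
  correlation-aware Var_R(S(t)); null p-values by seeded Monte Carlo with the
  add-one estimator (resolution floor 1/(B+1));
* ``acat`` / ``omnitest`` — the aggregated Cauchy combination of the three
  component p-values, robust to their dependence.

All statistics depend on z only through |z| (sign-flip invariant) and are
invariant to a consistent permutation of the traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from mtewas._mvn import abs_orthant2, prob_any_exceeds
from mtewas.meta import SignificanceSet
from mtewas.preprocess import TraitCorr

_P_CLIP_LO = 1e-300
_P_CLIP_HI = 1.0 - 1e-16
_SMALL_P_ASYMPTOTE = 1e-15


@dataclass
class MCConfig:
    """Monte-Carlo settings for the GHC/GBJ null reference distribution.

    ``n_draws`` null z-vectors give a p-value resolution floor of
    1/(n_draws+1).  ``antithetic`` mirrors each draw; note the exceedance
    statistics depend only on |z|, so mirroring does not add information and
    the flag exists for completeness.
    """

    n_draws: int = 10_000
    seed: int = 0
    antithetic: bool = False

    def validate(self) -> None:
        if self.n_draws < 10_000:
            raise ValueError("n_draws must be at least 10^4 for usable resolution")

    @property
    def resolution(self) -> float:
        return 1.0 / (self.n_draws + 1)


def z_from_summary(beta: float, se: float) -> float:
    """z statistic from an effect estimate and its standard error."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return beta / se


def _check_pd(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if np.linalg.eigvalsh(R).min() <= 1e-10:
        raise ValueError("correlation matrix is singular; repair it upstream")
    return R


def _as_matrix(R) -> np.ndarray:
    return R.matrix if isinstance(R, TraitCorr) else np.asarray(R, dtype=float)


def shom(z, R) -> tuple[float, float]:
    """Homogeneous-effect statistic and its chi2_1 p-value."""
    Rm = _check_pd(_as_matrix(R))
    z = np.asarray(z, dtype=float)
    e = np.ones(len(z))
    Ri_z = np.linalg.solve(Rm, z)
    Ri_e = np.linalg.solve(Rm, e)
    stat = float((e @ Ri_z) ** 2 / (e @ Ri_e))
    return stat, float(chi2.sf(stat, df=1))


def shom_many(Z: np.ndarray, R) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``shom`` over rows of Z (M x K)."""
    Rm = _check_pd(_as_matrix(R))
    e = np.ones(Rm.shape[0])
    Ri_e = np.linalg.solve(Rm, e)
    denom = float(e @ Ri_e)
    num = Z @ Ri_e
    stat = num**2 / denom
    return stat, chi2.sf(stat, df=1)


def acat(p_values, weights=None) -> float:
    """Aggregated Cauchy combination of dependent p-values.

    T = sum w_i tan((0.5 - p_i) pi) / sum w_i;  p = 0.5 - arctan(T)/pi.
    Inputs are clipped to [1e-300, 1 - 1e-16]; below 1e-15 the tangent is
    replaced by its small-p asymptote 1/(pi p) to avoid overflow.
    """
    p = np.clip(np.asarray(p_values, dtype=float), _P_CLIP_LO, _P_CLIP_HI)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    small = p < _SMALL_P_ASYMPTOTE
    terms = np.where(small, 1.0 / (np.pi * np.maximum(p, _P_CLIP_LO)), np.tan((0.5 - p) * np.pi))
    t_stat = float((w * terms).sum() / wsum)
    if t_stat > 1e14:  # back-transform via the same asymptote
        return float(1.0 / (np.pi * t_stat))
    return float(0.5 - np.arctan(t_stat) / np.pi)


def minp_pact(z, R) -> tuple[float, float]:
    """Minimum two-sided p across traits and its correlation-adjusted version.

    pact is the probability under MVN(0, R) that at least one |Z_k| reaches
    the observed minimum p's threshold; computed by deterministic numerical
    integration (box probability), switching to a stable inclusion-exclusion
    tail once the complement would lose precision.
    """
    Rm = _check_pd(_as_matrix(R))
    z = np.asarray(z, dtype=float)
    p = 2.0 * norm.sf(np.abs(z))
    p_min = float(np.clip(p.min(), _P_CLIP_LO, 1.0))
    if len(z) == 1:
        return p_min, p_min
    c = norm.isf(p_min / 2.0)
    pact = float(prob_any_exceeds(c, Rm))
    pact = float(np.clip(pact, p_min, min(len(z) * p_min, 1.0)))
    return p_min, pact


def minp_pact_many(Z: np.ndarray, R) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``minp_pact`` over rows of Z."""
    Rm = _check_pd(_as_matrix(R))
    p = 2.0 * norm.sf(np.abs(Z))
    p_min = np.clip(p.min(axis=1), _P_CLIP_LO, 1.0)
    c = norm.isf(p_min / 2.0)
    pact = prob_any_exceeds(c, Rm)
    pact = np.clip(pact, p_min, np.minimum(Z.shape[1] * p_min, 1.0))
    return p_min, pact


class _ExceedanceEngine:
    """Shared machinery for GHC/GBJ: Var_R(S(t)) and vectorised statistics."""

    def __init__(self, R: np.ndarray):
        self.R = _check_pd(R)
        self.K = R.shape[0]
        self.pairs = [
            (i, j) for i in range(self.K) for j in range(i + 1, self.K)
        ]
        self.rhos = np.array([self.R[i, j] for i, j in self.pairs])
        self.chol = np.linalg.cholesky(self.R)

    def var_s(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(Var_R(S(t)), 2*Phibar(t)) for an array of thresholds t >= 0."""
        q = 2.0 * norm.sf(t)
        var = self.K * q * (1.0 - q)
        for rho, _pair in zip(self.rhos, self.pairs):
            joint = abs_orthant2(t, rho)
            var = var + 2.0 * (joint - q * q)
        return np.maximum(var, 0.0), q

    def stats(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(ghc, gbj) statistics for each row of Z (M x K).

        Thresholds are the ordered |z| magnitudes t_1 >= ... >= t_K of each
        row, so the exceedance count at t_j is exactly j; ties in |z| leave
        the max over thresholds unchanged.
        """
        A = np.sort(np.abs(Z), axis=1)[:, ::-1]  # descending magnitudes
        var, q = self.var_s(A)
        var = np.maximum(var, 1e-12)
        j = np.arange(1, self.K + 1, dtype=float)
        expected = self.K * q
        ghc_terms = (j - expected) / np.sqrt(var)
        ghc_stat = ghc_terms.max(axis=1)
        # Berk-Jones LLR under independence, overdispersion-matched to Var_R
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = j * np.log(j / np.maximum(expected, 1e-300))
            km = self.K - j
            term2 = np.where(
                km > 0,
                km * np.log(np.maximum(km, 1e-300) / np.maximum(self.K * (1.0 - q), 1e-300)),
                0.0,
            )
        llr = 2.0 * (term1 + term2)
        llr = np.where(j > expected, llr, 0.0)
        var_binom = np.maximum(self.K * q * (1.0 - q), 1e-12)
        gbj_terms = llr * var_binom / var
        gbj_stat = np.maximum(gbj_terms, 0.0).max(axis=1)
        return ghc_stat, gbj_stat

    def null_stats(self, mc: MCConfig) -> tuple[np.ndarray, np.ndarray]:
        """Seeded MVN(0, R) reference distribution of (ghc, gbj) statistics."""
        rng = np.random.default_rng(mc.seed)
        if mc.antithetic:
            half = (mc.n_draws + 1) // 2
            raw = rng.standard_normal((half, self.K))
            raw = np.vstack([raw, -raw])[: mc.n_draws]
        else:
            raw = rng.standard_normal((mc.n_draws, self.K))
        Z = raw @ self.chol.T
        return self.stats(Z)


def _mc_pvalue(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one Monte-Carlo p: (r + 1)/(B + 1), r = # null >= observed."""
    sorted_null = np.sort(null)
    r = len(null) - np.searchsorted(sorted_null, observed, side="left")
    return (r + 1.0) / (len(null) + 1.0)


def ghc(z, R, mc: MCConfig) -> tuple[float, float]:
    """Generalized higher criticism statistic and Monte-Carlo p-value."""
    mc.validate()
    engine = _ExceedanceEngine(_as_matrix(R))
    stat, _ = engine.stats(np.asarray(z, dtype=float)[None, :])
    null_ghc, _ = engine.null_stats(mc)
    p = _mc_pvalue(stat, null_ghc)
    return float(stat[0]), float(p[0])


def gbj(z, R, mc: MCConfig) -> tuple[float, float]:
    """Generalized Berk-Jones statistic and Monte-Carlo p-value."""
    mc.validate()
    engine = _ExceedanceEngine(_as_matrix(R))
    _, stat = engine.stats(np.asarray(z, dtype=float)[None, :])
    _, null_gbj = engine.null_stats(mc)
    p = _mc_pvalue(stat, null_gbj)
    return float(stat[0]), float(p[0])


def omnitest(z, R, mc: MCConfig) -> dict:
    """One CpG's full multi-trait row: SHom, MinP/P_ACT, GHC, GBJ, omnibus."""
    z = np.asarray(z, dtype=float)
    Rm = _as_matrix(R)
    shom_stat, shom_p = shom(z, Rm)
    minp_raw, pact_p = minp_pact(z, Rm)
    ghc_stat, ghc_p = ghc(z, Rm, mc)
    gbj_stat, gbj_p = gbj(z, Rm, mc)
    omni_p = acat([pact_p, gbj_p, ghc_p])
    return {
        "shom_stat": shom_stat,
        "shom_p": shom_p,
        "minp_raw": minp_raw,
        "pact_p": pact_p,
        "ghc_stat": ghc_stat,
        "ghc_p": ghc_p,
        "gbj_stat": gbj_stat,
        "gbj_p": gbj_p,
        "omnitest_p": omni_p,
        "mc_draws": mc.n_draws,
        "mc_resolution": mc.resolution,
    }


def run_multitrait(
    single_trait: dict[str, pd.DataFrame], R: TraitCorr, mc: MCConfig
) -> pd.DataFrame:
    """Multi-trait statistics for every CpG common to the K single-trait tables.

    ``single_trait`` maps marker name -> EWAS summary table (cpg_id, beta,
    se); the marker order of ``R`` dictates the z-vector order.  The GHC/GBJ
    null reference distribution depends only on R, so one seeded set of
    ``mc.n_draws`` null statistics is shared by all CpGs.  Deterministic
    given ``mc.seed``.
    """
    mc.validate()
    markers = list(R.markers)
    missing = [m for m in markers if m not in single_trait]
    if missing:
        raise ValueError(f"missing single-trait tables for markers: {missing}")
    tables = []
    for m in markers:
        t = single_trait[m][["cpg_id", "beta", "se"]].dropna()
        tables.append(t.rename(columns={"beta": f"beta_{m}", "se": f"se_{m}"}))
    merged = tables[0]
    for t in tables[1:]:
        merged = merged.merge(t, on="cpg_id", how="inner")
    if merged.empty:
        raise ValueError("no CpGs shared across the single-trait tables")
    Z = np.column_stack(
        [
            merged[f"beta_{m}"].to_numpy(float) / merged[f"se_{m}"].to_numpy(float)
            for m in markers
        ]
    )
    Rm = _check_pd(R.matrix)
    shom_stat, shom_p = shom_many(Z, Rm)
    minp_raw, pact_p = minp_pact_many(Z, Rm)
    engine = _ExceedanceEngine(Rm)
    ghc_stat, gbj_stat = engine.stats(Z)
    null_ghc, null_gbj = engine.null_stats(mc)
    ghc_p = _mc_pvalue(ghc_stat, null_ghc)
    gbj_p = _mc_pvalue(gbj_stat, null_gbj)
    comp = np.column_stack([pact_p, gbj_p, ghc_p])
    omni_p = np.array([acat(row) for row in comp])
    return pd.DataFrame(
        {
            "cpg_id": merged["cpg_id"],
            "shom_stat": shom_stat,
            "shom_p": shom_p,
            "minp_raw": minp_raw,
            "pact_p": pact_p,
            "ghc_stat": ghc_stat,
            "ghc_p": ghc_p,
            "gbj_stat": gbj_stat,
            "gbj_p": gbj_p,
            "omnitest_p": omni_p,
            "mc_draws": mc.n_draws,
            "mc_seed": mc.seed,
        }
    )


def overlap_summary(
    sets: list[SignificanceSet], single_trait_labels: list[str] | None = None
) -> dict:
    """Pairwise intersection counts and per-multi-trait-set novelty counts.

    ``single_trait_labels`` names the sets that count as single-trait
    analyses; a multi-trait set member found in none of them is "novel".
    """
    members = {s.label: set(s.cpg_ids) for s in sets}
    labels = [s.label for s in sets]
    pairwise = pd.DataFrame(
        [[len(members[a] & members[b]) for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    single_labels = single_trait_labels or []
    single_union: set = set()
    for lab in single_labels:
        single_union |= members.get(lab, set())
    novel = {
        lab: len(members[lab] - single_union)
        for lab in labels
        if lab not in single_labels
    }
    return {"pairwise": pairwise, "novel": novel, "single_trait_union": len(single_union)}
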