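"""Reusable simulation experiments: null calibration, power/novelty, recovery.

These are the package's standard evaluation scenarios, shared by the test
suite and the acceptance script.  Problem sizes default to desk-scale
settings (thousands of CpGs, a few hundred samples per platform) chosen so a
full experiment runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from mtewas.ewas import fit_cpg_lmm, genomic_inflation, run_ewas
from mtewas.meta import fisher_combine_frame, meta_single_trait, significant_set
from mtewas.multitrait import MCConfig, run_multitrait
from mtewas.preprocess import estimate_trait_correlation
from mtewas.synthetic import MARKERS, SimConfig, generate_cohort


def _covariates(pheno):
    return (
        ["age"]
        + [c for c in pheno.columns if c.startswith("covariate_")]
        + [c for c in pheno.columns if c.startswith("celltype_") and c != "celltype_gran"]
    )


def null_calibration(
    seed: int,
    m_cpgs: int = 2000,
    n_samples: int = 400,
    rho: float = 0.4,
    mc_draws: int = 20_000,
) -> dict:
    """Type-I error and genomic inflation under a fully null cohort.

    One platform, equicorrelated marker target, no planted effects.  Returns
    empirical rejection rates at alpha = 0.05 and per-analysis lambdas.
    """
    target = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
    cfg = SimConfig(
        n_samples_per_platform=n_samples,
        n_cpgs_platform1=m_cpgs,
        n_cpgs_platform2=8,
        n_cpgs_shared=8,
        effect_classes={"null": 1.0},
        trait_corr_target=target,
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    ph = cohort.pheno[cohort.pheno["platform"] == "p1"].reset_index(drop=True)
    covs = _covariates(ph)
    tables = {m: run_ewas(cohort.beta_platform1, ph, m, covs) for m in MARKERS}
    corr = estimate_trait_correlation(ph)
    mt = run_multitrait(tables, corr, MCConfig(n_draws=mc_draws, seed=seed))
    out = {"m_cpgs": m_cpgs, "n_samples": n_samples}
    for name, col in (("shom", "shom_p"), ("pact", "pact_p"), ("omnitest", "omnitest_p")):
        out[f"type1_{name}_at_0.05"] = float((mt[col] < 0.05).mean())
        out[f"lambda_{name}"] = genomic_inflation(mt[col])
    for m in MARKERS:
        out[f"lambda_ewas_{m}"] = genomic_inflation(tables[m]["p"])
    return out


def power_novelty(
    seed: int,
    m_cpgs: int = 600,
    n_samples: int = 400,
    shared_frac: float = 0.05,
    effect_size: float = 0.035,
    mc_draws: int = 20_000,
) -> dict:
    """Two-platform run with shared effects planted at the single-trait
    detection boundary; compares single- and multi-trait discovery sets.

    The effect size default places the expected per-marker meta |z| at the
    shared-panel Bonferroni threshold, the regime in which multi-trait
    analysis can find sites that no single-trait analysis does.
    """
    cfg = SimConfig(
        n_samples_per_platform=n_samples,
        n_cpgs_platform1=m_cpgs,
        n_cpgs_platform2=m_cpgs,
        n_cpgs_shared=m_cpgs,
        effect_classes={"null": 1.0 - shared_frac, "shared": shared_frac},
        effect_size_scale=effect_size,
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    res = {}
    corrs = {}
    for bm in (cohort.beta_platform1, cohort.beta_platform2):
        ph = cohort.pheno[cohort.pheno["platform"] == bm.platform].reset_index(drop=True)
        covs = _covariates(ph)
        res[bm.platform] = {m: run_ewas(bm, ph, m, covs) for m in MARKERS}
        corrs[bm.platform] = estimate_trait_correlation(ph)

    single_union: set = set()
    single_counts = {}
    for m in MARKERS:
        found: set = set()
        for p in ("p1", "p2"):
            found |= set(significant_set(res[p][m], "p", label=f"{m}_{p}").cpg_ids)
        meta = meta_single_trait(res["p1"][m], res["p2"][m])
        meta_set = set(significant_set(meta, "p", label=f"{m}_meta").cpg_ids)
        found |= meta_set
        single_counts[m] = len(meta_set)
        single_union |= found

    mts = {
        p: run_multitrait(res[p], corrs[p], MCConfig(n_draws=mc_draws, seed=seed))
        for p in ("p1", "p2")
    }
    multi_union: set = set()
    multi_counts = {}
    for name, col in (("cpassoc", "shom_p"), ("omnitest", "omnitest_p")):
        for p in ("p1", "p2"):
            multi_union |= set(significant_set(mts[p], col, label=f"{name}_{p}").cpg_ids)
        fisher = fisher_combine_frame([mts["p1"], mts["p2"]], col)
        meta_set = set(significant_set(fisher, "fisher_p", label=f"{name}_meta").cpg_ids)
        multi_counts[name] = len(meta_set)
        multi_union |= meta_set

    planted = set(
        cohort.truth.cpg_effects.query("effect_class == 'shared'")["cpg_id"]
    )
    missed = single_union - multi_union
    return {
        "n_planted": len(planted),
        "n_single_union": len(single_union),
        "n_multi_union": len(multi_union),
        "single_meta_counts": single_counts,
        "multi_meta_counts": multi_counts,
        "single_planted": len(single_union & planted),
        "multi_planted": len(multi_union & planted),
        "strict_containment": len(missed) == 0,
        "missed_by_multi": len(missed),
        "missed_planted_by_multi": len(missed & planted),
        "novel_planted": len((multi_union - single_union) & planted),
    }


def lmm_recovery(seed: int, gamma: float = 0.02, n: int = 400, n_chips: int = 12, reps: int = 200) -> dict:
    """Bias of the REML slope estimate over replicate single-CpG fits."""
    rng = np.random.default_rng(seed)
    ests, ses = [], []
    for _ in range(reps):
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        chips = np.arange(n) % n_chips
        u = rng.normal(0, 0.2, n_chips)
        y = 0.1 + gamma * x + u[chips] + rng.normal(0, 0.4, n)
        fit = fit_cpg_lmm(y, X, chips)
        ests.append(fit.coef[1])
        ses.append(float(np.sqrt(fit.cov[1, 1])))
    bias = float(np.mean(ests) - gamma)
    return {
        "gamma_true": gamma,
        "gamma_mean_estimate": float(np.mean(ests)),
        "bias": bias,
        "bias_bound": float(2 * np.mean(ses) / np.sqrt(reps)),
        "reps": reps,
    }
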