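# mtewas

Multi-trait epigenome-wide association analysis of correlated inflammatory
markers.

## The problem

Chronic inflammation — tracked by circulating markers such as interleukin-6
(IL-6, pg/mL), soluble CD14 (sCD14, µg/mL) and D-dimer (µg/mL) — leaves a
signature in blood DNA methylation. The three markers are positively
intercorrelated and share physiology, yet a conventional EWAS regresses
methylation on one marker at a time, discarding the shared signal. Jointly
analysing the markers' summary statistics can recover CpG sites that no
single-trait scan reaches genome-wide significance for.

`mtewas` implements that joint analysis as a reusable, fully tested pipeline
for the common two-platform design: methylation assayed on two array panels
(a 450K-like and an 850K-like panel with a large common CpG subset) in
mutually exclusive subsets of the cohort, so platform-level results are
combined by meta-analysis. Because individual-level cohort data of this kind
are access-restricted, the package ships a first-class synthetic-cohort
generator that emulates the study's statistical structure (right-skewed
correlated markers, chip batch effects, covariate confounding, planted
null/shared/single-marker CpG effects) with full ground truth, so every
stage is testable end to end.

## The statistics

For each CpG `j`, marker `k` and platform, a linear mixed model on the
methylation beta value

    y_ij = x_i' b_jk + u_chip(i) + e_ij ,   u_chip ~ N(0, s²_chip)

is fit by profiled REML (chip = array batch, random intercept; age, binary
clinical covariates and blood cell-type proportions as fixed effects),
giving per-CpG summary statistics (Beta, SE, t, p). Platform results are
combined per marker by fixed-effect inverse-variance meta-analysis on the
shared panel.

The cross-phenotype layer works on the z-score vector
`z_j = (b_j1/SE_j1, …, b_jK/SE_jK)` and the markers' Pearson correlation
matrix `R` (the phenotype analogue of LD):

- **SHom (CPASSOC)** — homogeneous-effect statistic
  `S = (e'R⁻¹z)² / (e'R⁻¹e) ~ χ²₁`, a correlation-adjusted fixed-effect
  combination across traits;
- **MinP / P_ACT** — the minimum two-sided p across traits, adjusted to
  `P(min p of K correlated tests ≤ p_min)` via deterministic MVN box
  probabilities;
- **GHC / GBJ** — generalized higher criticism and generalized Berk–Jones:
  maxima over the ordered |z| thresholds of standardised exceedance counts,
  with the binomial variance replaced by the correlation-aware
  `Var_R(S(t))`; null p-values by seeded Monte Carlo;
- **OmniTest** — the aggregated Cauchy (ACAT) combination of the P_ACT, GBJ
  and GHC p-values;
- **Fisher's method** (`−2Σln p ~ χ²₂ₘ`) combines the multi-trait p-values
  across platforms.

Each analysis is Bonferroni-controlled separately at family α = 0.05 (for
374,642 shared CpGs the nominal threshold is 1.33×10⁻⁷). Discovery sets are
compared for overlap and for "novel" sites found by no single-trait
analysis. Significant CpGs feed a gene-set enrichment test that corrects
for per-gene CpG-count bias and multi-gene CpGs using Wallenius' noncentral
hypergeometric distribution with isotonic selection-probability weights.

## Worked example

```python
import numpy as np
from mtewas import (SimConfig, generate_cohort, filter_outliers,
                    estimate_trait_correlation, run_ewas, run_multitrait,
                    significant_set, MCConfig)

cfg = SimConfig(n_samples_per_platform=300,
                n_cpgs_platform1=500, n_cpgs_platform2=500, n_cpgs_shared=500,
                effect_classes={"null": 0.95, "shared": 0.05},
                effect_size_scale=0.2, seed=7)
cohort = generate_cohort(cfg)

pheno, removed = filter_outliers(cohort.pheno)          # 3-SD rule, one pass
ph1 = pheno[pheno.platform == "p1"].reset_index(drop=True)
covs = (["age"] + [c for c in ph1 if c.startswith("covariate_")]
        + [c for c in ph1 if c.startswith("celltype_") and c != "celltype_gran"])
tables = {m: run_ewas(cohort.beta_platform1, ph1, m, covs)
          for m in ("il6", "scd14", "ddimer")}
R = estimate_trait_correlation(ph1)
mt = run_multitrait(tables, R, MCConfig(n_draws=20_000, seed=7))

print(f"removed {len(removed)} marker outliers; "
      f"R il6~scd14 = {R.matrix[0,1]:.3f}")
print(f"CPASSOC hits: {len(significant_set(mt, 'shom_p', label='shom'))}, "
      f"OmniTest hits: {len(significant_set(mt, 'omnitest_p', label='omni'))}")
```

Output:

```
removed 24 marker outliers; R il6~scd14 = 0.300
CPASSOC hits: 25, OmniTest hits: 25
```

24 of 600 samples fall outside a 3-SD marker bound (log-normal tails), the
realised marker correlation sits at its 0.3 target, and at this effect size
both multi-trait tests recover all 25 planted shared-effect CpGs at the
Bonferroni threshold 0.05/500 = 1e-4.

The full workflow (simulate → QC → 3 markers × 2 platforms EWAS → meta →
CPASSOC + OmniTest → Fisher meta → significance sets → overlap/novelty →
enrichment → QQ/λ diagnostics) runs from one YAML config:

```bash
mtewas all --config config.yaml          # or: python -m mtewas.cli all ...
```

writing headered TSVs plus a machine-readable `summary.json` (counts per
analysis in the platform1/platform2/meta layout, overlaps, novel counts,
per-analysis genomic inflation factors λ, config hash and seed). Reruns of
the same config are byte-identical.

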