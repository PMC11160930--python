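# Methods

This note documents the models, numerical choices and known limitations of
`mtewas`. It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic cohorts

The generator (`mtewas.synthetic`) emulates a two-platform methylation study
of three inflammatory markers measured on the same individuals.

**Markers.** IL-6, sCD14 and D-dimer are drawn log-normal with location and
scale solved from cohort-typical medians and quartiles (IL-6 2.1
[1.4–3.4] pg/mL, sCD14 1.7 [1.4–2.1] µg/mL, D-dimer 0.3 [0.2–0.5] µg/mL),
which gives log-scale SDs of 0.66, 0.30 and 0.68. The latent-normal
correlation is back-solved analytically so the *exponentiated* variables
realise the requested Pearson correlation (default pairwise 0.3; observed
marker–marker correlations in such cohorts are not published, so 0.3 is a
configurable default, not a calibrated value). The inversion is exact: at
n = 10⁵ the realised correlations are 0.3007/0.2984/0.3008 against a 0.30
target. Note that the *sampling* SD of Pearson r for variables this skewed
is ≈0.05–0.06 at n = 500, so realised correlations at cohort-scale n
scatter well beyond the targeting error; the generator-fidelity test is
therefore run at n = 10⁴, where noise cannot mask bias.

**Covariates.** Age ~ N(51.4, 7.8²); seven binary clinical covariates with
cohort-typical prevalences; six blood cell-type proportions from a
Dirichlet centred on typical whole-blood composition. Covariates are drawn
independently of the markers; they add variance to methylation (per-CpG
coefficients drawn N(0, sd²) with sd 0.02 for age, 0.01 for binaries, 0.15
for cell types, all on the logit scale) which the EWAS adjustment removes.

**Methylation.** Per CpG, the logit of the beta value is
`μ_j + Σ_k γ_jk z(marker_k) + covariate terms + chip intercept + ε`, mapped
through the inverse logit. Baselines μ_j are a bimodal mixture
(0.35·N(−2.2,0.7) + 0.35·N(2.2,0.7) + 0.30·N(0,1)), as for real array data.
`z(·)` is the within-platform standardisation, so γ is a logit-scale shift
per marker SD. Effect classes are planted in exact counts: null, shared by
all three markers, or specific to one marker (sign random per CpG).
Chip assignment is round-robin; chip intercepts are N(0, chip_sd²) with
default 0.1, residual SD 0.35 (logit scale). Platforms share a CpG subset
but have disjoint samples, so the cross-platform meta-analysis is a genuine
two-cohort combination. One integer seed drives a `SeedSequence` tree
(phenotypes → panel → methylation → outliers); identical configs give
byte-identical cohorts.

**Default effect size.** `effect_size_scale = 0.05` was fixed from a power
calculation targeting "top-hit" strength at a ~900-sample meta-analysis.
Empirically the realised per-marker meta |z| is ≈ 110 × scale at meta
n ≈ 800–920 (the logistic compression makes effects ~35% stronger than the
linear approximation (γ/σ)√n suggests), so the default corresponds to
|z| ≈ 5.5.

**What the generator does not emulate.** Probe chemistry (Type I/II),
normalisation artifacts, genomic autocorrelation of methylation, cell-type
interactions, non-Gaussian residuals, and marker–covariate confounding.
Passing tests therefore demonstrate correctness of the statistics under the
assumed generating model, not robustness to real-data artifacts.

## QC

The marker outlier rule computes mean ± k·SD (k = 3, SD with n−1
denominator) per marker *once on the input table* and removes samples with
any marker strictly outside its bounds. The rule is deliberately not
iterated — re-applying it to its own output can remove more samples — and
the pipeline records that it ran exactly once. Whether such filters are
applied on raw or transformed marker values is often unstated in study
descriptions; raw values are used here. Complete-case filtering intersects
phenotype and methylation sample IDs and aligns matrix columns to the
phenotype row order.

The trait correlation is the Pearson matrix of raw post-QC marker values
(a covariate-residualised variant is available behind a flag for
sensitivity analysis). If an eigenvalue falls below 1e-8 the matrix is
repaired (eigenvalues floored at 1e-6, rescaled to unit diagonal) because
every downstream test needs an invertible MVN correlation.

## Per-CpG mixed model

Methylation is modelled on the beta-value scale (effect sizes are then
directly interpretable as methylation-fraction change per marker unit; an
M-value transform is a flag). The chip random intercept absorbs batch
effects; REML is profiled to the single ratio λ = s²_chip/s²_resid, and the
1-D objective is minimised by bounded Brent search on log λ over
[e⁻²³, e²³] with the λ = 0 boundary checked explicitly; at the boundary the
fit reduces *exactly* to OLS. The per-CpG solve uses the exchangeable block
structure (Woodbury via per-chip sums), so a fit costs O(G·p + p³) per
objective evaluation and an epigenome-wide scan runs at a few ms per CpG.
Degrees of freedom for the marker t-test are n − p_fixed (no Satterthwaite;
at n ≈ 300–500 per platform the distinction is numerically irrelevant, and
a test verifies t- and Gaussian-reference p-values agree to 5e-3 there).
Each CpG is fit independently — no empirical-Bayes variance moderation.

Numerical caveat: the REML optimum lies in a flat basin, so quantities that
are mathematically invariant (e.g. under marker rescaling) reproduce only
to the optimizer's effective precision (~1e-7 relative on t); the
non-iterative OLS path reproduces them to 1e-10.

## Meta-analysis and significance accounting

Fixed-effect inverse-variance weighting combines the two platforms on the
shared panel only; no heterogeneity statistics are computed (none are
needed for a two-cohort fixed-effect design, and random-effects meta is out
of scope). Fisher's method combines multi-trait p-values across platforms
with the statistic accumulated in log space; inputs are floored at 1e-300
(the documented minimum representable p). Bonferroni thresholds use strict
inequality ("less than"), and m_tests defaults to each analysis' own panel
size — platform panels for platform analyses, the shared panel for meta —
i.e. separate corrections per analysis.

## Cross-phenotype statistics

All tests consume z = beta/SE vectors (asymptotic normality of the t
statistics) and the *phenotype* Pearson matrix R — the study's substitution
for LD; a flag allows a null-z-score correlation estimate instead. All
statistics depend on z only through |z| and are invariant to consistent
trait permutation. MinP uses two-sided p-values throughout.

**SHom** uses equal trait weights: all traits are measured on the same
samples, so CPASSOC's sample-size weights cancel.

**P_ACT** needs `P(max_k |Z_k| ≥ c)` under MVN(0, R). For K ≤ 3 this is
computed deterministically: the bivariate normal CDF by Drezner–Wesolowsky
single-integral quadrature (machine precision against an independent
oracle), the trivariate symmetric box by Gauss–Legendre over the first
coordinate with the conditional bivariate box inside (absolute error well
under 1e-8, converged to ~1e-12 at the default 96/96 nodes). Once the
marginal tail drops below 1e-8 the complement `1 − box` would lose
precision, so the far tail switches to second-order inclusion–exclusion
with cancellation-free pairwise orthants
`P(Z₁≥c, Z₂≥c) = Φ̄(c)² + (1/2π)∫₀^{asin ρ} exp(−c²/(1+sin t)) dt`;
the neglected triple term is far below any usable resolution there. The
result is clipped into the provable envelope [p_min, K·p_min].

**GHC/GBJ.** With thresholds t_j the ordered |z| magnitudes (so the
exceedance count at t_j is exactly j; ties cannot change the max over
thresholds at K = 3, which a test asserts), GHC maximises
`(j − K·2Φ̄(t_j)) / sqrt(Var_R S(t_j))` where
`Var_R = K q(1−q) + Σ_{i≠j} [P(|Z_i|≥t, |Z_j|≥t; ρ_ij) − q²]`, q = 2Φ̄(t),
with the orthant terms computed by the exact formula above. GBJ uses the
independence Berk–Jones log-likelihood-ratio score
`2[j ln(j/(Kq)) + (K−j) ln((K−j)/(K(1−q)))]` (when j > Kq, else 0;
0·ln 0 ≡ 0), generalised by an overdispersion match: the score is scaled by
`Var_binomial/Var_R`. At R = I both reduce *exactly* to classic HC/BJ
(asserted against hand enumeration).

**Monte-Carlo p-values.** GHC/GBJ null distributions are resolved by seeded
MVN(0, R) simulation with the add-one estimator p = (r+1)/(B+1),
B ≥ 10⁴, resolution floor 1/(B+1) reported with every p-value. The null law
depends only on R, so one reference set of B statistics is shared by all
CpGs in a run — statistically identical to per-CpG draws and B-fold
cheaper. The analytic crossing-probability recursions of the original
methods are deliberately not implemented: at K = 3 the MC oracle is
exact-in-distribution, fast and directly testable. Fisher combinations of
MC p-values inherit the floor. The `antithetic` flag mirrors draws, which
is a no-op for these |z|-even statistics and exists for API completeness.

**OmniTest** is the equal-weight ACAT of (P_ACT, GBJ, GHC) p-values, with
tangents replaced by the asymptote 1/(πp) below 1e-15 and inputs clipped to
[1e-300, 1−1e-16]. ACAT is accurate in the tail but mildly conservative in
the distribution centre; its genomic λ on null data sits around 0.95, which
is visible in QQ diagnostics and harmless for discovery.

## Enrichment

Gene-level testing: a gene is selected if any significant CpG maps to it
(multi-gene CpGs credit every gene). Per-gene selection probability under
the null grows with the gene's CpG count; it is estimated by isotonic
regression of the selection indicator on the universe CpG count (with few
distinct counts, isotonic regression on tied values is identical to a
monotone fit of binned means, so one code path serves both). A term's odds
is mean in-term weight over mean out-of-term weight, and the p-value is the
Wallenius noncentral hypergeometric upper tail at the observed in-term
selected count, with masses computed by adaptive quadrature of the standard
integral representation (masses must sum to 1 within 1e-8, asserted at run
time; odds = 1 falls back to the exact central hypergeometric). Note the
direction: larger in-term odds makes a fixed overlap *less* surprising, so
the upper-tail p is non-decreasing in odds. FDR across terms is
Benjamini–Hochberg; reports default to q < 0.05. No GO database is bundled;
term maps are supplied (or generated) as plain tables.

## Pipeline

One YAML config drives all stages; every output TSV carries `# key=value`
headers with the config hash and seed, floats are printed at 10 significant
digits, and reruns are byte-identical. Stages communicate through files, so
the CLI subcommands (`simulate`, `qc`, `ewas`, `meta`, `multitrait`,
`enrich`, `diagnostics`, `all`) and `run_all` share one contract; a stage
failure aborts with the stage named, retaining partial outputs. The
default covariate list drops one cell-type proportion (the granulocyte
fraction, the largest) because the proportions sum to one and would
otherwise alias the intercept. QQ plots use expected quantiles (i−0.5)/n;
λ is the median observed χ²₁ quantile over 0.4549.

## Evaluation scenarios and problem sizes

The standard experiments (`mtewas.experiments`) use desk-scale sizes chosen
so each runs in minutes on one CPU: null calibration at M = 2000 CpGs,
n = 400, equicorrelated markers ρ = 0.4; the power/novelty experiment at
M = 600 shared CpGs, n = 400 per platform, 5% shared effects planted at
`effect_size_scale = 0.035` — the single-trait detection boundary
(threshold z at 0.05/600 is 3.94 ≈ 110 × 0.035), because "found by the
multi-trait analysis but by no single-trait analysis" is by construction a
boundary phenomenon; and 200-replicate parameter recovery at n = 400,
12 chips.

A structural point these experiments expose: a multi-trait test cannot
uniformly dominate every single-trait test. A borderline single-trait
discovery whose sibling z-scores are weak is diluted by SHom, pays a
factor ≈ K in MinP/P_ACT and a further averaging cost in ACAT, so strict
containment of all single-trait discoveries in the multi-trait sets fails
with appreciable probability — as does containment of single-trait *false
positives*, which a calibrated multi-trait test rightly does not replicate.
The attainable, and tested, claims are: multi-trait planted-detection
counts at least match every single-trait analysis, and multi-trait analysis
finds planted CpGs that no single-trait analysis does.

## Known limitations

- K > 3 traits would need a general MVN box-probability routine (the
  deterministic quadrature is implemented for K ≤ 3).
- GHC/GBJ p-values are Monte-Carlo-resolved; p-values below 1/(B+1) are
  reported at the floor, so extreme multi-trait metas are driven by the
  analytic P_ACT component.
- Fixed-effect meta only; no heterogeneity or random-effects options.
- The LMM assumes a single random intercept; no random slopes, no spatial
  correlation between CpGs, no variance shrinkage across CpGs.
- SHet (the heterogeneous-effect CPASSOC statistic) is not implemented;
  the homogeneous-effect test is the one used here.
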