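"""Seeded synthetic cohorts with the structure the multi-trait EWAS assumes.

The generator emulates a two-platform methylation study of three positively
intercorrelated, right-skewed inflammatory markers measured on the same
individuals: log-normal markers whose latent correlation is back-solved so the
realised Pearson correlations hit a target, independently drawn covariates
(age, binary clinical flags, blood cell-type proportions), round-robin chip
assignment with chip-level random intercepts, and methylation generated on the
logit scale with planted per-CpG effects that are null, shared by all three
markers, or specific to a single marker.  The two platforms share a common
CpG subset but have mutually exclusive samples, so cross-platform
meta-analysis is a genuine two-cohort combination.  Ground truth (effect
class, per-marker coefficients, chip intercepts) is returned alongside the
data.

Default marker location/scale parameters reproduce the medians and quartiles
typical of IL-6 (pg/mL), sCD14 (ug/mL) and D-dimer (ug/mL) in an HIV-positive
male cohort; all randomness flows from one integer seed through a
hierarchical `SeedSequence` tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

MARKERS = ("il6", "scd14", "ddimer")

# log-normal (mu, sigma) per marker, solved from median and quartiles
# median m -> mu = ln m; sigma = (ln q3 - ln q1) / (2 * 0.67449)
_MARKER_LOGNORM = {
    "il6": (np.log(2.1), (np.log(3.4) - np.log(1.4)) / (2 * 0.6744898)),
    "scd14": (np.log(1.7), (np.log(2.1) - np.log(1.4)) / (2 * 0.6744898)),
    "ddimer": (np.log(0.3), (np.log(0.5) - np.log(0.2)) / (2 * 0.6744898)),
}

_BINARY_COVARIATES = {
    "art": 0.834,
    "suppressed_vl": 0.535,
    "hcv": 0.418,
    "hbv": 0.096,
    "diabetes": 0.183,
    "smoking": 0.558,
    "alcohol": 0.604,
}

_CELLTYPES = ("cd4", "cd8", "nk", "b", "mono", "gran")
_CELLTYPE_MEANS = np.array([0.12, 0.09, 0.03, 0.04, 0.08, 0.64])

EFFECT_CLASSES = ("null", "shared", "single_il6", "single_scd14", "single_ddimer")


def _default_corr() -> np.ndarray:
    return np.full((3, 3), 0.3) + 0.7 * np.eye(3)


def _default_fracs() -> dict:
    return {"null": 0.94, "shared": 0.03, "single_il6": 0.01, "single_scd14": 0.01, "single_ddimer": 0.01}


def _default_cov_sd() -> dict:
    return {"age": 0.02, "binary": 0.01, "celltype": 0.15}


@dataclass
class SimConfig:
    """All knobs of the cohort generator.

    Effect sizes are logit-scale methylation shifts per standard deviation of
    the marker; ``chip_sd`` and ``residual_sd`` are logit-scale standard
    deviations of the chip random intercept and residual noise.
    """

    n_samples_per_platform: int = 460
    n_cpgs_platform1: int = 1200
    n_cpgs_platform2: int = 1400
    n_cpgs_shared: int = 1000
    n_chips: int = 12
    trait_corr_target: np.ndarray = field(default_factory=_default_corr)
    effect_classes: dict = field(default_factory=_default_fracs)
    effect_size_scale: float = 0.05
    chip_sd: float = 0.1
    residual_sd: float = 0.35
    covariate_effects: dict = field(default_factory=_default_cov_sd)
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML parses a bare `null` mapping key as None; normalise it back
        self.effect_classes = {
            ("null" if k is None else str(k)): float(v) for k, v in self.effect_classes.items()
        }

    def validate(self) -> None:
        if self.n_samples_per_platform < 1 or self.n_chips < 1:
            raise ValueError("sample and chip counts must be positive")
        if self.n_cpgs_shared > min(self.n_cpgs_platform1, self.n_cpgs_platform2):
            raise ValueError("n_cpgs_shared exceeds a platform panel size")
        target = np.asarray(self.trait_corr_target, dtype=float)
        if target.shape != (3, 3) or not np.allclose(target, target.T):
            raise ValueError("trait_corr_target must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(target), 1.0):
            raise ValueError("trait_corr_target must have unit diagonal")
        if np.linalg.eigvalsh(target).min() <= 0:
            raise ValueError("trait_corr_target is not positive definite")
        total = sum(self.effect_classes.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"effect class fractions must sum to 1, got {total}")
        unknown = set(self.effect_classes) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        if self.chip_sd < 0 or self.residual_sd < 0 or self.outlier_rate < 0 or self.outlier_rate >= 1:
            raise ValueError("chip_sd/residual_sd must be >= 0 and 0 <= outlier_rate < 1")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort."""

    cpg_effects: pd.DataFrame  # cpg_id, effect_class, gamma_<marker> (logit scale per marker SD)
    chip_intercepts: pd.DataFrame  # platform, chip_id, intercept
    outlier_ids: list


class Cohort(NamedTuple):
    pheno: pd.DataFrame
    beta_platform1: "BetaMatrix"
    beta_platform2: "BetaMatrix"
    truth: SimTruth


@dataclass
class BetaMatrix:
    """CpG x sample methylation beta values plus per-CpG annotation."""

    values: pd.DataFrame  # index cpg_id, columns sample_id, entries in (0,1)
    annotation: pd.DataFrame  # cpg_id, chr, pos_1based, gene (semicolon list)
    platform: str

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _latent_corr_from_target(target: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Latent-normal correlation whose exponentiated variables realise `target`.

    For X_i = exp(mu_i + sigma_i Z_i) with corr(Z_i, Z_j) = rho,
    corr(X_i, X_j) = (exp(sigma_i sigma_j rho) - 1) /
                     sqrt((exp(sigma_i^2)-1)(exp(sigma_j^2)-1)),
    inverted here for rho.
    """
    k = len(sigmas)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(np.expm1(sigmas[i] ** 2) * np.expm1(sigmas[j] ** 2))
            rho = np.log1p(target[i, j] * denom) / (sigmas[i] * sigmas[j])
            latent[i, j] = latent[j, i] = np.clip(rho, -0.999, 0.999)
    evals = np.linalg.eigvalsh(latent)
    if evals.min() < 1e-8:  # repair rarely needed for modest targets
        vals, vecs = np.linalg.eigh(latent)
        vals = np.maximum(vals, 1e-6)
        latent = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    return latent


def _assign_effect_classes(n: int, fracs: dict, rng: np.random.Generator) -> np.ndarray:
    """Exact planted counts: round(frac * n) per class, remainder to 'null'."""
    counts = {cls: int(round(fracs.get(cls, 0.0) * n)) for cls in EFFECT_CLASSES if cls != "null"}
    n_effect = sum(counts.values())
    if n_effect > n:
        raise ValueError("effect fractions imply more planted CpGs than available")
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for cls in EFFECT_CLASSES:
        if cls == "null":
            continue
        labels[order[pos : pos + counts[cls]]] = cls
        pos += counts[cls]
    return labels


def _make_annotation(cpg_ids: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    n = len(cpg_ids)
    chrom = rng.integers(1, 23, size=n)
    pos = rng.integers(10_000, 50_000_000, size=n)
    gene_idx = np.arange(n) // 5
    genes = np.array([f"GENE{g:05d}" for g in gene_idx], dtype=object)
    # ~10% of CpGs map to a second (neighbouring) gene
    multi = rng.random(n) < 0.10
    for i in np.where(multi)[0]:
        genes[i] = f"{genes[i]};GENE{gene_idx[i] + 1:05d}"
    return pd.DataFrame(
        {"cpg_id": list(cpg_ids), "chr": chrom, "pos_1based": pos, "gene": genes}
    )


def _simulate_pheno(
    config: SimConfig, platform: str, latent_corr: np.ndarray, seq: np.random.SeedSequence
) -> pd.DataFrame:
    rng = np.random.default_rng(seq)
    n = config.n_samples_per_platform
    mus = np.array([_MARKER_LOGNORM[m][0] for m in MARKERS])
    sigmas = np.array([_MARKER_LOGNORM[m][1] for m in MARKERS])
    latent = rng.multivariate_normal(np.zeros(3), latent_corr, size=n, method="cholesky")
    markers = np.exp(mus + sigmas * latent)
    data = {"sample_id": [f"{platform}_s{i:04d}" for i in range(n)]}
    for k, m in enumerate(MARKERS):
        data[m] = markers[:, k]
    data["age"] = rng.normal(51.4, 7.8, size=n)
    for name, prev in _BINARY_COVARIATES.items():
        data[f"covariate_{name}"] = (rng.random(n) < prev).astype(int)
    cellprops = rng.dirichlet(_CELLTYPE_MEANS * 40.0, size=n)
    for j, ct in enumerate(_CELLTYPES):
        data[f"celltype_{ct}"] = cellprops[:, j]
    df = pd.DataFrame(data)
    df["chip_id"] = [f"{platform}_chip{(i % config.n_chips):02d}" for i in range(n)]
    df["platform"] = platform
    return df


def _covariate_design(pheno: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Standardised covariate matrix used when generating methylation."""
    cols = ["age"] + [c for c in pheno.columns if c.startswith(("covariate_", "celltype_"))]
    mat = pheno[cols].to_numpy(dtype=float)
    mat = mat - mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return mat / sd, cols


def _cov_effect_sd(col: str, effects: dict) -> float:
    if col in effects:
        return float(effects[col])
    if col == "age":
        return float(effects.get("age", 0.0))
    if col.startswith("celltype_"):
        return float(effects.get("celltype", 0.0))
    return float(effects.get("binary", 0.0))


def _simulate_methylation(
    config: SimConfig,
    pheno: pd.DataFrame,
    cpg_ids: Sequence[str],
    baselines: np.ndarray,
    gammas: np.ndarray,
    cov_coefs: np.ndarray,
    cov_cols: list[str],
    platform: str,
    seq: np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(seq)
    n = len(pheno)
    m = len(cpg_ids)
    z = pheno[list(MARKERS)].to_numpy(dtype=float)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)  # within-cohort standardisation
    cov_mat, cols = _covariate_design(pheno)
    assert cols == cov_cols
    chips = sorted(pheno["chip_id"].unique())
    chip_u = rng.normal(0.0, config.chip_sd, size=len(chips))
    chip_map = dict(zip(chips, chip_u))
    chip_vec = pheno["chip_id"].map(chip_map).to_numpy()
    noise = rng.normal(0.0, config.residual_sd, size=(m, n))
    logit = baselines[:, None] + gammas @ z.T + cov_coefs @ cov_mat.T + chip_vec[None, :] + noise
    beta = 1.0 / (1.0 + np.exp(-logit))
    eps = 1e-9  # keep strictly inside (0, 1)
    beta = np.clip(beta, eps, 1.0 - eps)
    values = pd.DataFrame(beta, index=pd.Index(cpg_ids, name="cpg_id"), columns=pheno["sample_id"])
    intercepts = pd.DataFrame(
        {"platform": platform, "chip_id": chips, "intercept": chip_u}
    )
    return values, intercepts


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full two-platform cohort with ground truth.

    Returns phenotypes for both platforms stacked in one table (the platform
    of each sample is recorded in a ``platform`` column and implied by the
    beta-matrix sample columns), one :class:`BetaMatrix` per platform, and a
    :class:`SimTruth` record.  Byte-identical output for identical configs.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (s_pheno1, s_pheno2, s_panel, s_meth1, s_meth2, s_outlier) = root.spawn(6)

    sigmas = np.array([_MARKER_LOGNORM[m][1] for m in MARKERS])
    latent_corr = _latent_corr_from_target(np.asarray(config.trait_corr_target, float), sigmas)
    pheno1 = _simulate_pheno(config, "p1", latent_corr, s_pheno1)
    pheno2 = _simulate_pheno(config, "p2", latent_corr, s_pheno2)

    # union CpG panel: shared block first, then platform-specific blocks
    n1, n2, ns = config.n_cpgs_platform1, config.n_cpgs_platform2, config.n_cpgs_shared
    n_union = n1 + n2 - ns
    union_ids = [f"cg{i:07d}" for i in range(n_union)]
    ids1 = union_ids[:ns] + union_ids[ns:n1]
    ids2 = union_ids[:ns] + union_ids[n1:]

    rng_panel = np.random.default_rng(s_panel)
    labels = _assign_effect_classes(n_union, config.effect_classes, rng_panel)
    gammas = np.zeros((n_union, 3))
    signs = rng_panel.choice([-1.0, 1.0], size=n_union)
    for j, lab in enumerate(labels):
        if lab == "shared":
            gammas[j, :] = signs[j] * config.effect_size_scale
        elif lab.startswith("single_"):
            gammas[j, MARKERS.index(lab.removeprefix("single_"))] = signs[j] * config.effect_size_scale
    # bimodal logit baselines, as for real array beta values
    comp = rng_panel.choice(3, size=n_union, p=[0.35, 0.35, 0.30])
    base_mu = np.array([-2.2, 2.2, 0.0])[comp]
    base_sd = np.array([0.7, 0.7, 1.0])[comp]
    baselines = rng_panel.normal(base_mu, base_sd)
    annotation = _make_annotation(union_ids, rng_panel)
    _, cov_cols = _covariate_design(pheno1)
    cov_coefs = np.column_stack(
        [
            rng_panel.normal(0.0, _cov_effect_sd(c, config.covariate_effects), size=n_union)
            for c in cov_cols
        ]
    )

    idx1 = list(range(n1))
    idx2 = list(range(ns)) + list(range(n1, n_union))
    values1, chips1 = _simulate_methylation(
        config, pheno1, ids1, baselines[idx1], gammas[idx1], cov_coefs[idx1], cov_cols, "p1", s_meth1
    )
    values2, chips2 = _simulate_methylation(
        config, pheno2, ids2, baselines[idx2], gammas[idx2], cov_coefs[idx2], cov_cols, "p2", s_meth2
    )

    pheno = pd.concat([pheno1, pheno2], ignore_index=True)
    outlier_ids: list = []
    if config.outlier_rate > 0:
        pheno, outlier_ids = inject_outliers(
            pheno, config.outlier_rate, config.outlier_magnitude_sd, seed=s_outlier
        )

    effects = pd.DataFrame(
        {
            "cpg_id": union_ids,
            "effect_class": labels,
            **{f"gamma_{m}": gammas[:, k] for k, m in enumerate(MARKERS)},
        }
    )
    truth = SimTruth(
        cpg_effects=effects,
        chip_intercepts=pd.concat([chips1, chips2], ignore_index=True),
        outlier_ids=outlier_ids,
    )
    ann1 = annotation.iloc[idx1].reset_index(drop=True)
    ann2 = annotation.iloc[idx2].reset_index(drop=True)
    return Cohort(
        pheno=pheno,
        beta_platform1=BetaMatrix(values=values1, annotation=ann1, platform="p1"),
        beta_platform2=BetaMatrix(values=values2, annotation=ann2, platform="p2"),
        truth=truth,
    )


def inject_outliers(
    pheno: pd.DataFrame, rate: float, magnitude_sd: float, seed=0
) -> tuple[pd.DataFrame, list]:
    """Shift one marker of a seeded fraction of samples far out of range.

    Returns the modified table (a copy; modified sample ids also recorded in
    ``df.attrs['outlier_ids']``) and the list of modified sample ids.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must satisfy 0 <= rate < 1")
    out = pheno.copy()
    n_mod = int(round(rate * len(pheno)))
    if n_mod == 0:
        out.attrs["outlier_ids"] = []
        return out, []
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(pheno), size=n_mod, replace=False)
    markers = rng.choice(len(MARKERS), size=n_mod)
    ids = []
    for row, mk in zip(rows, markers):
        col = MARKERS[mk]
        sd = pheno[col].std(ddof=1)
        out.iloc[row, out.columns.get_loc(col)] += magnitude_sd * sd
        ids.append(out.iloc[row]["sample_id"])
    out.attrs["outlier_ids"] = ids
    return out, ids


def generate_gene_sets(
    annotation: pd.DataFrame,
    n_terms: int = 40,
    term_size: tuple[int, int] = (5, 40),
    seed: int = 0,
    enriched_genes: Sequence[str] | None = None,
    enriched_frac: float = 0.8,
) -> pd.DataFrame:
    """Random gene -> term map for enrichment testing.

    If ``enriched_genes`` is given, the first term (``TERM0000``) is seeded
    with a fraction of those genes so that a planted enrichment exists.
    Returns a long table (term_id, gene).
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for entry in annotation["gene"] for g in str(entry).split(";")})
    rows = []
    start = 0
    if enriched_genes:
        hits = [g for g in enriched_genes if g in set(genes)]
        take = max(1, int(round(enriched_frac * len(hits))))
        chosen = list(rng.choice(hits, size=min(take, len(hits)), replace=False))
        n_fill = max(0, rng.integers(*term_size) - len(chosen))
        fillers = list(rng.choice(genes, size=n_fill, replace=False))
        for g in sorted(set(chosen + fillers)):
            rows.append(("TERM0000", g))
        start = 1
    for t in range(start, n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            rows.append((f"TERM{t:04d}", g))
    return pd.DataFrame(rows, columns=["term_id", "gene"])
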