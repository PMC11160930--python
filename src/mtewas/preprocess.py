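"""Sample-level QC and estimation of the marker correlation structure.

Two QC steps mirror the study design: a single-pass 3-standard-deviation
outlier rule on the raw marker values (a sample is dropped if any marker lies
strictly outside mean +/- k*SD computed on the input table), and complete-case
restriction to samples with phenotype, covariates and methylation all present.
The Pearson correlation matrix of the (post-QC) raw marker values is the
correlation structure consumed by every multi-trait statistic; it is repaired
to positive definiteness if necessary because those statistics require an
invertible MVN correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mtewas.synthetic import MARKERS, BetaMatrix


@dataclass
class TraitCorr:
    """K x K Pearson correlation matrix of the markers, with marker order."""

    matrix: np.ndarray
    markers: tuple = field(default_factory=lambda: MARKERS)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.markers)
        if self.matrix.shape != (k, k):
            raise ValueError("correlation matrix shape does not match marker list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.matrix).min() <= 1e-8:
            raise ValueError("correlation matrix is not positive definite")


def filter_outliers(
    pheno: pd.DataFrame, k_sd: float = 3.0, markers=MARKERS
) -> tuple[pd.DataFrame, list]:
    """Remove samples with any marker strictly outside mean +/- k_sd * SD.

    Bounds are computed once on the input table (no re-iteration; applying
    the filter twice can remove more samples and the pipeline never does).
    SD uses the n-1 denominator.  A zero-variance marker removes nobody.
    """
    if len(pheno) < 2:
        raise ValueError("need at least 2 samples to estimate outlier bounds")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    mask = np.zeros(len(pheno), dtype=bool)
    for m in markers:
        vals = pheno[m].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        mean = vals.mean()
        mask |= (vals < mean - k_sd * sd) | (vals > mean + k_sd * sd)
    removed = pheno.loc[mask, "sample_id"].tolist()
    return pheno.loc[~mask].reset_index(drop=True), removed


def complete_cases(
    pheno: pd.DataFrame, beta: BetaMatrix
) -> tuple[pd.DataFrame, BetaMatrix]:
    """Intersect sample ids, drop rows with missing values, align columns.

    The returned beta matrix has its sample columns reordered to the
    phenotype row order so downstream model fits can align by position.
    """
    keep = pheno.dropna()
    shared = [s for s in keep["sample_id"] if s in set(beta.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between phenotype table and beta matrix")
    out_pheno = keep[keep["sample_id"].isin(shared)].reset_index(drop=True)
    out_values = beta.values[out_pheno["sample_id"].tolist()]
    return out_pheno, BetaMatrix(values=out_values, annotation=beta.annotation, platform=beta.platform)


def estimate_trait_correlation(
    pheno: pd.DataFrame,
    markers=MARKERS,
    residualize: bool = False,
    covariates: list | None = None,
) -> TraitCorr:
    """Pearson correlation of the raw marker values (post outlier filter).

    ``residualize=True`` correlates covariate-adjusted residuals instead (a
    sensitivity option; the primary analysis uses raw values).  If the
    estimate has an eigenvalue below 1e-8 it is repaired by flooring the
    eigenvalues at 1e-6 and rescaling to unit diagonal, with a warning —
    the downstream tests need a valid, invertible MVN correlation.
    """
    if len(pheno) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    vals = pheno[list(markers)].to_numpy(dtype=float)
    for j, m in enumerate(markers):
        if vals[:, j].std(ddof=1) == 0:
            raise ValueError(f"marker '{m}' is constant; correlation undefined")
    if residualize:
        cols = covariates or [
            c for c in pheno.columns if c == "age" or c.startswith(("covariate_", "celltype_"))
        ]
        design = np.column_stack([np.ones(len(pheno)), pheno[cols].to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
        vals = vals - design @ coef
    corr = np.corrcoef(vals, rowvar=False)
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < 1e-8:
        warnings.warn(
            "marker correlation matrix is numerically singular; "
            "flooring eigenvalues at 1e-6 and rescaling to unit diagonal",
            stacklevel=2,
        )
        vals_, vecs = np.linalg.eigh(corr)
        vals_ = np.maximum(vals_, 1e-6)
        corr = vecs @ np.diag(vals_) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
    return TraitCorr(matrix=corr, markers=tuple(markers))
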