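"""Per-CpG single-marker EWAS via a linear mixed model with a chip random intercept.

Model, per CpG j:  methylation beta value  y_i = x_i' b + u_{chip(i)} + e_i,
u_chip ~ N(0, s2_chip), e ~ N(0, s2_resid).  Variance components are estimated
by REML profiled down to the single ratio lambda = s2_chip / s2_resid; the
one-dimensional profiled objective is optimised by bounded Brent search on
log(lambda) to relative tolerance 1e-8 with the boundary lambda = 0 allowed,
at which the fit reduces exactly to ordinary least squares.  Fixed effects are
generalized least squares at the estimated components; the marker term's
two-sided p-value uses a t reference with n - p_fixed degrees of freedom.

The per-CpG solve exploits the exchangeable block structure of the chip
covariance (Woodbury identity via per-chip sums), so an epigenome-wide scan is
a few milliseconds per CpG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from scipy.stats import t as t_dist

from mtewas.synthetic import BetaMatrix

logger = logging.getLogger(__name__)

_CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # 0.45493642...
_LOG_LAMBDA_BOUNDS = (-23.0, 23.0)


@dataclass
class CpGFit:
    """REML fit of one CpG: fixed effects, their covariance, variance components."""

    coef: np.ndarray
    cov: np.ndarray
    sigma2_chip: float
    sigma2_resid: float
    loglik: float
    converged: bool
    df_resid: int


class _LMMWorkspace:
    """Design-side precomputations shared by every CpG fit on one cohort."""

    def __init__(self, design: np.ndarray, chip_codes: np.ndarray):
        self.X = np.asarray(design, dtype=float)
        n, p = self.X.shape
        rank = np.linalg.matrix_rank(self.X)
        if rank < p:
            # identify aliased columns by QR pivoting
            _, r = np.linalg.qr(self.X)
            diag = np.abs(np.diag(r))
            aliased = [int(i) for i in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
        self.n, self.p = n, p
        codes = np.asarray(chip_codes)
        self.order = np.argsort(codes, kind="stable")
        sorted_codes = codes[self.order]
        boundaries = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
        self.reduce_idx = boundaries
        self.group_sizes = np.diff(np.r_[boundaries, n]).astype(float)
        self.n_groups = len(boundaries)
        Xs = self.X[self.order]
        self.Xs = Xs
        self.XtX = self.X.T @ self.X
        self.SX = np.add.reduceat(Xs, boundaries, axis=0)  # per-chip column sums (G x p)

    def y_stats(self, y: np.ndarray):
        ys = y[self.order]
        return self.X.T @ y, float(y @ y), np.add.reduceat(ys, self.reduce_idx)


def _neg2_reml(lam: float, ws: _LMMWorkspace, Xty, yty, Sy):
    ng = ws.group_sizes
    cg = lam / (1.0 + lam * ng)
    A = ws.XtX - (ws.SX.T * cg) @ ws.SX
    b = Xty - ws.SX.T @ (cg * Sy)
    q = yty - float(cg @ (Sy * Sy))
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(L.T, np.linalg.solve(L, b))
    rss = max(q - float(b @ beta), 1e-300)
    dof = ws.n - ws.p
    sigma2 = rss / dof
    logdet_v0 = float(np.log1p(lam * ng).sum())
    logdet_a = 2.0 * float(np.log(np.diag(L)).sum())
    neg2 = dof * np.log(sigma2) + logdet_v0 + logdet_a
    return neg2, (beta, A, sigma2, logdet_v0, logdet_a)


def fit_cpg_lmm(y: np.ndarray, design: np.ndarray, chip: np.ndarray) -> CpGFit:
    """REML fit of a single random-intercept (chip) linear mixed model.

    Parameters are the methylation vector, the fixed-effect design matrix
    (including the intercept), and the chip grouping labels.  With fewer than
    two chips the model degenerates and the fit falls back to OLS with a
    logged warning.
    """
    y = np.asarray(y, dtype=float)
    chip = np.asarray(chip)
    if len(np.unique(chip)) < 2:
        logger.warning("fewer than 2 chips; falling back to ordinary least squares")
        chip = np.zeros(len(y), dtype=int)
        ws = _LMMWorkspace(design, chip)
        return _finalise(ws, *ws.y_stats(y), lam=0.0, converged=True)
    ws = _LMMWorkspace(design, chip)
    return _fit_with_workspace(ws, y)


def _fit_with_workspace(ws: _LMMWorkspace, y: np.ndarray) -> CpGFit:
    Xty, yty, Sy = ws.y_stats(y)

    def objective(log_lam):
        val, _ = _neg2_reml(np.exp(log_lam), ws, Xty, yty, Sy)
        return val

    res = minimize_scalar(
        objective,
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-11, "maxiter": 200},
    )
    lam_hat = float(np.exp(res.x))
    f_zero, _ = _neg2_reml(0.0, ws, Xty, yty, Sy)
    # boundary: accept lambda = 0 whenever it is at least as good, or the
    # optimiser ran into the lower bound
    if f_zero <= res.fun + 1e-10 or res.x <= _LOG_LAMBDA_BOUNDS[0] + 1e-6:
        lam_hat = 0.0
    return _finalise(ws, Xty, yty, Sy, lam=lam_hat, converged=bool(res.success))


def _finalise(ws: _LMMWorkspace, Xty, yty, Sy, lam: float, converged: bool) -> CpGFit:
    val, parts = _neg2_reml(lam, ws, Xty, yty, Sy)
    beta, A, sigma2, logdet_v0, logdet_a = parts
    dof = ws.n - ws.p
    cov = sigma2 * np.linalg.inv(A)
    loglik = -0.5 * (dof * np.log(2.0 * np.pi) + dof * np.log(sigma2) + dof + logdet_v0 + logdet_a)
    return CpGFit(
        coef=beta,
        cov=cov,
        sigma2_chip=lam * sigma2,
        sigma2_resid=sigma2,
        loglik=loglik,
        converged=converged,
        df_resid=dof,
    )


def build_design(
    pheno: pd.DataFrame, marker: str, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + marker + covariates; categoricals expanded to indicators.

    The marker is always column 1.  Categorical (non-numeric) covariates are
    expanded with the first level as reference.
    """
    cols: list[np.ndarray] = [np.ones(len(pheno)), pheno[marker].to_numpy(dtype=float)]
    names = ["intercept", marker]
    for cov in covariates:
        series = pheno[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    return np.column_stack(cols), names


def run_ewas(
    beta: BetaMatrix,
    pheno: pd.DataFrame,
    marker: str,
    covariates: list[str],
) -> pd.DataFrame:
    """Single-marker EWAS over every CpG of one platform.

    Returns one row per CpG with the marker term's beta, SE, t, two-sided p
    (t reference, n - p_fixed df) and the sample count.  Constant CpGs yield
    NA statistics and are counted in a single summary warning.
    """
    if marker not in pheno.columns:
        raise ValueError(f"marker '{marker}' not in phenotype table")
    missing = [c for c in covariates if c not in pheno.columns]
    if missing:
        raise ValueError(f"covariates not in phenotype table: {missing}")
    sample_ids = [s for s in pheno["sample_id"] if s in set(beta.sample_ids)]
    ph = pheno.set_index("sample_id").loc[sample_ids].reset_index()
    values = beta.values[sample_ids].to_numpy(dtype=float)
    design, _ = build_design(ph, marker, covariates)
    chip = ph["chip_id"].to_numpy()
    if len(np.unique(chip)) < 2:
        logger.warning("fewer than 2 chips; all CpGs fit by ordinary least squares")
        chip = np.zeros(len(ph), dtype=int)
    ws = _LMMWorkspace(design, chip)
    n = len(ph)
    rows = []
    n_constant = 0
    for j, cpg in enumerate(beta.cpg_ids):
        y = values[j]
        if np.ptp(y) == 0.0:
            n_constant += 1
            rows.append((cpg, marker, np.nan, np.nan, np.nan, np.nan, n, beta.platform))
            continue
        fit = _fit_with_workspace(ws, y)
        b = fit.coef[1]
        se = float(np.sqrt(fit.cov[1, 1]))
        t = b / se
        p = 2.0 * t_dist.sf(abs(t), fit.df_resid)
        rows.append((cpg, marker, b, se, t, p, n, beta.platform))
    if n_constant:
        warnings.warn(
            f"{n_constant} CpG(s) with constant methylation emitted with NA statistics",
            stacklevel=2,
        )
    result = pd.DataFrame(
        rows, columns=["cpg_id", "marker", "beta", "se", "t", "p", "n", "platform"]
    )
    ann = beta.annotation.set_index("cpg_id")
    result.insert(1, "chr", ann.loc[result["cpg_id"], "chr"].to_numpy())
    result.insert(2, "pos", ann.loc[result["cpg_id"], "pos_1based"].to_numpy())
    result.insert(3, "gene", ann.loc[result["cpg_id"], "gene"].to_numpy())
    return result


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda from a vector of p-values.

    lambda = median(chi2_1 quantile at 1 - p) / median of chi2_1; a
    well-calibrated analysis has lambda near 1.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    observed = chi2.isf(p, df=1)
    return float(np.median(observed) / _CHI2_1_MEDIAN)
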