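"""Cross-platform evidence combination and significance accounting.

Fixed-effect inverse-variance meta-analysis (METAL-style) for single-trait
effects on the shared CpG panel, Fisher's method for combining multi-trait
p-values across platforms, and Bonferroni family-wise accounting with a
strict-inequality convention at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

#: smallest p-value accepted by fisher_combine; callers floor before combining
MIN_P = 1e-300


@dataclass
class SignificanceSet:
    """CpGs significant in one analysis under a Bonferroni threshold."""

    label: str
    m_tests: int
    alpha_family: float
    threshold: float
    table: pd.DataFrame  # cpg_id, p — sorted ascending by p

    @property
    def cpg_ids(self) -> list:
        return self.table["cpg_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def inverse_variance_meta(results: pd.DataFrame) -> dict:
    """Fixed-effect inverse-variance combination of one CpG/marker's rows.

    Expects columns beta, se (and cpg_id/marker for the identity check).
    Weights w_i = 1/se_i^2; the meta z is Gaussian-referenced.
    """
    if len(results) < 1:
        raise ValueError("need at least one study result")
    for col in ("cpg_id", "marker"):
        if col in results.columns and results[col].nunique() > 1:
            raise ValueError(f"inverse_variance_meta given mismatched {col} values")
    se = results["se"].to_numpy(dtype=float)
    b = results["beta"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    meta_beta = float((w * b).sum() / w.sum())
    meta_se = float(w.sum() ** -0.5)
    meta_z = meta_beta / meta_se
    return {
        "meta_beta": meta_beta,
        "meta_se": meta_se,
        "meta_z": meta_z,
        "meta_p": float(2.0 * norm.sf(abs(meta_z))),
        "n_platforms": int(len(results)),
    }


def meta_single_trait(res_a: pd.DataFrame, res_b: pd.DataFrame) -> pd.DataFrame:
    """Vectorised inverse-variance meta of two platform EWAS tables.

    Restricted to the CpGs present in both tables (the shared panel);
    platform-specific CpGs never enter the meta-analysis.
    """
    cols = ["cpg_id", "beta", "se", "n"]
    merged = res_a[cols + ["chr", "pos", "gene", "marker"]].merge(
        res_b[cols], on="cpg_id", suffixes=("_1", "_2")
    )
    merged = merged.dropna(subset=["beta_1", "se_1", "beta_2", "se_2"])
    w1 = 1.0 / merged["se_1"] ** 2
    w2 = 1.0 / merged["se_2"] ** 2
    wsum = w1 + w2
    beta = (w1 * merged["beta_1"] + w2 * merged["beta_2"]) / wsum
    se = wsum**-0.5
    z = beta / se
    return pd.DataFrame(
        {
            "cpg_id": merged["cpg_id"],
            "chr": merged["chr"],
            "pos": merged["pos"],
            "gene": merged["gene"],
            "marker": merged["marker"],
            "beta": beta,
            "se": se,
            "t": z,
            "p": 2.0 * norm.sf(np.abs(z)),
            "n": merged["n_1"] + merged["n_2"],
            "platform": "meta",
        }
    )


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: X = -2 sum(ln p) ~ chi2 with 2m df under the null.

    Returns (statistic, degrees of freedom, combined p).  The sum is taken on
    the log scale so inputs near the representable floor survive; p <= 0 is a
    caller error (floor at MIN_P first).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor extreme values at MIN_P first")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return stat, df, float(chi2.sf(stat, df))


def fisher_combine_frame(frames: list[pd.DataFrame], p_col: str) -> pd.DataFrame:
    """Row-wise Fisher combination of one p-value column across platforms.

    Inner join on cpg_id; returns cpg_id, fisher_stat, fisher_df, fisher_p.
    """
    merged = frames[0][["cpg_id", p_col]].rename(columns={p_col: "p_0"})
    for i, frame in enumerate(frames[1:], start=1):
        merged = merged.merge(
            frame[["cpg_id", p_col]].rename(columns={p_col: f"p_{i}"}), on="cpg_id"
        )
    pcols = [c for c in merged.columns if c.startswith("p_")]
    pmat = np.clip(merged[pcols].to_numpy(dtype=float), MIN_P, 1.0)
    stat = -2.0 * np.log(pmat).sum(axis=1)
    df = 2 * len(pcols)
    return pd.DataFrame(
        {
            "cpg_id": merged["cpg_id"],
            "fisher_stat": stat,
            "fisher_df": df,
            "fisher_p": chi2.sf(stat, df),
        }
    )


def bonferroni_threshold(alpha_family: float, m_tests: int) -> float:
    """Nominal per-test threshold alpha / m controlling family-wise error."""
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must lie in (0, 1)")
    if m_tests <= 0:
        raise ValueError("m_tests must be a positive integer")
    return alpha_family / m_tests


def significant_set(
    results: pd.DataFrame,
    p_column: str,
    alpha_family: float = 0.05,
    m_tests: int | None = None,
    label: str = "",
) -> SignificanceSet:
    """CpGs with p strictly below the Bonferroni threshold, sorted by p.

    ``m_tests`` defaults to the number of non-NA p-values in the table (the
    analysis' own panel size), mirroring separate per-analysis corrections.
    """
    if p_column not in results.columns:
        raise ValueError(f"column '{p_column}' not present")
    pvals = results[[c for c in ("cpg_id", p_column) if c in results.columns]].dropna()
    if m_tests is None:
        m_tests = len(pvals)
    threshold = bonferroni_threshold(alpha_family, max(m_tests, 1)) if len(pvals) else alpha_family
    hits = pvals[pvals[p_column] < threshold].sort_values(p_column, kind="stable")
    table = hits.rename(columns={p_column: "p"}).reset_index(drop=True)
    return SignificanceSet(
        label=label,
        m_tests=int(m_tests),
        alpha_family=alpha_family,
        threshold=threshold,
        table=table,
    )
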