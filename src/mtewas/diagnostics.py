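"""QQ/Manhattan-ready tables and cross-result agreement measures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mtewas.ewas import genomic_inflation

__all__ = ["qq_coordinates", "manhattan_table", "compare_betas", "genomic_inflation"]


def qq_coordinates(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Expected quantiles are (i - 0.5)/n for the i-th smallest p-value.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0)),
        }
    )


def manhattan_table(results: pd.DataFrame, p_column: str = "p") -> pd.DataFrame:
    """chr, pos, -log10 p, sorted by genomic coordinate."""
    out = results[["cpg_id", "chr", "pos", p_column]].dropna().copy()
    out["neglog10_p"] = -np.log10(np.clip(out[p_column].to_numpy(float), 1e-300, 1.0))
    return out.sort_values(["chr", "pos"], kind="stable").reset_index(drop=True)


def compare_betas(res_a: pd.DataFrame, res_b: pd.DataFrame) -> float:
    """R^2 of effect estimates on the CpGs shared by two EWAS tables."""
    merged = res_a[["cpg_id", "beta"]].merge(
        res_b[["cpg_id", "beta"]], on="cpg_id", suffixes=("_a", "_b")
    ).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 shared CpGs to compare effect estimates")
    r = np.corrcoef(merged["beta_a"], merged["beta_b"])[0, 1]
    return float(r**2)
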