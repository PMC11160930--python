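"""Gene-set enrichment of significant CpG sets with CpG-count bias correction.

Genes carrying many CpG probes are more likely to harbour at least one
significant CpG by chance; CpGs mapping to several genes credit each of them.
Enrichment therefore models gene selection as biased urn sampling: each
gene's selection probability is estimated as a monotone (isotonic) function
of its total CpG count in the tested universe, a term's odds parameter is the
ratio of mean in-term to mean out-of-term weights, and the enrichment p-value
is the upper tail of Wallenius' noncentral hypergeometric distribution at the
observed in-term selected count.  With equal weights everything reduces to
the central hypergeometric (Fisher) test.  FDR control across terms is
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import hypergeom
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from mtewas.meta import SignificanceSet

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """CpG -> genes (one-to-many) and gene -> terms maps over a tested universe."""

    cpg_to_genes: dict  # cpg_id -> tuple of gene symbols
    gene_to_terms: dict  # gene -> tuple of term ids
    universe: list  # all CpGs tested in the analysis

    @classmethod
    def from_tables(
        cls, annotation: pd.DataFrame, gene_sets: pd.DataFrame, universe: list
    ) -> "AnnotationMap":
        """Build from the annotation TSV (cpg_id, gene ';'-separated) and a
        long gene-set table (term_id, gene)."""
        cpg_to_genes = {
            row.cpg_id: tuple(sorted(set(str(row.gene).split(";"))))
            for row in annotation.itertuples()
            if str(row.gene) not in ("", "nan", "-")
        }
        gene_to_terms: dict[str, set] = {}
        for row in gene_sets.itertuples():
            gene_to_terms.setdefault(row.gene, set()).add(row.term_id)
        return cls(
            cpg_to_genes=cpg_to_genes,
            gene_to_terms={g: tuple(sorted(t)) for g, t in gene_to_terms.items()},
            universe=list(universe),
        )


def map_cpgs_to_genes(sig: SignificanceSet, ann: AnnotationMap) -> pd.DataFrame:
    """Genes hit by at least one significant CpG, with per-gene CpG tallies.

    Multi-gene CpGs credit every mapped gene.  CpGs absent from the
    annotation are counted and logged, not fatal.
    """
    counts: dict[str, int] = {}
    n_unmapped = 0
    for cpg in sig.cpg_ids:
        genes = ann.cpg_to_genes.get(cpg)
        if not genes:
            n_unmapped += 1
            continue
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    if n_unmapped:
        logger.warning("%d significant CpG(s) missing from the annotation", n_unmapped)
    return pd.DataFrame(
        sorted(counts.items()), columns=["gene", "n_sig_cpgs"]
    )


def _wallenius_pmf(n: int, K: int, N: int, odds: float) -> np.ndarray:
    """Probability masses P(X = k), k = 0..n, of Wallenius' noncentral
    hypergeometric: draw n genes without replacement from N (K in the term)
    where in-term genes have draw odds ``odds``.

    Uses the integral representation
      P(X=k) = C(K,k) C(N-K,n-k) * int_0^1 (1-t^(odds/D))^k (1-t^(1/D))^(n-k) dt,
      D = odds*(K-k) + (N-K-(n-k)).
    """
    from scipy.special import comb

    masses = np.zeros(n + 1)
    for k in range(n + 1):
        if k > K or (n - k) > (N - K):
            continue
        d = odds * (K - k) + (N - K - (n - k))
        if d <= 0:  # all remaining mass exhausted; single possible outcome
            masses[k] = 1.0
            continue

        def integrand(t, k=k, d=d):
            return (1.0 - t ** (odds / d)) ** k * (1.0 - t ** (1.0 / d)) ** (n - k)

        val, _ = quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-12, epsrel=1e-10)
        masses[k] = comb(K, k, exact=False) * comb(N - K, n - k, exact=False) * val
    return masses


def wallenius_tail(
    k_observed: int, n_selected: int, K_term: int, N_universe: int, odds: float
) -> float:
    """P(X >= k_observed) under Wallenius' noncentral hypergeometric.

    The numerically integrated masses must sum to 1 within 1e-8 (asserted);
    odds = 1 reduces exactly to the central hypergeometric tail.
    """
    if not (0 <= k_observed <= min(n_selected, K_term)):
        raise ValueError("k_observed outside the feasible range")
    if odds <= 0:
        raise ValueError("odds must be positive")
    if n_selected > N_universe or K_term > N_universe:
        raise ValueError("selected count and term size cannot exceed the universe")
    if k_observed == 0:
        return 1.0
    if abs(odds - 1.0) < 1e-12:
        return float(hypergeom.sf(k_observed - 1, N_universe, K_term, n_selected))
    masses = _wallenius_pmf(n_selected, K_term, N_universe, odds)
    total = masses.sum()
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"Wallenius masses sum to {total}, not 1")
    return float(np.clip(masses[k_observed:].sum() / total, 0.0, 1.0))


def _gene_universe(ann: AnnotationMap) -> pd.DataFrame:
    """Per-gene CpG counts over the tested universe."""
    counts: dict[str, int] = {}
    for cpg in ann.universe:
        for g in ann.cpg_to_genes.get(cpg, ()):  # unannotated CpGs carry no gene
            counts[g] = counts.get(g, 0) + 1
    return pd.DataFrame(sorted(counts.items()), columns=["gene", "n_cpgs"])


def _selection_weights(universe: pd.DataFrame, selected: set) -> np.ndarray:
    """Per-gene selection-probability weight as a monotone function of CpG count.

    Isotonic regression of the selection indicator on the gene's CpG count;
    when fewer than 20 distinct counts exist, a monotone fit on binned means
    degenerates to the same isotonic solution, so the isotonic fit is used
    throughout.  Weights are floored away from zero so odds stay finite.
    """
    x = universe["n_cpgs"].to_numpy(dtype=float)
    y = universe["gene"].isin(selected).to_numpy(dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    w = iso.fit_transform(x, y)
    floor = max(y.mean() * 1e-3, 1e-6)
    return np.maximum(w, floor)


def gometh_test(sig: SignificanceSet, ann: AnnotationMap) -> pd.DataFrame:
    """Term-by-term Wallenius enrichment of the genes hit by significant CpGs.

    Returns one row per term: term_id, n_genes_in_term, n_selected_in_term,
    odds, wallenius_p, fdr_q (Benjamini-Hochberg), sorted by p.
    """
    selected_genes = set(map_cpgs_to_genes(sig, ann)["gene"])
    if not selected_genes:
        raise ValueError("no genes selected; nothing to test")
    universe = _gene_universe(ann)
    weights = _selection_weights(universe, selected_genes)
    gene_weight = dict(zip(universe["gene"], weights))
    n_universe = len(universe)
    n_selected = int(universe["gene"].isin(selected_genes).sum())

    term_genes: dict[str, set] = {}
    universe_genes = set(universe["gene"])
    for gene, terms in ann.gene_to_terms.items():
        if gene not in universe_genes:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    rows = []
    for term, genes in sorted(term_genes.items()):
        if not genes:
            logger.warning("term %s has no universe genes; skipped", term)
            continue
        k_term = len(genes)
        k_obs = len(genes & selected_genes)
        in_w = np.mean([gene_weight[g] for g in genes])
        out_genes = universe_genes - genes
        if out_genes:
            out_w = np.mean([gene_weight[g] for g in out_genes])
            odds = float(in_w / out_w) if out_w > 0 else 1.0
        else:
            odds = 1.0  # term covers the whole universe
        p = wallenius_tail(k_obs, n_selected, k_term, n_universe, odds)
        rows.append((term, k_term, k_obs, odds, p))
    result = pd.DataFrame(
        rows, columns=["term_id", "n_genes_in_term", "n_selected_in_term", "odds", "wallenius_p"]
    )
    if len(result):
        result["fdr_q"] = multipletests(result["wallenius_p"], method="fdr_bh")[1]
    else:
        result["fdr_q"] = []
    return result.sort_values("wallenius_p", kind="stable").reset_index(drop=True)
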