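"""Pathway enrichment of DR gene pairs by the cumulative hypergeometric test.

The unit of enrichment is the *gene pair*, not the gene.  With N background
genes there are n = N(N-1)/2 background pairs; a pathway holding g
background genes contributes m = g(g-1)/2 of them.  If k of the n pairs are
DR pairs and x of those have **both** genes in the pathway, the chance of at
least x pathway DR pairs under random allocation is

    P = 1 - sum_{i=0}^{x-1} C(m, i) C(n-m, k-i) / C(n, k)

i.e. the hypergeometric upper tail.  P-values are BH-adjusted across all
tested pathways (one family for the whole collection); pathways with fewer
than two background genes define no pairs and are excluded from testing.
This lets a pathway with few differentially *expressed* genes still be
detected when one strongly dysregulated gene reverses its ordering against
many pathway partners.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .dr_detection import bh_adjust
from .io_formats import GeneSetCollection

logger = logging.getLogger("drfunc")

ENRICHMENT_COLUMNS = [
    "pathway", "g", "m", "x", "k", "n", "p_raw", "p_adjusted", "significant",
]


def count_pathway_pairs(pathway_genes: set[str], background: set[str]) -> int:
    """Background gene pairs a pathway defines: g(g-1)/2 with g = |pathway ∩ background|."""
    g = len(set(pathway_genes) & set(background))
    return g * (g - 1) // 2


def enrichment_p(x: int, m: int, k: int, n: int) -> float:
    """Hypergeometric upper-tail P(X >= x) for x of k draws landing in m of n."""
    if not (0 <= m <= n and 0 <= k <= n and 0 <= x <= min(m, k)):
        raise ValueError(
            f"infeasible counts: x={x}, m={m}, k={k}, n={n} "
            "(need 0 <= x <= min(m, k), m <= n, k <= n)"
        )
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, n, m, k))


def enrich_all(
    dr_table: pd.DataFrame,
    collection: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every pathway of the collection for DR-pair enrichment.

    ``dr_table`` must come from the same background as ``collection`` (a DR
    gene outside the background is a dataset/collection mismatch and raises).
    A DR pair counts toward a pathway only when both its genes belong to the
    pathway's background genes.  Rows are sorted by (p_adjusted, pathway).
    """
    if collection.background_genes is None:
        raise ValueError("background not derived; call define_background first")
    background = collection.background_genes
    n = len(background) * (len(background) - 1) // 2
    k = len(dr_table)

    if k:
        dr_genes = set(dr_table["gene_i"]) | set(dr_table["gene_j"])
        stray = sorted(dr_genes - background)
        if stray:
            raise ValueError(
                f"DR table references gene(s) outside the background: "
                f"{stray[:5]} — dataset/collection mismatch"
            )

    tested = {
        name: genes & background
        for name, genes in collection.sets.items()
        if len(genes & background) >= 2
    }
    if not tested:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    dropped = len(collection.sets) - len(tested)
    if dropped:
        logger.info("excluded %d pathway(s) with <2 background genes", dropped)

    names = sorted(tested)
    gene_pos = {gene: p for p, gene in enumerate(sorted(background))}
    membership = np.zeros((len(names), len(background)), dtype=bool)
    for r, name in enumerate(names):
        membership[r, [gene_pos[g] for g in tested[name]]] = True

    if k:
        gi = dr_table["gene_i"].map(gene_pos).to_numpy(dtype=np.intp)
        gj = dr_table["gene_j"].map(gene_pos).to_numpy(dtype=np.intp)
        x = np.zeros(len(names), dtype=np.int64)
        step = max(1, 8_000_000 // max(len(names), 1))
        for s in range(0, k, step):
            x += (membership[:, gi[s:s + step]]
                  & membership[:, gj[s:s + step]]).sum(axis=1)
    else:
        x = np.zeros(len(names), dtype=np.int64)

    g = np.array([len(tested[name]) for name in names], dtype=np.int64)
    m = g * (g - 1) // 2
    with np.errstate(divide="ignore"):
        p_raw = np.where(x > 0, hypergeom.sf(x - 1, n, m, k), 1.0)
    p_adj = bh_adjust(p_raw)
    table = pd.DataFrame({
        "pathway": names, "g": g, "m": m, "x": x,
        "k": np.int64(k), "n": np.int64(n),
        "p_raw": p_raw, "p_adjusted": p_adj,
        "significant": p_adj < fdr,
    })
    return table.sort_values(
        ["p_adjusted", "pathway"], kind="mergesort"
    ).reset_index(drop=True)
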