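"""Differentially ranked (DR) gene-pair detection.

Each gene pair's phenotype-by-ordering table [[n1, n2], [m1, m2]] is tested
for association with Fisher's exact test (two-sided by default), p-values
are Benjamini-Hochberg adjusted across *all* tested pairs, and pairs below
the FDR threshold (default 5%) are reported with a direction label:

    Pattern 1  when the case odds of G_i > G_j exceed the control odds
               (n1/n2 > m1/m2, evaluated as the cross-product n1*m2 > n2*m1)
    Pattern 2  when the inequality is reversed
    ambiguous  when the cross-products are exactly equal

Because tens of millions of pairs may be tested, the Fisher p-values are
computed in batch: tables are deduplicated (with s case and t control
samples there are at most (s+1)^2 (t+1)^2 / 4 distinct tables, typically a
few thousand) and the conditional hypergeometric enumeration is vectorised
over the unique tables.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset, GeneSetCollection, define_background
from .reo_engine import PairOrderCounts, compute_pair_counts

logger = logging.getLogger("drfunc")

PATTERN1 = "Pattern1"
PATTERN2 = "Pattern2"
AMBIGUOUS = "ambiguous"

DR_TABLE_COLUMNS = [
    "gene_i", "gene_j", "n1", "n2", "m1", "m2", "p_raw", "p_adjusted", "pattern",
]

# Relative gate for counting a table's probability as "at most" the observed
# one in the two-sided tail sum; absorbs floating-point error in pmf values
# that are mathematically equal (same convention as the classical R/scipy
# implementations).
_TIE_GATE = 1.0 + 1e-7


def fisher_exact_batch(
    n1: np.ndarray,
    n2: np.ndarray,
    m1: np.ndarray,
    m2: np.ndarray,
    alternative: str = "two-sided",
) -> np.ndarray:
    """Fisher exact p-values for many 2x2 tables [[n1,n2],[m1,m2]] at once.

    ``alternative`` follows the usual convention for the (1,1) cell n1:
    'two-sided', 'greater' or 'less'.  Tables are deduplicated before the
    conditional enumeration, so cost scales with the number of distinct
    tables, not with the number of pairs.
    """
    tables = np.stack(
        [np.asarray(a, dtype=np.int64).ravel() for a in (n1, n2, m1, m2)], axis=1
    )
    if tables.min(initial=0) < 0:
        raise ValueError("counts must be nonnegative")
    row1 = tables[:, 0] + tables[:, 1]
    row2 = tables[:, 2] + tables[:, 3]
    if (row1 == 0).any() or (row2 == 0).any():
        raise ValueError(
            "each phenotype needs at least one non-tied sample "
            "(n1+n2 >= 1 and m1+m2 >= 1); filter all-tie pairs first"
        )

    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    a, b, c, d = uniq.T
    total = a + b + c + d
    k = a + b  # draws: case samples contributing an ordering
    K = a + c  # successes in population: samples with G_i > G_j
    lo = np.maximum(0, k - (total - K))
    hi = np.minimum(k, K)

    p = np.empty(len(uniq), dtype=np.float64)
    if alternative == "greater":
        p = hypergeom.sf(a - 1, total, K, k)
    elif alternative == "less":
        p = hypergeom.cdf(a, total, K, k)
    elif alternative == "two-sided":
        width = int((hi - lo).max()) + 1
        support = lo[:, None] + np.arange(width)[None, :]
        valid = support <= hi[:, None]
        pmf = hypergeom.pmf(
            np.where(valid, support, lo[:, None]),
            total[:, None], K[:, None], k[:, None],
        )
        pmf = np.where(valid, pmf, 0.0)
        p_obs = hypergeom.pmf(a, total, K, k)
        p = np.where(pmf <= p_obs[:, None] * _TIE_GATE, pmf, 0.0).sum(axis=1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return np.minimum(p, 1.0)[inverse].reshape(np.shape(n1))


def fisher_pair_test(counts: PairOrderCounts, alternative: str = "two-sided") -> float:
    """Fisher exact p for one pair's table; both margins must be nonzero."""
    return float(
        fisher_exact_batch(
            np.array([counts.n1]), np.array([counts.n2]),
            np.array([counts.m1]), np.array([counts.m2]),
            alternative=alternative,
        )[0]
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_pattern(counts: PairOrderCounts) -> str:
    """Direction of the REO shift via cross-products (no division by zero)."""
    return _patterns_from_products(
        np.array([counts.n1], dtype=np.int64) * counts.m2,
        np.array([counts.n2], dtype=np.int64) * counts.m1,
    )[0]


def _patterns_from_products(nm: np.ndarray, mn: np.ndarray) -> np.ndarray:
    out = np.full(nm.shape, AMBIGUOUS, dtype=object)
    out[nm > mn] = PATTERN1
    out[nm < mn] = PATTERN2
    return out


def detect_dr_pairs(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    fdr: float = 0.05,
    block_size: int = 512,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Run the full DR gene-pair scan over the background genes.

    Orchestrates pair counting over all background-gene pairs, batched
    Fisher tests, BH adjustment across every tested pair, FDR filtering and
    pattern assignment.  Pairs that are all ties in either phenotype cannot
    be tested and are skipped (logged).  Rows are sorted by
    (p_adjusted, gene_i, gene_j) and pair keys use i < j in sorted
    background-gene-id order, so tables from different runs align.
    """
    if not 0 <= fdr <= 1:
        raise ValueError(f"fdr threshold must be in [0, 1], got {fdr}")
    dataset.require_min_group_sizes(2)
    if collection.background_genes is None:
        collection = define_background(dataset, collection)
    genes = sorted(collection.background_genes)
    if len(genes) < 2:
        raise ValueError("background has fewer than 2 genes")

    chunks: list[tuple[np.ndarray, ...]] = []
    n_skipped = 0
    for block in compute_pair_counts(dataset, genes, block_size):
        testable = (block.n1 + block.n2 > 0) & (block.m1 + block.m2 > 0)
        n_skipped += int((~testable).sum())
        if not testable.any():
            continue
        sel = (arr[testable] for arr in block)
        i, j, n1, n2, m1, m2 = sel
        p = fisher_exact_batch(n1, n2, m1, m2, alternative=alternative)
        chunks.append((
            i.astype(np.int32), j.astype(np.int32),
            n1.astype(np.uint16), n2.astype(np.uint16),
            m1.astype(np.uint16), m2.astype(np.uint16), p,
        ))
    if n_skipped:
        logger.info("skipped %d pair(s) with all-tie phenotype margins", n_skipped)
    if not chunks:
        return pd.DataFrame(columns=DR_TABLE_COLUMNS)

    i, j, n1, n2, m1, m2, p_raw = (
        np.concatenate([c[f] for c in chunks]) for f in range(7)
    )
    p_adj = bh_adjust(p_raw)
    sig = p_adj < fdr
    logger.info(
        "tested %d pairs over %d background genes; %d significant at FDR %g",
        p_raw.size, len(genes), int(sig.sum()), fdr,
    )
    i, j, n1, n2, m1, m2 = (a[sig] for a in (i, j, n1, n2, m1, m2))
    p_raw, p_adj = p_raw[sig], p_adj[sig]
    patterns = _patterns_from_products(
        n1.astype(np.int64) * m2.astype(np.int64),
        n2.astype(np.int64) * m1.astype(np.int64),
    )
    gene_arr = np.array(genes, dtype=object)
    table = pd.DataFrame({
        "gene_i": gene_arr[i], "gene_j": gene_arr[j],
        "n1": n1.astype(np.int64), "n2": n2.astype(np.int64),
        "m1": m1.astype(np.int64), "m2": m2.astype(np.int64),
        "p_raw": p_raw, "p_adjusted": p_adj, "pattern": patterns,
    })
    table = table.sort_values(
        ["p_adjusted", "gene_i", "gene_j"], kind="mergesort"
    ).reset_index(drop=True)
    return table
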