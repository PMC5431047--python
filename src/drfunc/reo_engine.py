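"""Within-sample relative expression orderings (REOs) and pair counting.

For a gene pair (i, j) and one sample, the REO is 1 when gene i is expressed
above gene j in that sample and 0 when below; a pair with exactly equal
values in a sample is excluded from that sample's tally.  Aggregating the
REOs over samples in each phenotype gives the 2x2 table

    cases:    n1 = #{R_ij = 1},  n2 = #{R_ij = 0}
    controls: m1 = #{R_ij = 1},  m2 = #{R_ij = 0}

on which the differential-ranking test operates.  Because only orderings
within a sample are used, any strictly increasing per-sample transform
(log, quantile scaling, affine with positive slope) leaves the counts
unchanged — the property that makes the approach insensitive to batch and
platform effects.

Pairs are processed in row blocks so the working set scales with
block_size**2 x samples rather than with the full pair count.
"""

from __future__ import annotations

import logging
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .io_formats import CASE, CONTROL, ExpressionDataset

logger = logging.getLogger("drfunc")

GREATER = "greater"
LESS = "less"
TIE = "tie"


class PairOrderCounts(NamedTuple):
    """Ordering counts for one gene pair; i < j in the analysis gene order."""

    i: int
    j: int
    n1: int  # cases with G_i > G_j
    n2: int  # cases with G_i < G_j
    m1: int  # controls with G_i > G_j
    m2: int  # controls with G_i < G_j


class PairCountBlock(NamedTuple):
    """A vectorised chunk of pair counts (parallel arrays)."""

    i: np.ndarray
    j: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    m1: np.ndarray
    m2: np.ndarray

    def __len__(self) -> int:
        return self.i.size

    def iter_pairs(self) -> Iterator[PairOrderCounts]:
        for k in range(self.i.size):
            yield PairOrderCounts(
                int(self.i[k]), int(self.j[k]), int(self.n1[k]),
                int(self.n2[k]), int(self.m1[k]), int(self.m2[k]),
            )


def reo_of_sample(value_i: float, value_j: float) -> str:
    """REO of one gene pair in one sample: 'greater', 'less' or 'tie'.

    A tie (exact equality) contributes to neither ordering count.
    """
    if not (np.isfinite(value_i) and np.isfinite(value_j)):
        raise ValueError(
            f"expression values must be finite; got ({value_i}, {value_j})"
        )
    if value_i > value_j:
        return GREATER
    if value_i < value_j:
        return LESS
    return TIE


def _pair_block_counts(
    a_case: np.ndarray, b_case: np.ndarray,
    a_ctrl: np.ndarray, b_ctrl: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # a_*: (ba, samples); b_*: (bb, samples) -> (ba, bb) count matrices
    n1 = (a_case[:, None, :] > b_case[None, :, :]).sum(axis=2)
    n2 = (a_case[:, None, :] < b_case[None, :, :]).sum(axis=2)
    m1 = (a_ctrl[:, None, :] > b_ctrl[None, :, :]).sum(axis=2)
    m2 = (a_ctrl[:, None, :] < b_ctrl[None, :, :]).sum(axis=2)
    return n1, n2, m1, m2


def compute_pair_counts(
    dataset: ExpressionDataset,
    gene_subset: Sequence[str],
    block_size: int = 512,
) -> Iterator[PairCountBlock]:
    """Stream 2x2 ordering counts for every unordered pair of gene_subset.

    Pairs (i, j) with i < j index into ``gene_subset`` order; each of the
    G(G-1)/2 pairs is emitted exactly once, in blocks.  The emitted counts
    are independent of ``block_size``.
    """
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    genes = list(gene_subset)
    if len(genes) < 2:
        raise ValueError(f"need at least 2 genes to form pairs, got {len(genes)}")
    if len(set(genes)) != len(genes):
        raise ValueError("gene_subset contains duplicates")
    index = dataset.gene_index()
    missing = [g for g in genes if g not in index]
    if missing:
        raise ValueError(f"gene_subset not in dataset: {missing[:5]}")

    rows = np.array([index[g] for g in genes], dtype=np.intp)
    case_cols = dataset.sample_indices(CASE)
    ctrl_cols = dataset.sample_indices(CONTROL)
    x = dataset.values[rows]
    if not np.isfinite(x).all():
        raise ValueError("expression matrix contains non-finite values")
    x_case = np.ascontiguousarray(x[:, case_cols])
    x_ctrl = np.ascontiguousarray(x[:, ctrl_cols])

    g = len(genes)
    # One strip per row block: rows [sa, ea) against all columns [sa, g),
    # computed column-block by column-block, then emitted in lexicographic
    # (i, j) order so the stream is identical for every block_size.
    for sa in range(0, g, block_size):
        ea = min(sa + block_size, g)
        strips: list[tuple[np.ndarray, ...]] = []
        for sb in range(sa, g, block_size):
            eb = min(sb + block_size, g)
            strips.append(_pair_block_counts(
                x_case[sa:ea], x_case[sb:eb], x_ctrl[sa:ea], x_ctrl[sb:eb]
            ))
        n1, n2, m1, m2 = (
            np.concatenate([s[f] for s in strips], axis=1) for f in range(4)
        )
        ii, jj = np.meshgrid(
            np.arange(sa, ea, dtype=np.intp),
            np.arange(sa, g, dtype=np.intp),
            indexing="ij",
        )
        flat = (ii < jj).ravel()  # drop self-pairs and j<i duplicates
        yield PairCountBlock(
            ii.ravel()[flat], jj.ravel()[flat],
            n1.ravel()[flat], n2.ravel()[flat],
            m1.ravel()[flat], m2.ravel()[flat],
        )


def collect_pair_counts(
    dataset: ExpressionDataset,
    gene_subset: Sequence[str],
    block_size: int = 512,
) -> PairCountBlock:
    """Materialise the full count stream as one block (small runs / tests)."""
    blocks = list(compute_pair_counts(dataset, gene_subset, block_size))
    return PairCountBlock(*(np.concatenate([getattr(b, f) for b in blocks])
                            for f in PairCountBlock._fields))
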