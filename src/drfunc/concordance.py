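"""Cross-dataset reproducibility of DR gene-pair lists.

Two DR tables (typically from independent datasets of the same disease) are
compared on their shared pairs.  A shared pair is *concordant* when it
carries the same direction label (Pattern 1 or Pattern 2) in both lists.
With M shared pairs of which M1 are concordant, the chance of at least M1
concordances under independence is the upper binomial tail

    P = sum_{i=M1..M} C(M, i) p0^i (1 - p0)^(M-i)

with p0 = 0.5, since a directed DR pair has exactly two mutually exclusive
outcomes.  Lists with P < 0.05 are called significantly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

from .dr_detection import AMBIGUOUS


@dataclass
class ConcordanceReport:
    count_a: int           # DR pairs in table A
    count_b: int           # DR pairs in table B
    M: int                 # shared unambiguous pairs
    M1: int                # shared pairs with equal pattern
    ratio: float           # M1/M (nan when M == 0)
    p_binomial: float      # upper-tail binomial probability
    p0: float = 0.5
    significant: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "count_a": self.count_a, "count_b": self.count_b,
            "overlapped_pairs": self.M, "concordant_pairs": self.M1,
            "concordant_ratio": self.ratio, "p_binomial": self.p_binomial,
            "p0": self.p0, "significant": self.significant,
        }])


def _pattern_map(table: pd.DataFrame) -> dict[tuple[str, str], str]:
    sub = table[table["pattern"] != AMBIGUOUS]
    return {
        (gi, gj): pat
        for gi, gj, pat in zip(sub["gene_i"], sub["gene_j"], sub["pattern"])
    }


def overlap_and_count(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[int, int]:
    """(M, M1): shared unambiguous pairs and those with equal pattern.

    Both tables must key pairs canonically (gene_i < gene_j in sorted id
    order), which :func:`~drfunc.dr_detection.detect_dr_pairs` guarantees.
    """
    map_a, map_b = _pattern_map(table_a), _pattern_map(table_b)
    shared = map_a.keys() & map_b.keys()
    m1 = sum(1 for key in shared if map_a[key] == map_b[key])
    return len(shared), m1


def binomial_concordance_p(M: int, M1: int, p0: float = 0.5) -> float:
    """Exact upper-tail P(X >= M1), X ~ Binomial(M, p0); stable at large M."""
    if not 0 <= M1 <= M:
        raise ValueError(f"need 0 <= M1 <= M, got M1={M1}, M={M}")
    if not 0 <= p0 <= 1:
        raise ValueError(f"p0 must be a probability, got {p0}")
    return float(binom.sf(M1 - 1, M, p0))


def concordance_report(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> ConcordanceReport:
    """Assemble overlap counts, the concordant ratio and the binomial P."""
    m, m1 = overlap_and_count(table_a, table_b)
    ratio = m1 / m if m > 0 else math.nan
    p = binomial_concordance_p(m, m1) if m > 0 else 1.0
    return ConcordanceReport(
        count_a=len(table_a), count_b=len(table_b),
        M=m, M1=m1, ratio=ratio, p_binomial=p,
        significant=bool(m > 0 and p < alpha),
    )
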