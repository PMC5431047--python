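"""Two-phenotype expression simulator with planted rank reversals.

The generator draws a gene-by-sample matrix on a log2-like scale: each gene
has a fixed baseline mean (log-spaced across a dynamic range by default) and
each value adds independent Gaussian noise.  Controls follow the baselines
directly.  In cases, each *planted* gene pair has its two baseline means
swapped and pushed apart by ``effect_size`` times their original gap, so the
pair's expected within-sample ordering reverses between phenotypes — the
exact signal the DR-pair scan is built to find.  All other genes are
identically distributed in both groups, giving a clean null background.

Planted pairs are gene-disjoint so the ground truth is unambiguous, and by
default are sampled among gene pairs whose baseline gap exceeds a minimum,
so the planted reversal is a genuine ordering flip rather than a coin-flip
ordering drowned in noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    ExpressionDataset,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_phenotype,
)


def default_baseline_means(n_genes: int, low: float = 4.0, high: float = 12.0) -> np.ndarray:
    """Evenly spaced log2-scale baselines spanning a realistic dynamic range."""
    return np.linspace(low, high, n_genes)


@dataclass
class SimulationSpec:
    """Parameters of one simulated two-phenotype study.

    ``planted_pairs`` hold (i, j) gene indices whose mean ordering reverses
    in cases; pairs must be gene-disjoint.  ``seed`` drives only the noise —
    two specs differing only in seed are replicate studies of the same
    underlying signal.
    """

    n_genes: int = 300
    n_case: int = 30
    n_control: int = 30
    baseline_means: np.ndarray | None = None
    noise_sd: float = 0.5
    planted_pairs: tuple[tuple[int, int], ...] = ()
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_means is None:
            self.baseline_means = default_baseline_means(self.n_genes)
        self.baseline_means = np.asarray(self.baseline_means, dtype=np.float64)
        if self.baseline_means.shape != (self.n_genes,):
            raise ValueError("baseline_means must have one entry per gene")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be > 0, got {self.effect_size}")
        self.planted_pairs = tuple((int(i), int(j)) for i, j in self.planted_pairs)
        used: set[int] = set()
        for i, j in self.planted_pairs:
            if i == j:
                raise ValueError(f"planted pair ({i}, {j}) repeats a gene")
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                raise ValueError(f"planted pair ({i}, {j}) outside 0..{self.n_genes - 1}")
            if i in used or j in used:
                raise ValueError("planted pairs must be gene-disjoint")
            used.update((i, j))
        if len(used) > self.n_genes:
            raise ValueError("more planted genes than genes")


def gene_id(index: int) -> str:
    # zero-padded so lexicographic id order equals simulation index order
    return f"G{index:05d}"


def choose_planted_pairs(
    n_pairs: int,
    baseline_means: np.ndarray,
    min_gap: float = 1.0,
    seed: int = 0,
) -> tuple[tuple[int, int], ...]:
    """Sample gene-disjoint pairs whose baseline gap is at least ``min_gap``."""
    rng = np.random.default_rng(seed)
    means = np.asarray(baseline_means, dtype=np.float64)
    order = rng.permutation(means.size)
    pairs: list[tuple[int, int]] = []
    pool = list(order)
    while pool and len(pairs) < n_pairs:
        i = pool.pop()
        mates = [g for g in pool if abs(means[g] - means[i]) >= min_gap]
        if not mates:
            continue
        j = mates[rng.integers(len(mates))]
        pool.remove(j)
        pairs.append((min(i, j), max(i, j)))
    if len(pairs) < n_pairs:
        raise ValueError(
            f"could only place {len(pairs)} of {n_pairs} planted pairs with "
            f"gap >= {min_gap}; reduce n_pairs or min_gap"
        )
    return tuple(pairs)


def make_default_spec(
    n_pairs: int = 50,
    n_genes: int = 300,
    n_case: int = 30,
    n_control: int = 30,
    noise_sd: float = 0.5,
    effect_size: float = 2.0,
    seed: int = 0,
    structure_seed: int = 12345,
) -> SimulationSpec:
    """A standard planted-signal study; ``structure_seed`` fixes the planted
    set so that specs differing only in ``seed`` are true replicates."""
    means = default_baseline_means(n_genes)
    pairs = choose_planted_pairs(n_pairs, means, seed=structure_seed)
    return SimulationSpec(
        n_genes=n_genes, n_case=n_case, n_control=n_control,
        baseline_means=means, noise_sd=noise_sd,
        planted_pairs=pairs, effect_size=effect_size, seed=seed,
    )


def _case_means(spec: SimulationSpec) -> np.ndarray:
    means = spec.baseline_means.copy()
    for i, j in spec.planted_pairs:
        bi, bj = spec.baseline_means[i], spec.baseline_means[j]
        center, gap = (bi + bj) / 2.0, abs(bi - bj)
        half = spec.effect_size * gap / 2.0
        # swap: the originally lower gene ends up on top, pushed apart
        if bi >= bj:
            means[i], means[j] = center - half, center + half
        else:
            means[i], means[j] = center + half, center - half
    return means


def simulate_two_phenotype(
    spec: SimulationSpec,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw one dataset and return it with the planted ground truth.

    The ground-truth frame has columns (gene_i, gene_j, pattern) with the
    canonical pair key (gene_i < gene_j in id order) and the Pattern label
    the DR scan should assign: Pattern 1 when cases favour G_i > G_j more
    strongly than controls do, Pattern 2 otherwise.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ctrl_means = spec.baseline_means
    case_means = _case_means(spec)
    n_samples = spec.n_case + spec.n_control
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    values = np.empty((spec.n_genes, n_samples))
    values[:, : spec.n_case] = case_means[:, None] + noise[:, : spec.n_case]
    values[:, spec.n_case:] = ctrl_means[:, None] + noise[:, spec.n_case:]

    sample_ids = [f"case{s:03d}" for s in range(spec.n_case)] + [
        f"ctrl{s:03d}" for s in range(spec.n_control)
    ]
    phenotype = {s: (CASE if s.startswith("case") else CONTROL) for s in sample_ids}
    dataset = ExpressionDataset(
        gene_ids=[gene_id(g) for g in range(spec.n_genes)],
        values=values,
        sample_ids=sample_ids,
        phenotype=phenotype,
    )

    rows = []
    for i, j in spec.planted_pairs:
        a, b = min(i, j), max(i, j)  # canonical key: id order == index order
        case_delta = case_means[a] - case_means[b]
        ctrl_delta = ctrl_means[a] - ctrl_means[b]
        # ordering reverses by construction; direction follows the case side
        pattern = "Pattern1" if case_delta > ctrl_delta else "Pattern2"
        rows.append({"gene_i": gene_id(a), "gene_j": gene_id(b), "pattern": pattern})
    truth = pd.DataFrame(rows, columns=["gene_i", "gene_j", "pattern"])
    return dataset, truth


def replicate(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """The same study design with fresh noise."""
    return replace(spec, seed=seed)


def make_matched_collection(
    planted_pairs: tuple[tuple[int, int], ...],
    n_genes: int,
    pathway_size: int = 20,
    n_pathways: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """A collection with one signal pathway holding all planted genes.

    The signal pathway contains every planted-pair gene topped up with
    random fillers to ``pathway_size``; the remaining pathways are random
    draws of the same size.  Together the pathways cover all genes, so the
    derived background equals the measured genes.
    """
    if pathway_size < 2:
        raise ValueError(f"pathway_size must be >= 2, got {pathway_size}")
    planted_genes = sorted({g for pair in planted_pairs for g in pair})
    if len(planted_genes) > pathway_size:
        raise ValueError(
            f"pathway_size {pathway_size} cannot hold {len(planted_genes)} planted genes"
        )
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    rng = np.random.default_rng(seed)
    others = np.setdiff1d(np.arange(n_genes), np.array(planted_genes, dtype=int))
    n_fill = pathway_size - len(planted_genes)
    fillers = rng.choice(others, size=n_fill, replace=False) if n_fill else []
    sets = {"SIGNAL_PATHWAY": {gene_id(g) for g in [*planted_genes, *fillers]}}
    for p in range(n_pathways - 1):
        members = rng.choice(n_genes, size=min(pathway_size, n_genes), replace=False)
        sets[f"RANDOM_PW_{p:03d}"] = {gene_id(g) for g in members}
    # guarantee full gene coverage so background == measured genes
    covered = {g for s in sets.values() for g in s}
    leftover = [gene_id(g) for g in range(n_genes) if gene_id(g) not in covered]
    for start in range(0, len(leftover), max(pathway_size, 2)):
        chunk = leftover[start:start + max(pathway_size, 2)]
        if len(chunk) == 1:  # a singleton set defines no pairs; pad it
            chunk = chunk + [gene_id(0)]
        sets[f"COVER_PW_{start:04d}"] = set(chunk)
    return GeneSetCollection(sets=sets, source_label="synthetic")


def write_fixture_dir(
    spec: SimulationSpec,
    out_dir: str | Path,
    pathway_size: int = 110,
    n_pathways: int = 50,
) -> dict[str, Path]:
    """Write expression, phenotype, GMT and ground-truth files for a spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_two_phenotype(spec)
    collection = make_matched_collection(
        spec.planted_pairs, spec.n_genes, pathway_size, n_pathways, seed=spec.seed
    )
    paths = {
        "expression": out / "expression.tsv",
        "phenotype": out / "phenotype.tsv",
        "gmt": out / "pathways.gmt",
        "truth": out / "planted_pairs.tsv",
    }
    write_expression(dataset, paths["expression"])
    write_phenotype(dataset, paths["phenotype"])
    write_gmt(collection, paths["gmt"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
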