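import numpy as np
import pytest

from drfunc import (
    ExpressionDataset,
    GeneSetCollection,
    make_default_spec,
    simulate_two_phenotype,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Two genes, two cases, two controls; hand-enumerable orderings.

    Cases: (A,B) = (2,1), (3,5) -> one A>B, one A<B.
    Controls: (A,B) = (1,2), (0,4) -> both A<B.
    """
    return ExpressionDataset(
        gene_ids=["A", "B"],
        values=np.array([[2.0, 3.0, 1.0, 0.0], [1.0, 5.0, 2.0, 4.0]]),
        sample_ids=["c1", "c2", "n1", "n2"],
        phenotype={"c1": "case", "c2": "case", "n1": "control", "n2": "control"},
    )


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        sets={"P1": {"A", "B", "E"}, "P2": {"C", "F"}},
        source_label="fixture",
    )


@pytest.fixture(scope="session")
def planted_run():
    """One simulated planted-signal study, reused across tests."""
    spec = make_default_spec(seed=7)
    dataset, truth = simulate_two_phenotype(spec)
    return spec, dataset, truth


def random_dataset(rng: np.random.Generator, n_genes=20, n_case=6, n_control=6):
    """Unstructured random dataset for property tests."""
    values = rng.normal(size=(n_genes, n_case + n_control))
    samples = [f"s{k}" for k in range(n_case + n_control)]
    phen = {s: ("case" if k < n_case else "control") for k, s in enumerate(samples)}
    return ExpressionDataset(
        gene_ids=[f"G{k:03d}" for k in range(n_genes)],
        values=values,
        sample_ids=samples,
        phenotype=phen,
    )
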