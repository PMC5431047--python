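from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from drfunc import (
    ExpressionDataset,
    assign_pattern,
    bh_adjust,
    define_background,
    detect_dr_pairs,
    fisher_exact_batch,
    fisher_pair_test,
    make_default_spec,
    make_matched_collection,
    simulate_two_phenotype,
)
from drfunc.reo_engine import PairOrderCounts


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-fraction enumeration of all tables with the observed margins,
    summing probabilities not exceeding the observed table's."""
    N, K, k = a + b + c + d, a + c, a + b
    denom = comb(N, k)
    p_obs = Fraction(comb(K, a) * comb(N - K, k - a), denom)
    total = Fraction(0)
    for x in range(max(0, k - (N - K)), min(k, K) + 1):
        p = Fraction(comb(K, x) * comb(N - K, k - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


def counts(n1, n2, m1, m2):
    return PairOrderCounts(0, 1, n1, n2, m1, m2)


class TestFisherPairTest:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 0, 0, 10), 2 / 184756),  # fully reversed ordering
            ((5, 5, 5, 5), 1.0),           # perfectly balanced
            ((3, 0, 0, 3), 2 / 20),        # C(6,3)=20 margin enumeration
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_pair_test(counts(*table)) == pytest.approx(expected, rel=1e-12)

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(42)
        tables = []
        for _ in range(200):
            r1, r2 = rng.integers(1, 31, size=2)
            tables.append((
                int(rng.integers(0, r1 + 1)), int(r1),
                int(rng.integers(0, r2 + 1)), int(r2),
            ))
        a = np.array([t[0] for t in tables])
        b = np.array([t[1] - t[0] for t in tables])
        c = np.array([t[2] for t in tables])
        d = np.array([t[3] - t[2] for t in tables])
        batch = fisher_exact_batch(a, b, c, d)
        for p, (aa, bb, cc, dd) in zip(batch, zip(a, b, c, d)):
            expected = fisher_two_sided_oracle(int(aa), int(bb), int(cc), int(dd))
            assert p == pytest.approx(expected, rel=1e-12)

    def test_row_and_double_column_swap_invariance(self):
        base = fisher_pair_test(counts(7, 3, 2, 8))
        assert fisher_pair_test(counts(2, 8, 7, 3)) == pytest.approx(base, rel=1e-12)
        assert fisher_pair_test(counts(3, 7, 8, 2)) == pytest.approx(base, rel=1e-12)

    def test_one_sided_alternatives_are_tails(self):
        a, b, c, d = (np.array([x]) for x in (8, 2, 3, 7))
        greater = fisher_exact_batch(a, b, c, d, alternative="greater")[0]
        less = fisher_exact_batch(a, b, c, d, alternative="less")[0]
        # hypergeometric tails overlap in exactly the observed cell
        from scipy.stats import hypergeom
        pmf_obs = hypergeom.pmf(8, 20, 11, 10)
        assert greater + less == pytest.approx(1 + pmf_obs, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="non-tied"):
            fisher_pair_test(counts(0, 0, 5, 5))


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.03, 0.04]), [0.015, 0.04, 0.04], rtol=1e-12
        )

    def test_cap_and_singleton(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAssignPattern:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((9, 1, 2, 8), "Pattern1"),    # 9/1 > 2/8
            ((10, 0, 0, 10), "Pattern1"),  # cross-product handles /0
            ((0, 10, 10, 0), "Pattern2"),
            ((5, 5, 5, 5), "ambiguous"),
        ],
    )
    def test_cross_product_rule(self, table, expected):
        assert assign_pattern(counts(*table)) == expected


class TestDetectDrPairs:
    def test_planted_signal_recovered_with_pattern(self, planted_run):
        spec, dataset, truth = planted_run
        coll = make_matched_collection(
            spec.planted_pairs, spec.n_genes, pathway_size=110, n_pathways=10, seed=1
        )
        table = detect_dr_pairs(dataset, define_background(dataset, coll))
        found = table.set_index(["gene_i", "gene_j"])["pattern"]
        for row in truth.itertuples():
            assert found.get((row.gene_i, row.gene_j)) == row.pattern
        # output contract
        assert list(table.columns) == [
            "gene_i", "gene_j", "n1", "n2", "m1", "m2",
            "p_raw", "p_adjusted", "pattern",
        ]
        assert (table.p_adjusted < 0.05).all()
        assert (table.p_adjusted >= table.p_raw - 1e-15).all()
        assert (table.p_adjusted.diff().dropna() >= 0).all()

    def test_null_split_gives_near_empty_table(self):
        # case and control are disjoint halves of the same null population
        rng = np.random.default_rng(11)
        values = rng.normal(size=(60, 40))
        samples = [f"s{k}" for k in range(40)]
        from drfunc.synthetic_fixtures import gene_id
        ds = ExpressionDataset(
            gene_ids=[gene_id(k) for k in range(60)],
            values=values,
            sample_ids=samples,
            phenotype={s: ("case" if k < 20 else "control")
                       for k, s in enumerate(samples)},
        )
        coll = make_matched_collection((), 60, pathway_size=30, n_pathways=6, seed=2)
        table = detect_dr_pairs(ds, define_background(ds, coll))
        assert len(table) <= 0.001 * (60 * 59 // 2)

    def test_fdr_zero_gives_empty_table(self, planted_run):
        spec, dataset, _ = planted_run
        coll = make_matched_collection(
            spec.planted_pairs, spec.n_genes, pathway_size=110, n_pathways=5, seed=1
        )
        assert len(detect_dr_pairs(dataset, coll, fdr=0.0)) == 0

    def test_label_symmetry_swaps_patterns(self, planted_run):
        spec, dataset, _ = planted_run
        coll = make_matched_collection(
            spec.planted_pairs, spec.n_genes, pathway_size=110, n_pathways=5, seed=1
        )
        flipped = ExpressionDataset(
            gene_ids=dataset.gene_ids, values=dataset.values,
            sample_ids=dataset.sample_ids,
            phenotype={s: ("case" if l == "control" else "control")
                       for s, l in dataset.phenotype.items()},
        )
        a = detect_dr_pairs(dataset, coll).set_index(["gene_i", "gene_j"])
        b = detect_dr_pairs(flipped, coll).set_index(["gene_i", "gene_j"])
        assert set(a.index) == set(b.index)
        swap = {"Pattern1": "Pattern2", "Pattern2": "Pattern1",
                "ambiguous": "ambiguous"}
        for key in a.index:
            assert b.loc[key, "pattern"] == swap[a.loc[key, "pattern"]]
            assert b.loc[key, "p_raw"] == pytest.approx(a.loc[key, "p_raw"], rel=1e-12)

    def test_determinism_byte_identical(self, planted_run, tmp_path):
        spec, dataset, _ = planted_run
        coll = make_matched_collection(
            spec.planted_pairs, spec.n_genes, pathway_size=110, n_pathways=5, seed=1
        )
        outs = []
        for run in range(2):
            table = detect_dr_pairs(dataset, coll)
            path = tmp_path / f"run{run}.tsv"
            table.to_csv(path, sep="\t", index=False)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]
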