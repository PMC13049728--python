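"""DEG/DEP filters, top-k ranking and exact hypergeometric overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoforce import (
    GlycoforceError,
    filter_degs,
    filter_deps,
    hypergeometric_overlap,
    rank_top_migration,
)
from glycoforce.simulate import GeneSim, simulate_gene_table


def _rna_table(rows):
    return pd.DataFrame(
        [{"gene_id": g, "measure": "rna", "log2fc_bac": l2fc, "padj_bac": p}
         for g, l2fc, p in rows],
        columns=["gene_id", "measure", "log2fc_bac", "padj_bac"],
    )


class TestFilters:
    def test_deg_toy_table_hand_count(self):
        table = _rna_table([
            ("g1", 1.0, 0.05),    # FC 2.0, keeps
            ("g2", -0.7, 0.10),   # FC 1.62, keeps (down-regulation counts)
            ("g3", 1.5, 0.20),    # padj fails
            ("g4", 0.3, 0.05),    # FC 1.23 fails
            ("g5", 0.0, 0.01),    # FC 1.0 fails
        ])
        assert filter_degs(table) == {"g1", "g2"}

    def test_deg_boundaries(self):
        table = _rna_table([("g1", 1.0, 0.05), ("g2", 2.0, 0.5)])
        assert filter_degs(table, padj_max=0.0, fc_min=math.inf) == set()
        assert filter_degs(table, padj_max=1.0, fc_min=1.0 - 1e-9) \
            == {"g1", "g2"}

    def test_deg_empty_table(self):
        assert filter_degs(_rna_table([])) == set()

    def test_dep_toy_table(self):
        table = pd.DataFrame([
            {"gene_id": "p1", "measure": "protein", "log2fc_bac": 0.5,
             "p_bac": 0.01},   # keeps
            {"gene_id": "p2", "measure": "protein", "log2fc_bac": 0.5,
             "p_bac": 0.20},   # p fails
            {"gene_id": "p3", "measure": "protein", "log2fc_bac": 0.1,
             "p_bac": 0.01},   # FC 1.07 fails
            {"gene_id": "p4", "measure": "protein", "log2fc_bac": 0.0,
             "p_bac": 0.001},  # FC 1.0 fails
        ])
        assert filter_deps(table) == {"p1"}

    def test_dep_all_unit_fold_change_empty(self):
        table = pd.DataFrame([
            {"gene_id": f"p{i}", "measure": "protein", "log2fc_bac": 0.0,
             "p_bac": 0.001} for i in range(5)
        ])
        assert filter_deps(table) == set()

    def test_missing_columns_rejected(self):
        with pytest.raises(GlycoforceError, match="missing columns"):
            filter_degs(pd.DataFrame({"gene_id": ["g"]}))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        rows=st.lists(st.tuples(st.floats(-4, 4), st.floats(0, 1)),
                      min_size=0, max_size=40),
        p1=st.floats(0, 1), p2=st.floats(0, 1),
        f1=st.floats(1, 4), f2=st.floats(1, 4),
    )
    def test_relaxing_thresholds_never_shrinks(self, rows, p1, p2, f1, f2):
        table = _rna_table([(f"g{i}", l, p) for i, (l, p) in enumerate(rows)])
        tight = filter_degs(table, padj_max=min(p1, p2), fc_min=max(f1, f2))
        loose = filter_degs(table, padj_max=max(p1, p2), fc_min=min(f1, f2))
        assert tight <= loose

    def test_pure_function_repeat_identity(self):
        table, _ = simulate_gene_table(GeneSim(), seed=51)
        assert filter_degs(table) == filter_degs(table)

    def test_planted_dep_recall(self):
        # 200 proteins, 20 with 1.5-fold shifts at noise giving ~0.8 power
        recalls = []
        for seed in range(10):
            table, truth = simulate_gene_table(GeneSim(), seed=600 + seed)
            deps = filter_deps(table)
            recalls.append(len(deps & truth.true_dep) / len(truth.true_dep))
        assert 0.6 <= np.mean(recalls) <= 0.95


def _enumerate_tail(universe, a_size, b_size, k):
    """Exhaustive enumeration oracle: P(|B' intersect A| >= k) over all
    equally likely draws B' of size b."""
    A = set(range(a_size))
    total = hits = 0
    for B in itertools.combinations(range(universe), b_size):
        total += 1
        if len(A & set(B)) >= k:
            hits += 1
    return hits / total


class TestHypergeometricOverlap:
    def test_worked_example(self):
        # universe 10, |A| = 5, |B| = 4, overlap 4 -> C(5,4) C(5,0)/C(10,4)
        universe = set(range(10))
        a = set(range(5))
        b = set(range(4))
        res = hypergeometric_overlap(a, b, universe)
        assert res.overlap_size == 4
        assert res.p_value == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_total_probability(self):
        universe = set(range(10))
        res = hypergeometric_overlap(set(range(3)), set(range(5, 9)), universe)
        assert res.overlap_size == 0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_universes(self):
        for universe in (5, 8):
            for a_size in range(universe + 1):
                for b_size in range(universe + 1):
                    max_k = min(a_size, b_size)
                    k = max_k  # the fully nested draw
                    if b_size - k > universe - a_size:
                        continue
                    A = set(range(a_size))
                    B = set(range(k)) | set(range(a_size, a_size + b_size - k))
                    res = hypergeometric_overlap(A, B, set(range(universe)))
                    oracle = _enumerate_tail(universe, a_size, b_size,
                                             res.overlap_size)
                    assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_symmetry(self):
        universe = set(range(40))
        a = set(range(12))
        b = set(range(6, 25))
        r1 = hypergeometric_overlap(a, b, universe)
        r2 = hypergeometric_overlap(b, a, universe)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_non_subset_rejected(self):
        with pytest.raises(GlycoforceError, match="subset"):
            hypergeometric_overlap({"x"}, set(), {"a", "b"})

    def test_enriched_table_yields_small_p(self):
        table, truth = simulate_gene_table(GeneSim(target_enrichment=0.5),
                                           seed=52)
        degs = filter_degs(table)
        res = hypergeometric_overlap(degs, truth.targets, truth.universe)
        assert res.p_value < 1e-6


class TestRankTopMigration:
    def _table(self, triples):
        return pd.DataFrame([
            {"gene_id": g, "measure": "rna", "log2fc_mac": m, "log2fc_bac": b}
            for g, m, b in triples
        ])

    def test_toy_three_genes(self):
        table = self._table([("g1", 2.0, 2.0), ("g2", 0.0, 0.0),
                             ("g3", -1.0, -1.0)])
        up, down, trunc = rank_top_migration(table, {"g1", "g2", "g3"}, k=1)
        assert up == ["g1"] and down == ["g3"]
        assert not trunc

    def test_mean_of_contrasts_is_the_score(self):
        table = self._table([("g1", 4.0, 0.0), ("g2", 1.0, 1.5)])
        up, _, _ = rank_top_migration(table, {"g1", "g2"}, k=1)
        assert up == ["g1"]  # mean 2.0 > 1.25

    def test_row_order_invariance_and_ties(self):
        triples = [("b", 1.0, 1.0), ("a", 1.0, 1.0), ("c", 0.0, 0.0)]
        t1 = self._table(triples)
        t2 = self._table(triples[::-1])
        subset = {"a", "b", "c"}
        assert rank_top_migration(t1, subset, k=2) \
            == rank_top_migration(t2, subset, k=2)
        up, _, _ = rank_top_migration(t1, subset, k=2)
        assert up == ["a", "b"]  # tie broken lexicographically

    def test_planted_top_k_exact(self, rng):
        winners = [f"w{i:02d}" for i in range(25)]
        others = [f"z{i:03d}" for i in range(100)]
        triples = [(g, 3.0 + rng.uniform(0, 1), 3.0) for g in winners]
        triples += [(g, rng.uniform(-1, 1), rng.uniform(-1, 1))
                    for g in others]
        table = self._table(triples)
        up, _, _ = rank_top_migration(table, set(winners) | set(others), k=25)
        assert sorted(up) == winners

    def test_k_exceeding_pool_flags_truncation(self):
        table = self._table([("g1", 1.0, 1.0)])
        up, down, trunc = rank_top_migration(table, {"g1"}, k=25)
        assert trunc and up == ["g1"]

    def test_missing_contrast_rejected(self):
        table = self._table([("g1", 1.0, np.nan)])
        with pytest.raises(GlycoforceError, match="contrasts"):
            rank_top_migration(table, {"g1"}, k=1)
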