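import numpy as np
import pytest

import kpang
from kpang.graph import GraphError
from kpang.metrics import (
    AlignedPairSet,
    _OrientedUnionFind,
    OrientationConflict,
    aligned_pairs,
    coverage_stats,
    jaccard_index,
    oracle_partition,
    verify_k_complete,
    verify_k_faithful,
)

from conftest import random_collection


class TestOrientedUnionFind:
    def test_orientation_propagates_through_chains(self):
        uf = _OrientedUnionFind()
        uf.union("a", "b", -1)
        uf.union("b", "c", -1)
        ra, sa = uf.find("a")
        rc, sc = uf.find("c")
        assert ra == rc and sa == sc  # a and c are same-oriented

    def test_conflict_detected(self):
        uf = _OrientedUnionFind()
        uf.union("a", "b", 1)
        with pytest.raises(OrientationConflict):
            uf.union("a", "b", -1)


class TestOracle:
    def test_unique_kmers_give_singletons(self):
        col = kpang.SequenceCollection.from_records([("r", "ACGTTTG")])
        op = oracle_partition(col, 7)
        assert all(len(c) == 1 for c in op.as_sets())

    def test_opposite_strand_orientations(self, two_seq_collection):
        op = oracle_partition(two_seq_collection, 3)
        # (1,1) and (2,4) share a class with opposite orientations
        assert op.same_class((1, 1), (2, 4))
        assert op.orient[(1, 1)] != op.orient[(2, 4)]

    def test_same_strand_orientations(self, repeat_collection):
        op = oracle_partition(repeat_collection, 3)
        assert op.same_class((1, 1), (1, 4))
        assert op.orient[(1, 1)] == op.orient[(1, 4)]


class TestVerifiers:
    def test_quotient_output_passes_both(self):
        rng = np.random.default_rng(61)
        for _ in range(8):
            col = random_collection(rng)
            k = int(rng.choice([3, 5, 7]))
            res = kpang.build_pangenome_graph(col, k, compress=False)
            assert verify_k_faithful(col, res.assignment, k)
            assert verify_k_complete(col, res.singular, k).ok

    def test_under_merged_assignment_fails(self, repeat_collection):
        ident = kpang.AssignmentVector(
            F=np.array([0, 1, 2, 3, 4, 5, 6, 0]), num_vertices=6
        )
        assert not verify_k_faithful(repeat_collection, ident, 3)
        text = kpang.concatenate(repeat_collection)
        g = kpang.build_singular_graph(text, ident)
        report = verify_k_complete(repeat_collection, g, 3)
        assert not report.ok
        assert set(report.violations) == {
            (((1, 1)), ((1, 4))),
            (((1, 2)), ((1, 5))),
            (((1, 3)), ((1, 6))),
        }

    def test_over_merged_assignment_fails(self):
        # merge two equal-label oracle singleton classes by hand
        col = kpang.SequenceCollection.from_records([("r", "ATTGCAT")])
        text = kpang.concatenate(col)
        res = kpang.build_pangenome_graph(col, 5, compress=False)
        F = res.assignment.F.copy()
        # positions 2 and 3 are distinct vertices labeled T; fuse them
        assert text.char(2) == text.char(3) == "T"
        F[F == F[3]] = F[2]
        ids = sorted({abs(int(x)) for x in F if x != 0})
        remap = {old: new for new, old in enumerate(ids, start=1)}
        F = np.array(
            [int(np.sign(x)) * remap[abs(int(x))] if x else 0 for x in F]
        )
        merged = kpang.AssignmentVector(F=F, num_vertices=len(ids))
        assert not verify_k_faithful(col, merged, 5)

    def test_complete_on_unique_identity_graph(self):
        col = kpang.SequenceCollection.from_records([("r", "ACGTTTG")])
        res = kpang.build_pangenome_graph(col, 7, compress=False)
        assert verify_k_complete(col, res.singular, 7).ok

    def test_mismatched_paths_error(self, two_seq_collection):
        g = kpang.BidirectedVariationGraph(
            vertices={1: "A"}, edges=set(), paths=[("S1", [(1, 1)])]
        )
        with pytest.raises(GraphError):
            verify_k_complete(two_seq_collection, g, 3)


class TestAlignedPairs:
    def test_reverse_complement_pair(self, two_seq_collection):
        g = kpang.build_pangenome_graph(two_seq_collection, 3).graph
        mu = aligned_pairs(g)
        assert mu.pairs == frozenset(
            (("S1", p), ("S2", 5 - p), False) for p in range(1, 5)
        )

    def test_identical_sequences(self):
        m, L = 3, 12
        col = kpang.SequenceCollection.from_records(
            [(f"h{i}", "ACGGTCAGTCAT") for i in range(m)]
        )
        g = kpang.build_pangenome_graph(col, 11).graph
        mu = aligned_pairs(g)
        # L pairs per sequence pair, all same-strand
        assert len(mu) == L * m * (m - 1) // 2
        assert all(flag for _, _, flag in mu.pairs)

    def test_invariant_under_compression(self):
        rng = np.random.default_rng(67)
        for _ in range(5):
            col = random_collection(rng)
            res = kpang.build_pangenome_graph(col, int(rng.choice([3, 5, 7])))
            assert (
                aligned_pairs(res.singular).pairs
                == aligned_pairs(res.graph).pairs
            )

    def test_reverse_complementing_a_record_maps_mu(self):
        cfg = kpang.SimulationConfig(
            n_haplotypes=3, length=60, substitution_rate=0.05, seed=71
        )
        col, _ = kpang.generate_collection(cfg)
        records = list(col.records)
        name, seq = records[1]
        L = len(seq)
        records[1] = (name, kpang.reverse_complement(seq))
        col_rc = kpang.SequenceCollection.from_records(records)
        k = 5
        mu_a = aligned_pairs(kpang.build_pangenome_graph(col, k).graph)
        mu_b = aligned_pairs(kpang.build_pangenome_graph(col_rc, k).graph)

        def map_pair(pair):
            (na, pa), (nb, pb), flag = pair
            a = (na, L + 1 - pa) if na == name else (na, pa)
            b = (nb, L + 1 - pb) if nb == name else (nb, pb)
            if (na == name) != (nb == name):
                flag = not flag
            return (min(a, b), max(a, b), flag)

        assert {map_pair(p) for p in mu_a.pairs} == set(mu_b.pairs)


class TestJaccard:
    def test_identity_and_disjoint(self, two_seq_collection):
        g = kpang.build_pangenome_graph(two_seq_collection, 3).graph
        mu = aligned_pairs(g)
        assert jaccard_index(mu, mu) == 1.0
        names = frozenset(["S1", "S2"])
        a = AlignedPairSet(
            pairs=frozenset({(("S1", 1), ("S2", 1), True)}),
            record_names=names,
        )
        b = AlignedPairSet(
            pairs=frozenset({(("S1", 2), ("S2", 2), True)}),
            record_names=names,
        )
        assert jaccard_index(a, b) == 0.0

    def test_partial_overlap(self):
        names = frozenset(["r"])
        x = (("r", 1), ("r", 5), True)
        y = (("r", 2), ("r", 6), True)
        z = (("r", 3), ("r", 7), True)
        a = AlignedPairSet(pairs=frozenset({x, y}), record_names=names)
        b = AlignedPairSet(pairs=frozenset({y, z}), record_names=names)
        assert jaccard_index(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_one(self):
        names = frozenset(["r"])
        empty = AlignedPairSet(pairs=frozenset(), record_names=names)
        assert jaccard_index(empty, empty) == 1.0

    def test_mismatched_names_error(self):
        a = AlignedPairSet(pairs=frozenset(), record_names=frozenset(["x"]))
        b = AlignedPairSet(pairs=frozenset(), record_names=frozenset(["y"]))
        with pytest.raises(ValueError):
            jaccard_index(a, b)


class TestCoverageStats:
    def test_compressed_pair(self, two_seq_collection):
        g = kpang.build_pangenome_graph(two_seq_collection, 3).graph
        st = coverage_stats(g)
        assert (st.node_count, st.edge_count, st.total_label_length) == (1, 0, 4)
        assert st.max_node_coverage == 2 and st.private_fraction == 0.0

    def test_single_unique_sequence(self):
        col = kpang.SequenceCollection.from_records([("r", "ACGTTTGAC")])
        st = coverage_stats(kpang.build_pangenome_graph(col, 9).graph)
        assert st.max_node_coverage == 1 and st.private_fraction == 1.0

    def test_m_identical_sequences(self):
        m = 5
        col = kpang.SequenceCollection.from_records(
            [(f"h{i}", "ACGGTCAGTCAT") for i in range(m)]
        )
        st = coverage_stats(kpang.build_pangenome_graph(col, 11).graph)
        assert st.max_node_coverage == m and st.private_fraction == 0.0
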