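import numpy as np
import pytest

import kpang
from kpang.graph import (
    GraphError,
    _chains,
    compress_unbranched,
    isomorphic,
    read_gfa,
    split_to_singular,
    write_gfa,
)

from conftest import random_collection


def build(collection, k, compress=True):
    return kpang.build_pangenome_graph(collection, k, compress=compress)


class TestBuildSingular:
    def test_reverse_complement_pair(self, two_seq_collection):
        res = build(two_seq_collection, 3, compress=False)
        g = res.singular
        assert [g.vertices[v] for v in sorted(g.vertices)] == list("ATTG")
        assert g.edge_count == 3
        assert g.path_steps("S1") == [(1, 1), (2, 1), (3, 1), (4, 1)]
        assert g.path_steps("S2") == [(4, -1), (3, -1), (2, -1), (1, -1)]
        g.validate()

    def test_identity_assignment_is_simple_path(self):
        col = kpang.SequenceCollection.from_records([("r", "ACGTTTG")])
        res = build(col, 7, compress=False)
        assert res.singular.node_count == 7
        assert res.singular.edge_count == 6

    def test_tandem_repeat_forms_cycle(self, repeat_collection):
        g = build(repeat_collection, 3, compress=False).singular
        assert g.node_count == 3 and g.edge_count == 3
        assert ((1, -1), (3, 1)) in g.edges  # the cycle-closing edge

    def test_labels_reconstruct_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(8):
            col = random_collection(rng)
            g = build(col, int(rng.choice([3, 5, 7])), compress=False).singular
            for name in col.names:
                assert g.path_label(name) == col.sequence(name)


class TestCompression:
    def test_pair_collapses_to_one_vertex(self, two_seq_collection):
        g = build(two_seq_collection, 3).graph
        assert g.vertices == {1: "ATTG"}
        assert g.edge_count == 0
        assert g.path_steps("S1") == [(1, 1)]
        assert g.path_steps("S2") == [(1, -1)]

    def test_tandem_repeat_self_link(self, repeat_collection):
        g = build(repeat_collection, 3).graph
        assert g.vertices == {1: "ATT"}
        assert g.edges == {((1, -1), (1, 1))}  # right side to left side
        assert g.path_steps("S1") == [(1, 1), (1, 1)]

    def test_single_unrepeated_sequence(self):
        col = kpang.SequenceCollection.from_records([("r", "ACGTTTGAC")])
        g = build(col, 9).graph
        assert g.vertices == {1: "ACGTTTGAC"} and g.edge_count == 0

    def test_requires_singular_input(self, two_seq_collection):
        g = build(two_seq_collection, 3).graph
        with pytest.raises(GraphError, match="singular"):
            compress_unbranched(g)

    def test_conservation_and_roundtrip(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            col = random_collection(rng)
            res = build(col, int(rng.choice([3, 5, 7])))
            singular, compressed = res.singular, res.graph
            compressed.validate()
            # sum of compressed label lengths == number of singular vertices
            assert compressed.total_label_length == singular.node_count
            # sum of (label length x coverage) == N
            assert (
                sum(
                    len(compressed.vertices[v]) * compressed.coverage(v)
                    for v in compressed.vertices
                )
                == col.N
            )
            assert isomorphic(split_to_singular(compressed), singular)
            # idempotence: re-compressing the split graph changes nothing
            assert isomorphic(
                compress_unbranched(split_to_singular(compressed)), compressed
            )
            for name in col.names:
                assert compressed.path_label(name) == col.sequence(name)

    def test_vectorized_contexts_match_path_derived_contexts(self):
        """The (text, F) classification pass and the path-walk pass agree."""
        from kpang.graph import _side_contexts, _side_contexts_fast

        rng = np.random.default_rng(97)
        for _ in range(8):
            col = random_collection(rng)
            k = int(rng.choice([3, 5, 7]))
            res = kpang.build_pangenome_graph(col, k, compress=False)
            fast = _side_contexts_fast(res.text, res.assignment)
            slow = _side_contexts(res.singular)
            assert fast.left == slow.left and fast.right == slow.right

    def test_masked_labels_pass_through(self):
        col = kpang.SequenceCollection.from_records([("r", "ATTGNACCA")])
        g = build(col, 3).graph
        assert "".join(g.path_label("r")) == "ATTGNACCA"
        assert any("N" in lab for lab in g.vertices.values())

    def test_side_neighbor_labels_bounded_by_alphabet(self):
        """The distinct oriented neighbor labels on any side of a singular
        vertex are drawn from the 4-letter alphabet.  Distinct neighbors may
        share a label when transitive merge chains join occurrences whose
        one-character extensions agree without a directly shared window, so
        only the label-set size is bounded; compression therefore contracts
        a side only when it carries exactly one edge."""
        rng = np.random.default_rng(43)
        for _ in range(5):
            col = random_collection(rng)
            g = build(col, int(rng.choice([3, 5]))).singular
            for v in g.vertices:
                for side in (1, -1):
                    labels = {
                        kpang.graph.oriented_label(g.vertices[w], -s)
                        for w, s in g.neighbors_on_side(v, side)
                    }
                    assert len(labels) <= 4
                    assert labels <= set("ACGT")


class TestSplit:
    def test_splits_vertex_into_chain(self, two_seq_collection):
        compressed = build(two_seq_collection, 3).graph
        split = split_to_singular(compressed)
        assert split.node_count == 4 and split.edge_count == 3
        assert split.path_label("S1") == "ATTG"
        assert split.path_label("S2") == "CAAT"

    def test_already_singular_is_isomorphic_copy(self, two_seq_collection):
        singular = build(two_seq_collection, 3, compress=False).singular
        assert isomorphic(split_to_singular(singular), singular)


class TestChainWalker:
    def test_breaks_pure_cycle_at_lowest_id(self):
        """A contraction map that closes into a cycle with no boundary."""
        g = kpang.BidirectedVariationGraph(
            vertices={1: "A", 2: "T", 3: "G"},
            edges=set(),
            paths=[],
        )
        nxt = {
            (1, 1): (2, 1),
            (2, 1): (3, 1),
            (3, 1): (1, 1),
            (1, -1): (3, -1),
            (3, -1): (2, -1),
            (2, -1): (1, -1),
        }
        chains = _chains(g, nxt)
        assert chains == [[(1, 1), (2, 1), (3, 1)]]


class TestGfa:
    def test_compressed_pair_serialization(self, tmp_path, two_seq_collection):
        g = build(two_seq_collection, 3).graph
        path = tmp_path / "pair.gfa"
        write_gfa(g, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "H\tVN:Z:1.0"
        assert "S\t1\tATTG" in lines
        assert not any(line.startswith("L") for line in lines)
        assert "P\tS1\t1+\t*" in lines and "P\tS2\t1-\t*" in lines

    def test_tandem_self_link(self, tmp_path, repeat_collection):
        g = build(repeat_collection, 3).graph
        path = tmp_path / "rep.gfa"
        write_gfa(g, path)
        lines = path.read_text().splitlines()
        assert sum(line.startswith("S\t") for line in lines) == 1
        l_lines = [line for line in lines if line.startswith("L\t")]
        assert l_lines == ["L\t1\t-\t1\t-\t0M"]
        assert "P\tS1\t1+,1+\t*" in lines

    def test_roundtrip_isomorphic(self, tmp_path):
        rng = np.random.default_rng(47)
        for trial in range(6):
            col = random_collection(rng)
            g = build(col, int(rng.choice([3, 5, 7]))).graph
            path = tmp_path / f"g{trial}.gfa"
            write_gfa(g, path)
            assert isomorphic(read_gfa(path), g)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("S\t1\n", "malformed"),
            ("S\t1\tA\nL\t1\t+\t2\t+\t0M\n", "unknown segment"),
            ("S\t1\tA\nL\t1\t+\t1\t+\t5M\n", "blunt"),
            ("S\t1\tA\nP\tx\t1?\t*\n", "malformed"),
        ],
    )
    def test_malformed_gfa(self, tmp_path, content, match):
        path = tmp_path / "bad.gfa"
        path.write_text(content)
        with pytest.raises(GraphError, match=match):
            read_gfa(path)


class TestInvariance:
    def test_record_permutation_yields_isomorphic_graph(self):
        rng = np.random.default_rng(53)
        col = random_collection(rng)
        perm = list(col.records)
        rng.shuffle(perm)
        col_perm = kpang.SequenceCollection.from_records(perm)
        for k in (3, 5):
            a = build(col, k).graph
            b = build(col_perm, k).graph
            assert isomorphic(a, b)

    def test_validate_rejects_broken_graphs(self):
        g = kpang.BidirectedVariationGraph(
            vertices={1: "A", 2: "C"},
            edges=set(),
            paths=[("p", [(1, 1)])],
        )
        with pytest.raises(GraphError, match="not on any path"):
            g.validate()
        g2 = kpang.BidirectedVariationGraph(
            vertices={1: "A"},
            edges={((1, 1), (1, 1))},
            paths=[("p", [(1, 1)])],
        )
        with pytest.raises(GraphError, match="unrealized"):
            g2.validate()
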