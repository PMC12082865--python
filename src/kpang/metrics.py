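"""Verification oracles and graph-evaluation metrics.

The oracle computes, by exhaustive enumeration, the equivalence closure of
the shared-k-mer relation over oriented sequence positions — the ground
truth the quotient algorithm must reproduce.  It is quadratic in the number
of k-mer occurrence pairs and intended for small inputs only.

Also here: verifiers for k-completeness and k-faithfulness of a graph or
assignment, the aligned-pair set mu(G) (two genome positions represented by
the same offset of the same vertex label), the Jaccard index between such
sets, and node-coverage statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .graph import BidirectedVariationGraph, GraphError
from .kmer_index import canonicalize_kmer, _require_odd
from .quotient import AssignmentVector
from .sequence_io import (
    DNA_ALPHABET,
    SequenceCollection,
    concatenate,
)

LocalPos = tuple[int, int]  # (1-based sequence index, 1-based offset)


class OrientationConflict(RuntimeError):
    """Two chains of shared k-mers force opposite orientations on one
    position — impossible for odd k on valid input."""


class _OrientedUnionFind:
    """Union-find carrying a relative orientation (+-1) to the parent."""

    def __init__(self) -> None:
        self.parent: dict = {}
        self.rel: dict = {}
        self.rank: dict = {}

    def find(self, x) -> tuple[object, int]:
        if x not in self.parent:
            self.parent[x] = x
            self.rel[x] = 1
            self.rank[x] = 0
            return x, 1
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        sign = 1
        for y in reversed(path):
            sign *= self.rel[y]
            self.parent[y] = x
            self.rel[y] = sign
        return x, self.rel[path[0]] if path else 1

    def union(self, a, b, sign: int) -> None:
        """Record orientation(a) = sign * orientation(b)."""
        ra, sa = self.find(a)
        rb, sb = self.find(b)
        if ra == rb:
            if sa != sign * sb:
                raise OrientationConflict(f"{a} ~ {b} with both signs")
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb, sa, sb = rb, ra, sb, sa
            # orientation(b) = sign * orientation(a) with the same sign
        self.parent[rb] = ra
        self.rel[rb] = sa * sign * sb
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


@dataclass(frozen=True)
class OraclePartition:
    """Ground-truth partition of sequence positions with orientations.

    ``classes`` maps each position to its class representative; ``orient``
    gives the position's orientation relative to that representative.
    Same-class positions carry equal bases when same-oriented and
    complementary bases when opposite-oriented.
    """

    classes: dict[LocalPos, LocalPos]
    orient: dict[LocalPos, int]

    def as_sets(self) -> set[frozenset]:
        groups: dict[LocalPos, set[LocalPos]] = {}
        for pos, rep in self.classes.items():
            groups.setdefault(rep, set()).add(pos)
        return {frozenset(g) for g in groups.values()}

    def same_class(self, a: LocalPos, b: LocalPos) -> bool:
        return self.classes[a] == self.classes[b]


def _kmer_occurrences(
    collection: SequenceCollection, k: int
) -> dict[str, list[tuple[int, int, int]]]:
    """Canonical k-mer -> list of (seq index, start, strand sign)."""
    occ: dict[str, list[tuple[int, int, int]]] = {}
    for i, (_, seq) in enumerate(collection.records, start=1):
        for p in range(1, len(seq) - k + 2):
            window = seq[p - 1 : p + k - 1]
            if not DNA_ALPHABET.issuperset(window):
                continue
            canon, sign = canonicalize_kmer(window)
            occ.setdefault(canon, []).append((i, p, sign))
    return occ


def _occurrence_position(occ: tuple[int, int, int], c: int, k: int) -> LocalPos:
    i, p, sign = occ
    return (i, p + c - 1) if sign > 0 else (i, p + k - c)


def oracle_partition(collection: SequenceCollection, k: int) -> OraclePartition:
    """Equivalence closure of the shared-k-mer relation over both strands.

    Every pair of equal canonical k-mer occurrences unions its k
    offset-matched position pairs with relative orientation given by the
    product of the occurrence strands.  Intended for small inputs (the
    enumeration is quadratic in per-k-mer occurrence counts).
    """
    _require_odd(k)
    uf = _OrientedUnionFind()
    all_positions = [
        (i, j)
        for i, (_, seq) in enumerate(collection.records, start=1)
        for j in range(1, len(seq) + 1)
    ]
    for pos in all_positions:
        uf.find(pos)
    for occs in _kmer_occurrences(collection, k).values():
        anchor = occs[0]
        for other in occs[1:]:
            rel = anchor[2] * other[2]
            for c in range(1, k + 1):
                uf.union(
                    _occurrence_position(anchor, c, k),
                    _occurrence_position(other, c, k),
                    rel,
                )
    classes: dict[LocalPos, LocalPos] = {}
    orient: dict[LocalPos, int] = {}
    reps: dict[object, LocalPos] = {}
    rep_sign: dict[object, int] = {}
    for pos in sorted(all_positions):
        root, sign = uf.find(pos)
        if root not in reps:
            reps[root] = pos  # lowest position is the class representative
            rep_sign[root] = sign
        classes[pos] = reps[root]
        orient[pos] = sign * rep_sign[root]
    return OraclePartition(classes=classes, orient=orient)


# -- verifiers -----------------------------------------------------------


def _assignment_partition(
    collection: SequenceCollection, assignment: AssignmentVector
) -> tuple[dict[LocalPos, int], dict[LocalPos, int]]:
    """Map local positions to (vertex ID, orientation) from F."""
    text = concatenate(collection)
    classes: dict[LocalPos, int] = {}
    orient: dict[LocalPos, int] = {}
    for i in range(1, text.n + 1):
        start = text.boundaries[i - 1]
        for j in range(1, text.sequence_length(i) + 1):
            f = int(assignment.F[start + j - 1])
            classes[(i, j)] = abs(f)
            orient[(i, j)] = 1 if f > 0 else -1
    return classes, orient


def verify_k_faithful(
    collection: SequenceCollection,
    assignment: AssignmentVector,
    k: int,
) -> bool:
    """True iff F induces exactly the oracle partition with consistent
    orientations (up to a global per-class flip)."""
    oracle = oracle_partition(collection, k)
    classes, orient = _assignment_partition(collection, assignment)
    groups: dict[int, list[LocalPos]] = {}
    for pos, v in classes.items():
        groups.setdefault(v, []).append(pos)
    if {frozenset(g) for g in groups.values()} != oracle.as_sets():
        return False
    for members in groups.values():
        flip = None
        for pos in members:
            rel = orient[pos] * oracle.orient[pos]
            if flip is None:
                flip = rel
            elif rel != flip:
                return False
    return True


@dataclass(frozen=True)
class CompletenessReport:
    ok: bool
    violations: tuple[tuple[LocalPos, LocalPos], ...]


def verify_k_complete(
    collection: SequenceCollection,
    graph: BidirectedVariationGraph,
    k: int,
) -> CompletenessReport:
    """Check that every pair of equal k-mer occurrences (both strands) is
    reflected: the two length-k oriented step windows are equal (after
    reversal-with-flip for opposite strands).

    Violations are reported as the position pairs whose steps differ.
    """
    _require_odd(k)
    if not graph.is_singular():
        raise GraphError("k-completeness check requires a singular graph")
    steps_by_seq: list[list] = []
    for i, (name, seq) in enumerate(collection.records, start=1):
        try:
            steps = graph.path_steps(name)
        except KeyError as exc:
            raise GraphError(f"graph has no path for record {name!r}") from exc
        if graph.path_label(name) != seq:
            raise GraphError(f"path {name!r} does not spell its sequence")
        steps_by_seq.append(steps)

    def window(occ: tuple[int, int, int]) -> tuple:
        i, p, sign = occ
        w = steps_by_seq[i - 1][p - 1 : p + k - 1]
        if sign > 0:
            return tuple(w)
        return tuple((v, -o) for v, o in reversed(w))

    violations: set[tuple[LocalPos, LocalPos]] = set()
    for occs in _kmer_occurrences(collection, k).values():
        for a, b in combinations(occs, 2):
            wa, wb = window(a), window(b)
            if wa == wb:
                continue
            for c in range(1, k + 1):
                if wa[c - 1] != wb[c - 1]:
                    pa = _occurrence_position(a, c, k)
                    pb = _occurrence_position(b, c, k)
                    violations.add((min(pa, pb), max(pa, pb)))
    return CompletenessReport(
        ok=not violations, violations=tuple(sorted(violations))
    )


# -- aligned pairs and topology metrics ----------------------------------

NamedPos = tuple[str, int]  # (record name, 1-based coordinate)
AlignedPair = tuple[NamedPos, NamedPos, bool]  # (lo, hi, same_strand)


@dataclass(frozen=True)
class AlignedPairSet:
    """The set mu(G): unordered pairs of distinct genome positions that are
    represented by the same offset of the same vertex label, each marked
    same-strand or opposite-strand."""

    pairs: frozenset[AlignedPair]
    record_names: frozenset[str]

    def __len__(self) -> int:
        return len(self.pairs)


def aligned_pairs(graph: BidirectedVariationGraph) -> AlignedPairSet:
    """Compute mu(G) exactly from the graph's paths.

    For a -1-oriented step the label offsets are traversed in reverse, so
    base t of the step maps to label offset L+1-t.
    """
    buckets: dict[tuple[int, int], list[tuple[NamedPos, int]]] = {}
    names = []
    for name, steps in graph.paths:
        names.append(name)
        pos = 0
        for v, o in steps:
            L = len(graph.vertices[v])
            for t in range(1, L + 1):
                pos += 1
                offset = t if o == 1 else L + 1 - t
                buckets.setdefault((v, offset), []).append(((name, pos), o))
        expected = sum(
            len(graph.vertices[v]) for v, _ in steps
        )
        if pos != expected:  # pragma: no cover - arithmetic guard
            raise GraphError(f"path/label length mismatch on {name!r}")
    pairs = set()
    for entries in buckets.values():
        if len(entries) < 2:
            continue
        for (pa, oa), (pb, ob) in combinations(entries, 2):
            if pa == pb:
                continue
            lo, hi = (pa, pb) if pa <= pb else (pb, pa)
            pairs.add((lo, hi, oa == ob))
    return AlignedPairSet(
        pairs=frozenset(pairs), record_names=frozenset(names)
    )


def jaccard_index(a: AlignedPairSet, b: AlignedPairSet) -> float:
    """|a & b| / |a | b|, with 1.0 when both sets are empty."""
    if a.record_names != b.record_names:
        raise ValueError(
            "aligned-pair sets are keyed by different record names"
        )
    union = a.pairs | b.pairs
    if not union:
        return 1.0
    return len(a.pairs & b.pairs) / len(union)


@dataclass(frozen=True)
class CoverageStats:
    node_count: int
    edge_count: int
    total_label_length: int
    max_node_coverage: int
    private_fraction: float
    private_node_fraction: float

    def as_dict(self) -> dict:
        return {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "total_label_length": self.total_label_length,
            "max_node_coverage": self.max_node_coverage,
            "private_fraction": self.private_fraction,
            "private_node_fraction": self.private_node_fraction,
        }


def coverage_stats(graph: BidirectedVariationGraph) -> CoverageStats:
    """Topology counts plus node-coverage statistics.

    Coverage of a node is the number of path steps visiting it in any
    orientation; a private node has coverage 1.  ``private_fraction`` is
    base-weighted (total label length in private nodes over the collection
    size N); ``private_node_fraction`` is the node-count variant.
    """
    cov: dict[int, int] = {v: 0 for v in graph.vertices}
    N = 0
    for _, steps in graph.paths:
        for v, _ in steps:
            cov[v] += 1
            N += len(graph.vertices[v])
    private_bases = sum(
        len(graph.vertices[v]) for v, c in cov.items() if c == 1
    )
    private_nodes = sum(1 for c in cov.values() if c == 1)
    return CoverageStats(
        node_count=graph.node_count,
        edge_count=graph.edge_count,
        total_label_length=graph.total_label_length,
        max_node_coverage=max(cov.values()) if cov else 0,
        private_fraction=private_bases / N if N else 0.0,
        private_node_fraction=(
            private_nodes / graph.node_count if graph.node_count else 0.0
        ),
    )
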