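"""Bidirected variation graphs: construction from F, compression, GFA I/O.

A bidirected variation graph has sequence-labeled vertices with two sides
(+1 = right, -1 = left); an edge links a side of one vertex to a side of
another (or the same) vertex, and a walk entering a node on one side must
exit on the other.  Genomes are stored as named paths of oriented steps
``(vertex, +-1)``; a step with orientation -1 contributes the reverse
complement of the vertex label.  Consecutive steps ``<v,o>, <v',o'>`` are
joined by the edge ``{(v,o), (v',-o')}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quotient import AssignmentVector
from .sequence_io import (
    _COMPLEMENT_BYTES,
    SEPARATOR,
    ConcatenatedText,
    _reverse_complement_lenient,
    complement_char,
)

Side = tuple[int, int]  # (vertex ID, side +-1)
Edge = tuple[Side, Side]  # canonically ordered
Step = tuple[int, int]  # (vertex ID, orientation +-1)


class GraphError(ValueError):
    pass


def edge_key(a: Side, b: Side) -> Edge:
    """Canonical form of a bidirected link: equal to its own flip."""
    return (a, b) if a <= b else (b, a)


def step_edge(u: Step, w: Step) -> Edge:
    """Edge realized by two consecutive path steps."""
    return edge_key((u[0], u[1]), (w[0], -w[1]))


def oriented_label(label: str, o: int) -> str:
    return label if o == 1 else _reverse_complement_lenient(label)


@dataclass
class BidirectedVariationGraph:
    vertices: dict[int, str]
    edges: set[Edge]
    paths: list[tuple[str, list[Step]]]

    # -- basic queries ---------------------------------------------------

    @property
    def node_count(self) -> int:
        return len(self.vertices)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    @property
    def total_label_length(self) -> int:
        return sum(len(lab) for lab in self.vertices.values())

    def is_singular(self) -> bool:
        return all(len(lab) == 1 for lab in self.vertices.values())

    def path_label(self, name: str) -> str:
        for pname, steps in self.paths:
            if pname == name:
                return "".join(
                    oriented_label(self.vertices[v], o) for v, o in steps
                )
        raise KeyError(name)

    def path_steps(self, name: str) -> list[Step]:
        for pname, steps in self.paths:
            if pname == name:
                return steps
        raise KeyError(name)

    def neighbors_on_side(self, v: int, side: int) -> list[Side]:
        """Opposite endpoints of all edges incident to side ``side`` of v."""
        out = []
        for a, b in self.edges:
            if a == (v, side):
                out.append(b)
            if b == (v, side) and a != (v, side):
                out.append(a)
        return out

    def coverage(self, v: int) -> int:
        return sum(
            1 for _, steps in self.paths for w, _ in steps if w == v
        )

    # -- representation axioms -------------------------------------------

    def validate(self) -> None:
        """Check the representation axioms.

        Every vertex occurs in some path, every edge is realized by some
        consecutive step pair, and every consecutive step pair is joined by
        a stored edge.
        """
        if not self.vertices:
            raise GraphError("graph has no vertices")
        for v, lab in self.vertices.items():
            if not lab:
                raise GraphError(f"vertex {v} has an empty label")
        on_paths = set()
        realized = set()
        for name, steps in self.paths:
            if not steps:
                raise GraphError(f"path {name!r} is empty")
            for v, o in steps:
                if v not in self.vertices:
                    raise GraphError(f"path {name!r} visits unknown vertex {v}")
                if o not in (1, -1):
                    raise GraphError(f"bad orientation {o} in path {name!r}")
                on_paths.add(v)
            for u, w in zip(steps, steps[1:]):
                e = step_edge(u, w)
                realized.add(e)
                if e not in self.edges:
                    raise GraphError(
                        f"path {name!r} uses unrecorded edge {e}"
                    )
        orphan = set(self.vertices) - on_paths
        if orphan:
            raise GraphError(f"vertices not on any path: {sorted(orphan)}")
        unrealized = self.edges - realized
        if unrealized:
            raise GraphError(f"unrealized edges: {sorted(unrealized)}")

    # -- canonical form / isomorphism ------------------------------------

    def canonical_form(self):
        """Canonically relabeled copy, comparable across isomorphic graphs.

        Vertices are renumbered by first occurrence along the paths taken in
        name-sorted order, and flipped so that each vertex's first occurrence
        has orientation +1.  For path-covered graphs (the representation
        axioms guarantee coverage) two graphs with identical path names and
        sequences are isomorphic iff their canonical forms are equal.
        """
        mapping: dict[int, int] = {}
        flip: dict[int, int] = {}
        for _, steps in sorted(self.paths, key=lambda x: x[0]):
            for v, o in steps:
                if v not in mapping:
                    mapping[v] = len(mapping) + 1
                    flip[v] = o
        if len(mapping) != len(self.vertices):
            raise GraphError("canonical form requires a path-covered graph")
        labels = tuple(
            oriented_label(self.vertices[v], flip[v])
            for v in sorted(mapping, key=mapping.get)
        )
        edges = frozenset(
            edge_key(
                (mapping[a[0]], a[1] * flip[a[0]]),
                (mapping[b[0]], b[1] * flip[b[0]]),
            )
            for a, b in self.edges
        )
        paths = tuple(
            (name, tuple((mapping[v], o * flip[v]) for v, o in steps))
            for name, steps in sorted(self.paths, key=lambda x: x[0])
        )
        return (labels, edges, paths)


def isomorphic(a: BidirectedVariationGraph, b: BidirectedVariationGraph) -> bool:
    """Isomorphism of two path-covered graphs sharing path names/sequences."""
    return a.canonical_form() == b.canonical_form()


def _paths_to_graph(
    labels: dict[int, str], paths: list[tuple[str, list[Step]]]
) -> BidirectedVariationGraph:
    """Assemble a graph whose edge set is exactly the realized one."""
    edges = {
        step_edge(u, w)
        for _, steps in paths
        for u, w in zip(steps, steps[1:])
    }
    return BidirectedVariationGraph(vertices=labels, edges=edges, paths=paths)


# -- construction from the assignment vector -----------------------------


def build_singular_graph(
    text: ConcatenatedText, assignment: AssignmentVector
) -> BidirectedVariationGraph:
    """Materialize the singular graph encoded by (text, F).

    Vertex v's label is ``s[p]`` for any position with ``F[p] = +v`` (the
    complement for ``-v`` occurrences); the character-consistency invariant
    makes all choices agree.  One path per input sequence; edges are exactly
    those realized by consecutive positions.
    """
    assignment.validate(text)
    body = np.asarray(assignment.F[1:])
    codes = np.frombuffer(text.s.encode("ascii"), dtype=np.uint8)
    nonsep = codes != ord(SEPARATOR)
    absF = np.abs(body)
    signs = np.sign(body)
    # labels: oriented character at the first occurrence of each vertex
    # (the character-consistency invariant makes all occurrences agree)
    ch = codes.copy()
    neg = body < 0
    ch[neg] = _COMPLEMENT_BYTES[ch[neg]]
    uniq, first = np.unique(absF[nonsep], return_index=True)
    labels = {
        int(v): chr(c) for v, c in zip(uniq, ch[nonsep][first])
    }
    # edges realized by consecutive non-separator positions, deduplicated
    # in the canonical (sorted-endpoint) form
    m = nonsep[:-1] & nonsep[1:]
    v1, s1 = absF[:-1][m], signs[:-1][m]
    v2, s2 = absF[1:][m], -signs[1:][m]
    swap = (v1 > v2) | ((v1 == v2) & (s1 > s2))
    # pack each canonically ordered side pair into one int64 for fast dedup
    a = (np.where(swap, v2, v1) << 1) | (np.where(swap, s2, s1) > 0)
    b = (np.where(swap, v1, v2) << 1) | (np.where(swap, s1, s2) > 0)
    edges = set()
    for code in np.unique((a << 32) | b).tolist():
        hi, lo = code >> 32, code & 0xFFFFFFFF
        edges.add(
            (
                (hi >> 1, 1 if hi & 1 else -1),
                (lo >> 1, 1 if lo & 1 else -1),
            )
        )
    paths: list[tuple[str, list[Step]]] = []
    absl = absF.tolist()
    sgnl = signs.tolist()
    for i, name in enumerate(text.names, start=1):
        start = text.boundaries[i - 1] - 1  # 0-based into the arrays
        length = text.sequence_length(i)
        steps = list(
            zip(absl[start : start + length], sgnl[start : start + length])
        )
        paths.append((name, steps))
    return BidirectedVariationGraph(
        vertices=labels, edges=edges, paths=paths
    )


# -- unbranched path compression -----------------------------------------

_BRANCH = "#"  # sentinel context value: side touches >1 oriented label


@dataclass
class _SideContexts:
    """Per-vertex oriented neighbor characters, normalized to +1 orientation.

    ``left[v]``/``right[v]`` hold the single oriented neighbor character seen
    on that side ('$' at sequence ends), or the branch sentinel on any
    disagreement or immediate-inversion adjacency.
    """

    left: dict[int, str] = field(default_factory=dict)
    right: dict[int, str] = field(default_factory=dict)

    def _update(self, table: dict[int, str], v: int, ch: str) -> None:
        cur = table.get(v)
        if cur is None:
            table[v] = ch
        elif cur != ch:
            table[v] = _BRANCH

    def mark_branch(self, v: int, side: int) -> None:
        table = self.right if side == 1 else self.left
        table[v] = _BRANCH

    def observe(self, v: int, o: int, prev_ch: str, next_ch: str) -> None:
        # normalize the (prev, next) pair seen along the path to the
        # vertex's +1 orientation
        if o == 1:
            lc, rc = prev_ch, next_ch
        else:
            lc, rc = complement_char(next_ch), complement_char(prev_ch)
        self._update(self.left, v, lc)
        self._update(self.right, v, rc)

    def mergeable(self, v: int, side: int) -> bool:
        ch = (self.right if side == 1 else self.left).get(v)
        return ch is not None and ch != _BRANCH and ch != SEPARATOR


def _side_contexts(graph: BidirectedVariationGraph) -> _SideContexts:
    ctx = _SideContexts()
    labels = graph.vertices
    for _, steps in graph.paths:
        m = len(steps)
        for idx, (v, o) in enumerate(steps):
            prev_ch = (
                oriented_label(labels[steps[idx - 1][0]], steps[idx - 1][1])
                if idx > 0
                else SEPARATOR
            )
            next_ch = (
                oriented_label(labels[steps[idx + 1][0]], steps[idx + 1][1])
                if idx < m - 1
                else SEPARATOR
            )
            ctx.observe(v, o, prev_ch, next_ch)
            # immediate inversions: the same vertex re-entered on the side
            # it was just left through can never be merged across
            if idx > 0 and steps[idx - 1] == (v, -o):
                ctx.mark_branch(v, -o)
            if idx < m - 1 and steps[idx + 1] == (v, -o):
                ctx.mark_branch(v, o)
    return ctx


def _side_contexts_fast(
    text: ConcatenatedText, assignment: AssignmentVector
) -> _SideContexts:
    """Vectorized context classification straight from (text, F).

    Produces exactly the contexts of :func:`_side_contexts` for the graph
    built from this text and assignment: the oriented neighbor characters
    of an occurrence are the raw text characters around it ('$' included),
    swapped and complemented for -1-oriented occurrences.
    """
    body = np.asarray(assignment.F[1:])
    codes = np.frombuffer(text.s.encode("ascii"), dtype=np.uint8)
    nonsep = codes != ord(SEPARATOR)
    absF = np.abs(body)
    sgn = np.sign(body)
    dollar = np.uint8(ord(SEPARATOR))
    prev = np.concatenate([[dollar], codes[:-1]])
    nxt = np.concatenate([codes[1:], [dollar]])
    comp = _COMPLEMENT_BYTES
    pos = sgn > 0
    lc = np.where(pos, prev, comp[nxt])[nonsep]
    rc = np.where(pos, nxt, comp[prev])[nonsep]
    v_ns = absF[nonsep]
    order = np.argsort(v_ns, kind="stable")
    vs, lcs, rcs = v_ns[order], lc[order], rc[order]
    starts = np.concatenate([[0], np.nonzero(vs[1:] != vs[:-1])[0] + 1])
    ctx = _SideContexts()
    left, right = ctx.left, ctx.right
    for v, lmin, lmax, rmin, rmax in zip(
        vs[starts].tolist(),
        np.minimum.reduceat(lcs, starts).tolist(),
        np.maximum.reduceat(lcs, starts).tolist(),
        np.minimum.reduceat(rcs, starts).tolist(),
        np.maximum.reduceat(rcs, starts).tolist(),
    ):
        left[v] = chr(lmin) if lmin == lmax else _BRANCH
        right[v] = chr(rmin) if rmin == rmax else _BRANCH
    # immediate inversions: the vertex is re-entered through the side it
    # was just left through (F[p+1] = -F[p] within one sequence)
    both = nonsep[:-1] & nonsep[1:]
    inv = both & (body[1:] == -body[:-1])
    for v, s in zip(absF[:-1][inv].tolist(), sgn[:-1][inv].tolist()):
        ctx.mark_branch(v, s)
    return ctx


def _contraction_map(
    graph: BidirectedVariationGraph, ctx: _SideContexts
) -> dict[Side, Step]:
    """For each mergeable side with a contractible edge, the continuation step.

    ``nxt[(v, o)]`` is the oriented step that follows ``(v, o)`` inside its
    chain: the edge out of side ``o`` of v leads into side ``s`` of w, which
    a walk traverses with orientation ``-s``.
    """
    incident: dict[Side, list[Side]] = {}
    for a, b in graph.edges:
        incident.setdefault(a, []).append(b)
        if b != a:
            incident.setdefault(b, []).append(a)
    nxt: dict[Side, Step] = {}
    for (v, side), others in incident.items():
        if len(others) != 1 or not ctx.mergeable(v, side):
            continue
        (w, wside) = others[0]
        if not ctx.mergeable(w, wside):
            continue
        if (w, wside) == (v, side):
            continue  # same-side self link is never contractible
        nxt[(v, side)] = (w, -wside)
    return nxt


def _chains(
    graph: BidirectedVariationGraph, nxt: dict[Side, Step]
) -> list[list[Step]]:
    """Maximal unbranched chains as oriented walks.

    Each chain is a list of oriented steps; plain chains are oriented so the
    lowest-ID endpoint has orientation +1, and chains that close into cycles
    with no boundary at all are broken at their lowest-ID vertex.
    """
    assigned: set[int] = set()
    chains: list[list[Step]] = []
    for v0 in sorted(graph.vertices):
        if v0 in assigned:
            continue
        chain: list[Step] = [(v0, 1)]
        members = {v0}
        is_cycle = False
        # extend forward out of the current last step's exit side
        while True:
            cur = chain[-1]
            step = nxt.get((cur[0], cur[1]))
            if step is None:
                break
            if step[0] in members:
                # closed into a cycle: break at the starting (lowest-ID) vertex
                is_cycle = step[0] == v0
                break
            chain.append(step)
            members.add(step[0])
        if not is_cycle:
            # extend backward out of the first step's entry side
            while True:
                cur = chain[0]
                step = nxt.get((cur[0], -cur[1]))
                if step is None:
                    break
                if step[0] in members:
                    break
                chain.insert(0, (step[0], -step[1]))
                members.add(step[0])
            # orient the chain so its lowest-ID endpoint has orientation +1
            low = min(chain[0][0], chain[-1][0])
            low_o = chain[0][1] if chain[0][0] == low else chain[-1][1]
            if low_o == -1:
                chain = [(v, -o) for v, o in reversed(chain)]
        assigned |= members
        chains.append(chain)
    return chains


def compress_unbranched(
    graph: BidirectedVariationGraph,
    text: ConcatenatedText | None = None,
    assignment: AssignmentVector | None = None,
) -> BidirectedVariationGraph:
    """Contract every maximal unbranched chain into a single vertex.

    A classification pass over all path occurrences assigns each vertex its
    oriented neighbor characters per side (with '$' at sequence ends); any
    disagreement, and any immediate inversion (a step followed by the same
    vertex with flipped orientation), marks the side as branching.  An edge
    is contracted iff both of its sides are non-branching with a unique
    non-'$' neighbor character — by k-completeness a unique oriented label
    determines a unique neighbor, so the contraction preserves all path
    labels.  The result is the unique maximal contraction: splitting each
    compressed vertex back into characters recovers the input graph up to
    isomorphism.

    ``text``/``assignment`` are accepted for pipeline symmetry and checked
    for consistency when given; the paths of a singular graph carry the
    same information.
    """
    if not graph.is_singular():
        raise GraphError("compression requires a singular graph")
    if text is not None and assignment is not None:
        assignment.validate(text)
        ctx = _side_contexts_fast(text, assignment)
    else:
        ctx = _side_contexts(graph)
    nxt = _contraction_map(graph, ctx)
    chains = _chains(graph, nxt)
    chains.sort(key=lambda ch: min(v for v, _ in ch))
    where: dict[int, tuple[int, int, int]] = {}  # v -> (chain ID, index, orient)
    labels: dict[int, str] = {}
    chain_steps: dict[int, list[Step]] = {}
    for cid, chain in enumerate(chains, start=1):
        labels[cid] = "".join(
            oriented_label(graph.vertices[v], o) for v, o in chain
        )
        chain_steps[cid] = chain
        for idx, (v, o) in enumerate(chain):
            where[v] = (cid, idx, o)
    new_paths: list[tuple[str, list[Step]]] = []
    for name, steps in graph.paths:
        out: list[Step] = []
        i = 0
        m = len(steps)
        while i < m:
            v, o = steps[i]
            cid, idx, corient = where[v]
            chain = chain_steps[cid]
            L = len(chain)
            step_o = o * corient
            if L == 1:  # singleton chains are trivially consistent
                out.append((cid, step_o))
                i += 1
                continue
            # a path can only enter a chain at one of its ends (interior
            # sides carry exactly one edge), and once entered the interior
            # steps are forced; checking the entry point suffices
            if (
                i + L > m
                or (step_o == 1 and idx != 0)
                or (step_o == -1 and idx != L - 1)
            ):
                raise GraphError(
                    f"path {name!r} enters chain {cid} without traversing it"
                )
            out.append((cid, step_o))
            i += L
        new_paths.append((name, out))
    compressed = _paths_to_graph(labels, new_paths)
    compressed.validate()
    return compressed


def split_to_singular(
    graph: BidirectedVariationGraph,
) -> BidirectedVariationGraph:
    """Split every vertex into a chain of single-character vertices.

    The inverse of compression up to isomorphism; paths are rewritten so
    that a -1-oriented step traverses its chain in reverse with flipped
    orientations.
    """
    mapping: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    nid = 0
    for v in sorted(graph.vertices):
        lab = graph.vertices[v]
        ids = []
        for ch in lab:
            nid += 1
            labels[nid] = ch
            ids.append(nid)
        mapping[v] = ids
    new_paths: list[tuple[str, list[Step]]] = []
    for name, steps in graph.paths:
        out: list[Step] = []
        for v, o in steps:
            ids = mapping[v]
            if o == 1:
                out.extend((c, 1) for c in ids)
            else:
                out.extend((c, -1) for c in reversed(ids))
        new_paths.append((name, out))
    split = _paths_to_graph(labels, new_paths)
    split.validate()
    return split


# -- GFA 1.0 -------------------------------------------------------------


def _orient_char(o: int) -> str:
    return "+" if o == 1 else "-"


def write_gfa(graph: BidirectedVariationGraph, path: str | Path) -> None:
    """Serialize as GFA 1.0 with S/L/P lines and 0M overlaps.

    A step ``<v,+1>`` maps to ``v+``; a bidirected edge ``{(v,o), (w,o')}``
    serializes as ``L v o w -o' 0M`` (one line per canonical edge).
    """
    lines = ["H\tVN:Z:1.0"]
    for v in sorted(graph.vertices):
        lines.append(f"S\t{v}\t{graph.vertices[v]}")
    for (v, o), (w, o2) in sorted(graph.edges):
        lines.append(
            f"L\t{v}\t{_orient_char(o)}\t{w}\t{_orient_char(-o2)}\t0M"
        )
    for name, steps in graph.paths:
        body = ",".join(f"{v}{_orient_char(o)}" for v, o in steps)
        lines.append(f"P\t{name}\t{body}\t*")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gfa(path: str | Path) -> BidirectedVariationGraph:
    """Parse blunt (0M-overlap) GFA 1.0 written by :func:`write_gfa`."""
    vertices: dict[int, str] = {}
    edges: set[Edge] = set()
    paths: list[tuple[str, list[Step]]] = []
    orient = {"+": 1, "-": -1}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        tag = fields[0]
        try:
            if tag == "H":
                continue
            elif tag == "S":
                vertices[int(fields[1])] = fields[2]
            elif tag == "L":
                v, fo, w, to, overlap = (
                    int(fields[1]),
                    orient[fields[2]],
                    int(fields[3]),
                    orient[fields[4]],
                    fields[5],
                )
                if overlap not in ("0M", "*"):
                    raise GraphError(
                        f"line {lineno}: only blunt (0M) links supported, "
                        f"got {overlap!r}"
                    )
                edges.add(edge_key((v, fo), (w, -to)))
            elif tag == "P":
                steps = []
                for item in fields[2].split(","):
                    steps.append((int(item[:-1]), orient[item[-1]]))
                paths.append((fields[1], steps))
            # other record types ignored
        except GraphError:
            raise
        except (IndexError, KeyError, ValueError) as exc:
            raise GraphError(f"malformed GFA line {lineno}: {raw!r}") from exc
    graph = BidirectedVariationGraph(
        vertices=vertices, edges=edges, paths=paths
    )
    for name, steps in paths:
        for v, _ in steps:
            if v not in vertices:
                raise GraphError(
                    f"path {name!r} references unknown segment {v}"
                )
    for (v, _), (w, _) in edges:
        if v not in vertices or w not in vertices:
            raise GraphError(f"link references unknown segment {v} or {w}")
    return graph
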