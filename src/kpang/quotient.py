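"""The quotient core: constrained BFS over the implicit bipartite graph.

Positions of the concatenated text form one part of a bipartite graph; the
canonical k-mers form the other.  An edge of *color* c joins position p to
k-mer b when p can be extended to an occurrence of b in which it is the c-th
character of the canonical form.  A BFS that may change color at positions
but must keep it at k-mer nodes visits exactly one equivalence class of the
merge relation per run: positions that must share a vertex in the
k-complete, k-faithful singular bidirected variation graph.

Only the occurrences recorded in K/R are stored; covering occurrences of a
position and the member positions of a (k-mer, color) pair are derived with
offset arithmetic.  For a forward occurrence starting at a, position a+c-1
has color c; for a reverse occurrence starting at a, position a+k-c has
color c (so the focal character is the complement of canonical character c).

Queue growth is bounded by the canonical-member rule: for every
(k-mer, color) pair, the member with the lowest position is *canonical*;
only the canonical member may fan out to all other members, everyone else
enqueues just the canonical member.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .kmer_index import KmerError, KmerIndex
from .sequence_io import _COMPLEMENT_BYTES, SEPARATOR, ConcatenatedText


class QuotientError(RuntimeError):
    """Internal inconsistency during the quotient BFS (indicates a bug)."""


@dataclass(frozen=True)
class CoveringOccurrence:
    """A k-mer occurrence covering a focal position.

    ``color`` is the 1-based offset of the focal position within the
    canonical k-mer's label; ``sign`` is the strand of the occurrence
    (the sign of ``K[start]``).
    """

    kmer_id: int
    start: int
    sign: int
    color: int


@dataclass(frozen=True)
class AssignmentVector:
    """Signed position -> vertex map produced by the quotient algorithm.

    ``|F[p]|`` is the vertex ID at position p (0 exactly at separators);
    the sign is the vertex orientation at p: +1 means the vertex's canonical
    label equals ``s[p]``, -1 means it equals its complement.  Vertex IDs
    form the contiguous range ``1..num_vertices``.
    """

    F: np.ndarray  # 1-based; F[0] unused
    num_vertices: int

    def vertex(self, p: int) -> int:
        return int(abs(self.F[p]))

    def orientation(self, p: int) -> int:
        return 1 if self.F[p] > 0 else -1

    def validate(self, text: ConcatenatedText) -> None:
        """Check completeness and per-class character consistency."""
        F = self.F
        if len(F) != len(text.s) + 1:
            raise QuotientError("assignment length mismatch")
        body = np.asarray(F[1:])
        codes = np.frombuffer(text.s.encode("ascii"), dtype=np.uint8)
        sep = codes == ord(SEPARATOR)
        if (body[sep] != 0).any():
            raise QuotientError("separator position assigned")
        if (body[~sep] == 0).any():
            raise QuotientError("sequence position left unassigned")
        absF = np.abs(body[~sep])
        ch = codes[~sep].copy()
        neg = body[~sep] < 0
        ch[neg] = _COMPLEMENT_BYTES[ch[neg]]
        order = np.argsort(absF, kind="stable")
        va, ca = absF[order], ch[order]
        same = va[1:] == va[:-1]
        if (ca[1:][same] != ca[:-1][same]).any():
            raise QuotientError("a vertex carries inconsistent characters")
        uniq = va[np.concatenate([[True], ~same])] if len(va) else va
        if (
            len(uniq) != self.num_vertices
            or (len(uniq) and (uniq[0] != 1 or uniq[-1] != self.num_vertices))
        ):
            raise QuotientError("vertex IDs are not contiguous")


def covering_occurrences(
    index: KmerIndex, p: int
) -> list[CoveringOccurrence]:
    """All stored k-mer occurrences whose window covers position ``p``."""
    if index.text.is_separator(p):
        raise ValueError(f"position {p} is a separator")
    k = index.k
    K = index.K
    out = []
    for q in range(k):
        start = p - q
        if start < 1:
            break
        Ks = int(K[start])
        if Ks == 0:
            continue
        if Ks > 0:
            out.append(CoveringOccurrence(Ks, start, 1, q + 1))
        else:
            out.append(CoveringOccurrence(-Ks, start, -1, k - q))
    return out


def occurrence_positions(
    index: KmerIndex, kmer_id: int, color: int
) -> list[tuple[int, int]]:
    """Positions (with strand signs) that a (k-mer, color) pair ties together.

    For every start in ``R[kmer_id]``: a forward occurrence contributes
    ``(start+color-1, +1)``, a reverse one ``(start+k-color, -1)``.  These
    are exactly the positions that must share one vertex; the signs give
    their relative orientations.
    """
    if not 1 <= kmer_id <= index.M:
        raise KmerError(f"k-mer ID {kmer_id} out of range 1..{index.M}")
    if not 1 <= color <= index.k:
        raise KmerError(f"color {color} out of range 1..{index.k}")
    K = index.K
    k = index.k
    return [
        (start + color - 1, 1) if K[start] > 0 else (start + k - color, -1)
        for start in index.R[kmer_id]
    ]


def quotient(index: KmerIndex, text: ConcatenatedText) -> AssignmentVector:
    """Compute the signed assignment vector F by repeated constrained BFS.

    Seeds are scanned in ascending position order; each run allocates the
    next vertex ID and fixes the class's canonical orientation to +1 at the
    seed.  The resulting partition of non-separator positions equals the
    equivalence closure of the shared-k-mer relation over both strands, and
    any traversal order yields an isomorphic graph; the ascending-seed
    discipline merely pins a canonical labeling.
    """
    s = text.s
    n = len(s)
    k = index.k
    K = index.K.tolist()  # plain ints are much faster in the BFS loop
    R = index.R
    F = [0] * (n + 1)
    # (k-mer, color) pairs are keyed as j*(k+1)+c into a visited byte table
    # and a canonical-member cache; both are O(kM) and avoid tuple hashing
    kk = k + 1
    expanded = bytearray((index.M + 1) * kk)
    canon_cache: dict[int, tuple[int, int]] = {}
    # a position can only merge with another through a k-mer that occurs
    # more than once; flag such starts and the positions they cover so the
    # BFS crosses unique regions at byte-lookup cost
    counts = np.zeros(index.M + 1, dtype=np.int64)
    for j in range(1, index.M + 1):
        counts[j] = len(R[j])
    multi_start = counts[np.abs(index.K)] > 1
    cs = np.cumsum(multi_start.astype(np.int64))
    lo_idx = np.maximum(np.arange(n + 1) - k, 0)
    multi = bytearray(multi_start.tobytes())
    covered = bytearray(((cs - cs[lo_idx]) > 0).tobytes())
    # strand-signed occurrence lists (+start forward, -start reverse) let
    # the member loops run without consulting K
    starts_all = np.nonzero(index.K)[0]
    vals = index.K[starts_all]
    ids = np.abs(vals)
    order = np.argsort(ids, kind="stable")
    cut = np.searchsorted(ids[order], np.arange(2, index.M + 1))
    signed = np.where(vals > 0, starts_all, -starts_all)[order]
    RS: list = [None]
    RS.extend(g.tolist() for g in np.split(signed, cut))
    sep = SEPARATOR
    v = 0
    queue: deque[int] = deque()
    append = queue.append
    popleft = queue.popleft
    for p0 in range(1, n + 1):
        if s[p0 - 1] == sep or F[p0]:
            continue
        v += 1
        F[p0] = v
        if not covered[p0]:
            continue  # no repeated k-mer covers p0: a singleton class
        append(p0)
        while queue:
            p = popleft()
            fsign = 1 if F[p] > 0 else -1
            lo = p - k + 1
            if lo < 1:
                lo = 1
            for start in range(lo, p + 1):
                if not multi[start]:
                    continue
                Ks = K[start]
                if Ks > 0:
                    j = Ks
                    sign_in = 1
                    c = p - start + 1
                else:
                    j = -Ks
                    sign_in = -1
                    c = k - (p - start)
                key = j * kk + c
                if expanded[key]:
                    continue
                Rj = RS[j]
                cm1 = c - 1
                kmc = k - c
                # the canonical member is cached only for long occurrence
                # lists, where recomputation would be the dominant cost;
                # short lists are cheaper to rescan than to cache
                cache_it = len(Rj) > 8
                canon = canon_cache.get(key) if cache_it else None
                if canon is None:
                    cpos = n + 1
                    csign = 1
                    for s0 in Rj:
                        if s0 > 0:
                            q = s0 + cm1
                            sgn = 1
                        else:
                            q = kmc - s0
                            sgn = -1
                        if q < cpos:
                            cpos = q
                            csign = sgn
                    if cache_it and cpos != p:
                        canon_cache[key] = (cpos, csign)
                else:
                    cpos, csign = canon
                if cpos == p:
                    target = fsign * sign_in * v
                    for s0 in Rj:
                        if s0 > 0:
                            p2 = s0 + cm1
                            want = target
                        else:
                            p2 = kmc - s0
                            want = -target
                        f2 = F[p2]
                        if f2 == 0:
                            F[p2] = want
                            append(p2)
                        elif f2 != want:
                            raise QuotientError(
                                "orientation conflict at position "
                                f"{p2}: have {f2}, derived {want}"
                            )
                    expanded[key] = 1
                else:
                    want = fsign * sign_in * csign * v
                    f2 = F[cpos]
                    if f2 == 0:
                        F[cpos] = want
                        append(cpos)
                    elif f2 != want:
                        raise QuotientError(
                            "orientation conflict at canonical position "
                            f"{cpos}: have {f2}, derived {want}"
                        )
    return AssignmentVector(F=np.asarray(F, dtype=np.int64), num_vertices=v)
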