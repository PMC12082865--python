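"""Canonical k-mer indexing: the signed ID vector K and inverted index R.

For an odd k, every window of the concatenated text is either invalid
(spans a separator, contains a masked character, or runs past the end) or
carries a signed ID: ``K[i] = +j`` when ``s[i..i+k-1]`` equals the canonical
k-mer with ID ``j`` and ``-j`` when it equals its reverse complement.
Odd-length DNA strings are never reverse-complement palindromes, so the sign
is always well defined.  IDs are assigned in order of first occurrence while
scanning left to right, which pins every downstream output to a deterministic
labeling.  ``R[j]`` lists the ascending start positions of k-mer ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import (
    DNA_ALPHABET,
    ConcatenatedText,
    SequenceCollection,
    concatenate,
    reverse_complement,
)

# positions and K are 1-based: index 0 of every vector is an unused sentinel.

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_MAX_VECTORIZED_K = 31  # 2 bits/base must fit an int64


class KmerError(ValueError):
    pass


def _require_odd(k: int) -> None:
    if k < 1 or k % 2 == 0:
        raise KmerError(f"k must be a positive odd integer, got {k}")


def canonicalize_kmer(kmer: str) -> tuple[str, int]:
    """Return ``(canonical, sign)`` for an odd-length A/C/G/T k-mer.

    The canonical form is the lexicographic minimum of the k-mer and its
    reverse complement; sign is +1 when the k-mer itself is canonical.
    """
    _require_odd(len(kmer))
    if not DNA_ALPHABET.issuperset(kmer):
        raise KmerError(f"k-mer {kmer!r} contains non-ACGT characters")
    rc = reverse_complement(kmer)
    # odd length => kmer != rc, so the comparison is strict
    return (kmer, 1) if kmer < rc else (rc, -1)


@dataclass(frozen=True)
class KmerIndex:
    """The signed canonical k-mer ID vector and its inverted index.

    ``K`` has length ``len(s)+1`` with index 0 unused.  ``R`` is a list whose
    entry ``R[j]`` (``R[0]`` is ``None``) holds the ascending 1-based start
    positions of canonical k-mer ``j``; ``M`` is the number of distinct
    canonical k-mers.
    """

    k: int
    K: np.ndarray
    R: list
    M: int
    text: ConcatenatedText

    def kmer_label(self, j: int) -> str:
        """Recover the canonical k-mer string with ID ``j``."""
        if not 1 <= j <= self.M:
            raise KmerError(f"k-mer ID {j} out of range 1..{self.M}")
        start = int(self.R[j][0])
        window = self.text.s[start - 1 : start - 1 + self.k]
        return window if self.K[start] > 0 else reverse_complement(window)

    def occurrence_count(self, j: int) -> int:
        if not 1 <= j <= self.M:
            raise KmerError(f"k-mer ID {j} out of range 1..{self.M}")
        return len(self.R[j])


def _build_codes(s: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window scan: (valid starts 0-based, canonical codes, signs)."""
    base = _BASE_CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    n = len(s)
    nw = n - k + 1
    if nw <= 0:
        return (np.empty(0, np.int64),) * 3
    bad = (base < 0).astype(np.int64)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    window_bad = cbad[k:] - cbad[:-k]  # invalid chars per window
    valid = window_bad == 0
    b = np.where(base < 0, 0, base)
    fwd = np.zeros(nw, dtype=np.int64)
    rc = np.zeros(nw, dtype=np.int64)
    for t in range(k):
        fwd = (fwd << 2) | b[t : t + nw]
        rc |= (3 - b[t : t + nw]) << (2 * t)
    canon = np.minimum(fwd, rc)
    sign = np.where(fwd <= rc, 1, -1).astype(np.int64)
    starts = np.nonzero(valid)[0]
    return starts, canon[starts], sign[starts]


def _build_codes_slow(s: str, k: int):
    """String-based fallback for k too large for 2-bit packing."""
    starts, canon, sign = [], [], []
    for i in range(len(s) - k + 1):
        window = s[i : i + k]
        if not DNA_ALPHABET.issuperset(window):
            continue
        c, sg = canonicalize_kmer(window)
        starts.append(i)
        canon.append(c)
        sign.append(sg)
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(canon, dtype=object),
        np.asarray(sign, dtype=np.int64),
    )


def build_kmer_index(text: ConcatenatedText, k: int) -> KmerIndex:
    """Scan the text once and build K, R and M.

    Invalid windows get ``K=0``, which is what confines k-mers within single
    sequences (every window touching a separator or masked character is
    dropped).  Sequences shorter than k simply yield all-zero windows.
    """
    _require_odd(k)
    s = text.s
    if k <= _MAX_VECTORIZED_K:
        starts0, canon, sign = _build_codes(s, k)
    else:
        starts0, canon, sign = _build_codes_slow(s, k)
    K = np.zeros(len(s) + 1, dtype=np.int64)
    if len(starts0) == 0:
        return KmerIndex(k=k, K=K, R=[None], M=0, text=text)
    # factorize assigns codes in order of first appearance == scan order
    ids, _ = pd.factorize(canon, sort=False)
    M = int(ids.max()) + 1
    starts1 = starts0 + 1  # to 1-based
    K[starts1] = sign * (ids + 1)
    # group ascending starts by ID
    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    cut = np.searchsorted(sorted_ids, np.arange(1, M))
    groups = np.split(starts1[order], cut)
    R: list = [None]
    R.extend(g.tolist() for g in groups)
    return KmerIndex(k=k, K=K, R=R, M=M, text=text)


def rare_kmer_fraction(
    collection: SequenceCollection, k: int, *, by: str = "distinct"
) -> float:
    """Fraction of rare canonical k-mers (total occurrence count exactly 1).

    ``by='distinct'`` (default) divides by the number of distinct canonical
    k-mers M; ``by='occurrence'`` divides by the total occurrence count.
    """
    if by not in ("distinct", "occurrence"):
        raise ValueError(f"unknown base {by!r}")
    _require_odd(k)
    index = build_kmer_index(concatenate(collection), k)
    if index.M == 0:
        raise KmerError(f"no valid k-mer window for k={k}")
    counts = np.fromiter(
        (len(index.R[j]) for j in range(1, index.M + 1)),
        dtype=np.int64,
        count=index.M,
    )
    rare = int((counts == 1).sum())
    denom = index.M if by == "distinct" else int(counts.sum())
    return rare / denom


@dataclass(frozen=True)
class KSelection:
    """Outcome of the rare-k-mer-based k selection."""

    k: int
    fraction: float
    reached_target: bool
    evaluated: tuple[tuple[int, float], ...]


def _fraction_or_zero(collection: SequenceCollection, k: int) -> float:
    try:
        return rare_kmer_fraction(collection, k)
    except KmerError:
        return 0.0  # k larger than every sequence: nothing is indexable


def select_k(
    collection: SequenceCollection,
    target_fraction: float = 0.05,
    k_min: int = 3,
    k_max: int = 41,
) -> KSelection:
    """Smallest odd k in [k_min, k_max] whose rare fraction reaches the target.

    The rare fraction grows approximately monotonically with k for real
    collections, so a coarse grid of odd k values is evaluated first and the
    bracketing interval is then scanned linearly.  If no k reaches the target
    the result carries ``k_max`` with ``reached_target=False``.
    """
    _require_odd(k_min)
    _require_odd(k_max)
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    ks = list(range(k_min, k_max + 1, 2))
    evaluated: dict[int, float] = {}

    def frac(k: int) -> float:
        if k not in evaluated:
            evaluated[k] = _fraction_or_zero(collection, k)
        return evaluated[k]

    def result(k: int, reached: bool) -> KSelection:
        return KSelection(
            k=k,
            fraction=frac(k),
            reached_target=reached,
            evaluated=tuple(sorted(evaluated.items())),
        )

    if len(ks) <= 9:
        grid = ks
    else:
        idx = np.unique(
            np.linspace(0, len(ks) - 1, num=8).round().astype(int)
        )
        grid = [ks[i] for i in idx]
    hit = next((g for g in grid if frac(g) >= target_fraction), None)
    if hit is None:
        return result(k_max, False)
    lo = k_min
    for g in grid:
        if g == hit:
            break
        lo = g
    for k in range(lo, hit + 1, 2):
        if frac(k) >= target_fraction:
            return result(k, True)
    return result(hit, True)
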