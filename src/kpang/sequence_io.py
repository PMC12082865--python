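"""FASTA input, sequence normalization and strand arithmetic.

A collection of DNA sequences is handled as an ordered list of named records
plus, for indexing, a single concatenated text in which every sequence is
followed by one ``$`` separator.  All public coordinates are 1-based and
intervals are closed, i.e. ``S[j1..j2]`` includes both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

SEPARATOR = "$"
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# IUPAC-aware table used internally where masked characters may pass through
# (graph labels); the public reverse_complement is strict by contract.
_COMPLEMENT_LENIENT = str.maketrans(
    "ACGTRYSWKMBDHVN$", "TGCAYRSWMKVHDBN$"
)


class SequenceError(ValueError):
    """Raised for malformed sequence input (names, characters, emptiness)."""


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of a plain A/C/G/T string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    Ambiguity characters are rejected; callers must pre-filter.
    """
    if not DNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise SequenceError(
            f"reverse_complement requires A/C/G/T only, got {bad}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def _reverse_complement_lenient(seq: str) -> str:
    """Reverse complement tolerating IUPAC ambiguity codes (N -> N etc.);
    unknown characters pass through unchanged."""
    return seq.translate(_COMPLEMENT_LENIENT)[::-1]


_LENIENT_OK = frozenset("ACGTRYSWKMBDHVN$")

# byte-level complement for vectorized passes; unknown bytes map to
# themselves (masked characters pass through verbatim)
_COMPLEMENT_BYTES = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTRYSWKMBDHVN", b"TGCAYRSWMKVHDBN"):
    _COMPLEMENT_BYTES[_a] = _b


def complement_char(ch: str) -> str:
    """Complement of a single character; '$' and unknown characters map to
    themselves (masked labels pass through verbatim)."""
    return ch.translate(_COMPLEMENT_LENIENT)


@dataclass(frozen=True)
class SequenceCollection:
    """An ordered collection of named DNA sequences.

    ``n`` is the number of sequences and ``N`` the total residue count
    (separators excluded).  Names are unique and non-empty; sequences are
    non-empty and uppercase.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("collection contains no sequences")
        names = [name for name, _ in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise SequenceError(f"duplicate record names: {dupes}")
        for name, seq in self.records:
            if not name:
                raise SequenceError("empty record name")
            if not seq:
                raise SequenceError(f"record {name!r} has zero length")
            if seq != seq.upper():
                raise SequenceError(
                    f"record {name!r} is not normalized to uppercase"
                )
            if SEPARATOR in seq:
                raise SequenceError(f"record {name!r} contains {SEPARATOR!r}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]]
    ) -> "SequenceCollection":
        return cls(tuple((name, seq.upper()) for name, seq in records))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def N(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def sequence(self, name: str) -> str:
        for rec_name, seq in self.records:
            if rec_name == name:
                return seq
        raise KeyError(name)

    @property
    def has_ambiguity(self) -> bool:
        return any(
            not DNA_ALPHABET.issuperset(seq) for _, seq in self.records
        )


def read_fasta(
    path: str | Path, ambiguity_policy: str = "mask"
) -> SequenceCollection:
    """Read a multi-record FASTA file into a :class:`SequenceCollection`.

    Sequences are uppercased.  Under ``strict`` any character outside
    A/C/G/T raises; under ``mask`` (default) such characters are retained
    verbatim — the k-mer index later treats every window containing one as
    non-indexable, so each masked base becomes its own graph vertex.
    """
    if ambiguity_policy not in ("mask", "strict"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if ambiguity_policy == "strict" and not DNA_ALPHABET.issuperset(seq):
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise SequenceError(
                f"record {rec.id!r} contains non-ACGT characters {bad} "
                "(ambiguity_policy='strict')"
            )
        records.append((rec.id, seq))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return SequenceCollection.from_records(records)


@dataclass(frozen=True)
class ConcatenatedText:
    """The indexing text ``s``: sequences in input order, each followed by '$'.

    ``boundaries[i]`` is the 1-based start offset of sequence ``i`` (0-based
    list index) in ``s``.  Non-separator global positions map bijectively to
    local coordinates ``<i, j>`` with 1-based sequence index ``i`` and offset
    ``j``.
    """

    s: str
    names: tuple[str, ...]
    boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.s.count(SEPARATOR) != len(self.names):
            raise SequenceError("separator count does not match record count")
        if not self.s.endswith(SEPARATOR):
            raise SequenceError("text must end with a separator")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def N(self) -> int:
        return len(self.s) - self.n

    def char(self, p: int) -> str:
        """Character at 1-based global position ``p``."""
        return self.s[p - 1]

    def is_separator(self, p: int) -> bool:
        return self.s[p - 1] == SEPARATOR

    def sequence_length(self, i: int) -> int:
        """Length of 1-based sequence ``i``."""
        start = self.boundaries[i - 1]
        end = (
            self.boundaries[i] if i < self.n else len(self.s) + 1
        )
        return end - start - 1

    def global_to_local(self, p: int) -> tuple[int, int]:
        """Map global position ``p`` to ``<i, j>`` (both 1-based)."""
        if not 1 <= p <= len(self.s) or self.is_separator(p):
            raise ValueError(f"position {p} is not a sequence position")
        # boundaries is ascending; find the record containing p
        import bisect

        i = bisect.bisect_right(self.boundaries, p)
        return i, p - self.boundaries[i - 1] + 1

    def local_to_global(self, i: int, j: int) -> int:
        if not 1 <= i <= self.n:
            raise ValueError(f"sequence index {i} out of range")
        if not 1 <= j <= self.sequence_length(i):
            raise ValueError(f"offset {j} out of range for sequence {i}")
        return self.boundaries[i - 1] + j - 1


def concatenate(collection: SequenceCollection) -> ConcatenatedText:
    """Build the concatenated text ``s`` with one '$' after every sequence."""
    parts = []
    boundaries = []
    offset = 1
    for _, seq in collection.records:
        boundaries.append(offset)
        parts.append(seq)
        parts.append(SEPARATOR)
        offset += len(seq) + 1
    return ConcatenatedText(
        s="".join(parts),
        names=collection.names,
        boundaries=tuple(boundaries),
    )
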