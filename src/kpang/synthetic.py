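"""Synthetic haplotype collections with logged ground-truth edits.

The generator emulates a small collection of related haplotypes: one
ancestral i.i.d. sequence, from which each haplotype is derived by
per-base substitutions, short indels, tandem duplications (within-genome
repeats) and segmental inversions (reverse-complemented segments, which
exercise reverse-strand merging).  Every edit is logged with coordinates so
graph-level assertions can be checked against known structure.  Output is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import SequenceCollection, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the haplotype simulator.

    Substitution and indel rates are per ancestral base; inversion and
    duplication rates are expected event counts per haplotype (Poisson).
    Length ranges are inclusive.
    """

    n_haplotypes: int = 10
    length: int = 1000
    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    inversion_rate: float = 0.0
    duplication_rate: float = 0.0
    indel_length_range: tuple[int, int] = (1, 3)
    inversion_length_range: tuple[int, int] = (30, 100)
    duplication_length_range: tuple[int, int] = (10, 50)
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.length < 1:
            raise ValueError("n_haplotypes and length must be positive")
        for name in ("substitution_rate", "indel_rate", "gc_content"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.inversion_rate < 0 or self.duplication_rate < 0:
            raise ValueError("event rates must be non-negative")
        for name in (
            "indel_length_range",
            "inversion_length_range",
            "duplication_length_range",
        ):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"{name}=({lo}, {hi}) is not a valid range")


@dataclass(frozen=True)
class EditEvent:
    """One logged edit: 1-based closed coordinates in the haplotype as it
    was at application time (inversions are applied last, so their
    coordinates are valid in the final sequence)."""

    haplotype: str
    kind: str  # substitution | insertion | deletion | duplication | inversion
    start: int
    end: int
    detail: str = ""


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _apply_substitutions(
    rng: np.random.Generator, seq: list[str], rate: float, name: str,
    log: list[EditEvent],
) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        old = seq[i]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(0, 3)]
        seq[i] = new
        log.append(
            EditEvent(name, "substitution", i + 1, i + 1, f"{old}>{new}")
        )


def _apply_indels(
    rng: np.random.Generator, seq: list[str], cfg: SimulationConfig,
    name: str, log: list[EditEvent],
) -> list[str]:
    if cfg.indel_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < cfg.indel_rate)[0]
    lo, hi = cfg.indel_length_range
    # apply right to left so earlier coordinates stay valid
    for i in reversed(hits):
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5 and len(seq) > size:
            removed = "".join(seq[i : i + size])
            del seq[i : i + size]
            log.append(
                EditEvent(name, "deletion", i + 1, i + len(removed), removed)
            )
        else:
            ins = _random_sequence(rng, size, cfg.gc_content)
            seq[i:i] = list(ins)
            log.append(EditEvent(name, "insertion", i + 1, i + size, ins))
    return seq


def _apply_duplications(
    rng: np.random.Generator, seq: list[str], cfg: SimulationConfig,
    name: str, log: list[EditEvent],
) -> None:
    lo, hi = cfg.duplication_length_range
    for _ in range(int(rng.poisson(cfg.duplication_rate))):
        size = int(rng.integers(lo, hi + 1))
        if size >= len(seq):
            continue
        start = int(rng.integers(0, len(seq) - size))
        segment = seq[start : start + size]
        seq[start + size : start + size] = segment  # tandem copy
        log.append(
            EditEvent(
                name, "duplication", start + 1, start + size,
                f"copy_at={start + size + 1}",
            )
        )


def _apply_inversions(
    rng: np.random.Generator, seq: list[str], cfg: SimulationConfig,
    name: str, log: list[EditEvent],
) -> None:
    lo, hi = cfg.inversion_length_range
    used: list[tuple[int, int]] = []
    for _ in range(int(rng.poisson(cfg.inversion_rate))):
        size = int(rng.integers(lo, hi + 1))
        if size >= len(seq):
            continue
        for _attempt in range(20):
            start = int(rng.integers(0, len(seq) - size))
            span = (start, start + size)
            if all(span[1] <= a or span[0] >= b for a, b in used):
                break
        else:
            continue  # could not place without overlap
        used.append(span)
        segment = "".join(seq[start : start + size])
        seq[start : start + size] = list(reverse_complement(segment))
        log.append(EditEvent(name, "inversion", start + 1, start + size))


def generate_collection(
    config: SimulationConfig,
) -> tuple[SequenceCollection, list[EditEvent]]:
    """Draw an ancestor and derive the haplotypes, logging every edit.

    Edits are applied per haplotype in the order substitutions, indels,
    duplications, inversions; because inversions neither overlap each other
    nor change length, their logged coordinates address the final sequence.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _random_sequence(rng, config.length, config.gc_content)
    records = []
    log: list[EditEvent] = []
    for h in range(1, config.n_haplotypes + 1):
        name = f"hap{h}"
        seq = list(ancestor)
        _apply_substitutions(
            rng, seq, config.substitution_rate, name, log
        )
        seq = _apply_indels(rng, seq, config, name, log)
        _apply_duplications(rng, seq, config, name, log)
        _apply_inversions(rng, seq, config, name, log)
        if not seq:
            raise ValueError(
                f"haplotype {name} became empty; lower the deletion pressure"
            )
        records.append((name, "".join(seq)))
    return SequenceCollection.from_records(records), log


def write_fasta(collection: SequenceCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in collection.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_event_log(events: list[EditEvent], path: str | Path) -> None:
    """Serialize the edit log as TSV for fixture reuse."""
    with open(path, "w") as fh:
        fh.write("haplotype\tkind\tstart\tend\tdetail\n")
        for e in events:
            fh.write(f"{e.haplotype}\t{e.kind}\t{e.start}\t{e.end}\t{e.detail}\n")
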