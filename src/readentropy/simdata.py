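"""Synthetic genomes with planted repeats and closed-form expected entropy loss.

A synthetic genome is an i.i.d. random background with a configurable GC
content into which exact repeat families are planted: a random unit of
known length copied a known number of times, either verbatim (direct) or
reverse-complemented (inverted), optionally adjacent (tandem).  Because
the background is effectively collision-free at the lengths used
(4^k >> L^2 for k >= 21 and L <= 1e5), the k-mer multiset structure —
and hence the entropy loss — of the generated genome is known exactly,
which gives every downstream statistic an analytic oracle.

For a genome of length L with no ambiguity codes there are
N = 2(L - k + 1) substring instances over both strands, and

    H = log10 N - (1/N) * sum over classes with count c >= 2 of c*log10(c)
    dH = [sum c*log10(c) / N] / log10 N

An inverted copy raises dH exactly as a direct one does: the pooled
two-strand multiset already contains the reverse complement of every
window, so copying a unit in either orientation adds multiplicity to the
same pair of k-mer classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fasta_io import SequenceRecord, write_fasta
from .kmer_counting import reverse_complement

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class PlantedRepeat:
    """One exact repeat family to plant.

    copies counts all occurrences of the unit (>= 2).  Direct
    orientation copies the unit verbatim; inverted plants the first copy
    forward and every further copy reverse-complemented.  tandem places
    the copies adjacently as one array; otherwise each copy lands at an
    independent non-overlapping position.
    """

    unit_length: int
    copies: int = 2
    orientation: str = "direct"  # "direct" | "inverted"
    tandem: bool = False

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.copies < 2:
            raise ValueError("copies must be >= 2")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def footprint(self) -> int:
        return self.unit_length * self.copies


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for a reproducible random genome with planted repeats."""

    length: int
    gc_content: float = 0.5
    seed: int = 0
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    ambiguity_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.ambiguity_rate < 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1)")
        object.__setattr__(self, "planted_repeats", tuple(self.planted_repeats))
        if sum(r.footprint for r in self.planted_repeats) > self.length:
            raise ValueError("planted repeat footprint exceeds genome length")


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _materialize(spec: SyntheticGenomeSpec) -> tuple[str, list[tuple[int, int]]]:
    """Build the genome string and the half-open intervals of planted blocks.

    A block is one contiguous planted stretch: a single copy, or the
    whole array for a tandem family.  Any substring window duplicated by
    the planting must overlap at least one block interval (under the
    collision-free background assumption), which is what lets the
    expected-loss oracle enumerate exactly the windows that matter.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _background(rng, spec.length, spec.gc_content)

    occupied: list[tuple[int, int]] = []

    def place(block_len: int) -> int:
        if block_len > spec.length:
            raise ValueError("planted block longer than genome")
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            start = int(rng.integers(0, spec.length - block_len + 1))
            if all(start >= e or start + block_len <= s for s, e in occupied):
                occupied.append((start, start + block_len))
                return start
        raise ValueError("could not place planted repeats without overlap "
                         "(footprint too dense)")

    for fam in spec.planted_repeats:
        unit = _background(rng, fam.unit_length, spec.gc_content).tobytes().decode()
        copies = []
        for i in range(fam.copies):
            if fam.orientation == "inverted" and i > 0:
                copies.append(reverse_complement(unit))
            else:
                copies.append(unit)
        if fam.tandem:
            blocks = ["".join(copies)]
        else:
            blocks = copies
        for block in blocks:
            start = place(len(block))
            seq[start : start + len(block)] = np.frombuffer(
                block.encode(), dtype="S1")

    if spec.ambiguity_rate > 0:
        mask = rng.random(spec.length) < spec.ambiguity_rate
        seq[mask] = b"N"

    return seq.tobytes().decode(), sorted(occupied)


def random_genome(spec: SyntheticGenomeSpec) -> SequenceRecord:
    """Generate the genome described by spec (deterministic per seed)."""
    sequence, _ = _materialize(spec)
    return SequenceRecord(identifier=f"synthetic_seed{spec.seed}", residues=sequence)


def homopolymer_record(length: int, base: str = "A") -> SequenceRecord:
    """A single-letter sequence; its entropy loss has an exact closed form.

    For poly-A of length L >= k the two-strand multiset holds exactly
    two classes (A^k and T^k) of L-k+1 instances each, so
    H = log10(2) and dH = 1 - log10(2)/log10(2(L-k+1)).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if base not in "ACGT":
        raise ValueError("base must be one of A, C, G, T")
    return SequenceRecord(identifier=f"homopolymer_{base}{length}", residues=base * length)


def expected_entropy_loss(spec: SyntheticGenomeSpec, k: int) -> float:
    """Analytic dH^(k) for the genome random_genome(spec) would produce.

    Valid under the collision-free background assumption (4^k >> L^2)
    and only for ambiguity_rate 0, where the instance count is exactly
    N = 2(L - k + 1).  Every k-mer class duplicated by the planting must
    involve a window overlapping a planted block, so enumerating just
    those windows (with their true flanking context, which matters at
    tandem-array junctions) yields the exact multiplicity profile;
    classes with both-strand count c >= 2 contribute c*log10(c) to the
    loss sum and dH = [sum c*log10(c) / N] / log10 N.

    Requires the same seed the generator uses, because the count
    structure depends on the actual planted unit sequences.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > spec.length:
        raise ValueError(f"k={k} exceeds genome length {spec.length}")
    if spec.ambiguity_rate != 0:
        raise ValueError("closed form requires ambiguity_rate == 0")
    N = 2 * (spec.length - k + 1)
    if N <= 1:
        raise ValueError("genome too short for a meaningful entropy loss")

    seq, intervals = _materialize(spec)
    # forward-strand windows overlapping any planted interval
    starts: set[int] = set()
    last_start = spec.length - k
    for s, e in intervals:
        starts.update(range(max(0, s - k + 1), min(last_start, e - 1) + 1))
    fwd: dict[str, int] = {}
    for p in starts:
        kmer = seq[p : p + k]
        fwd[kmer] = fwd.get(kmer, 0) + 1

    loss_sum = 0.0
    seen: set[str] = set()
    for kmer in fwd:
        for cls in (kmer, reverse_complement(kmer)):
            if cls in seen:
                continue
            seen.add(cls)
            # both-strand class count: forward hits of the k-mer plus
            # forward hits of its reverse complement (covers palindromes)
            c = fwd.get(cls, 0) + fwd.get(reverse_complement(cls), 0)
            if c >= 2:
                loss_sum += c * math.log10(c)
    return (loss_sum / N) / math.log10(N)


def write_genome_fasta(spec: SyntheticGenomeSpec, path: str | Path) -> SequenceRecord:
    """Generate a genome, write it as FASTA plus a key=value sidecar.

    The sidecar (<path>.spec.txt) records every generator parameter so a
    run can be reproduced exactly.
    """
    record = random_genome(spec)
    write_fasta([record], path)
    sidecar = Path(str(path) + ".spec.txt")
    lines = [
        f"length={spec.length}",
        f"gc_content={spec.gc_content}",
        f"seed={spec.seed}",
        f"ambiguity_rate={spec.ambiguity_rate}",
    ]
    for i, fam in enumerate(spec.planted_repeats):
        lines.append(
            f"repeat{i}=unit_length:{fam.unit_length},copies:{fam.copies},"
            f"orientation:{fam.orientation},tandem:{fam.tandem}"
        )
    sidecar.write_text("\n".join(lines) + "\n")
    return record
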