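"""Counting the length-k substrings of a sequence set over both strands.

Every position of every record contributes one window on the forward
strand and one on the reverse-complement strand; the two strands are
pooled into a single multiset without canonicalization (a k-mer and its
reverse complement are distinct keys).  Windows containing any non-ACGT
character are skipped and do not contribute to the instance total.

For bounded-memory operation on large genomes the multiset can be split
into disjoint subsets by k-mer prefix: entropy is additive over any
disjoint partition of the substring classes, so each prefix subset can
be counted in its own pass and the partial sums combined.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import AlphabetError, DegenerateInputError
from .fasta_io import SequenceRecord

# IUPAC nucleotide complement (upper-case only; input is sanitized upstream)
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_IUPAC_COMPLEMENT)
_IUPAC_SET = frozenset(_IUPAC_COMPLEMENT)
_ACGT = frozenset("ACGT")


def reverse_complement(s: str) -> str:
    """Reverse-complement a nucleotide string, honouring IUPAC codes.

    Raises
    ------
    AlphabetError
        If a character outside the IUPAC nucleotide alphabet occurs.
    """
    bad = set(s) - _IUPAC_SET
    if bad:
        raise AlphabetError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class PartitionSpec:
    """One prefix class of the disjoint k-mer partition.

    ``prefix is None`` (with prefix_length 0) denotes the trivial
    partition containing every k-mer.
    """

    prefix_length: int
    prefix: Optional[str] = None

    def __post_init__(self) -> None:
        if self.prefix_length < 0:
            raise ValueError("prefix_length must be >= 0")
        if self.prefix is not None and len(self.prefix) != self.prefix_length:
            raise ValueError("prefix length does not match prefix_length")
        if self.prefix is not None and set(self.prefix) - _ACGT:
            raise ValueError("prefix must be over {A,C,G,T}")

    @property
    def is_all(self) -> bool:
        return self.prefix is None


ALL_KMERS = PartitionSpec(prefix_length=0, prefix=None)


@dataclass
class KmerCountTable:
    """The multiset S_k of length-k substrings with occurrence counts.

    ``total_instances`` is the number of substring instances retained in
    this table (sum of counts).  In partitioned mode
    ``skipped_by_prefix`` records how many valid windows fell outside
    the prefix class, so the global instance total across all partitions
    is ``total_instances + skipped_by_prefix``.
    """

    k: int
    counts: Counter = field(default_factory=Counter)
    partition: PartitionSpec = ALL_KMERS
    skipped_by_prefix: int = 0

    @property
    def total_instances(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def global_total_instances(self) -> int:
        return self.total_instances + self.skipped_by_prefix


def partition_prefixes(prefix_length: int) -> list[PartitionSpec]:
    """All 4^m prefix classes of length m, in lexicographic order.

    m = 0 yields the single trivial "all k-mers" partition.
    """
    if prefix_length < 0:
        raise ValueError("prefix_length must be >= 0")
    if prefix_length > 8:
        raise ValueError("prefix_length > 8 would enumerate > 65536 passes")
    if prefix_length == 0:
        return [ALL_KMERS]
    return [
        PartitionSpec(prefix_length, "".join(p))
        for p in itertools.product("ACGT", repeat=prefix_length)
    ]


def _count_strand(seq: str, k: int, prefix: Optional[str], counts: Counter) -> tuple[int, int]:
    """Count k-windows of one strand string; returns (kept, skipped_by_prefix).

    Windows containing a non-ACGT character are excluded entirely.  The
    scan walks maximal ACGT runs so an ambiguity code invalidates
    exactly the windows covering it.
    """
    kept = 0
    skipped = 0
    n = len(seq)
    run_start = 0
    pos = 0
    while pos <= n:
        ch = seq[pos] if pos < n else None
        if ch is None or ch not in _ACGT:
            run_len = pos - run_start
            if run_len >= k:
                for i in range(run_start, pos - k + 1):
                    if prefix is None or seq.startswith(prefix, i):
                        counts[seq[i : i + k]] += 1
                        kept += 1
                    else:
                        skipped += 1
            run_start = pos + 1
        pos += 1
    return kept, skipped


def count_kmers(
    records: Iterable[SequenceRecord],
    k: int,
    partition: PartitionSpec = ALL_KMERS,
) -> KmerCountTable:
    """Count the pooled both-strand k-substring multiset of a record set.

    Records shorter than k contribute nothing.  With a non-trivial
    ``partition`` only k-mers beginning with the prefix are retained;
    valid windows outside the prefix class are tallied in
    ``skipped_by_prefix``.

    Raises
    ------
    ValueError
        k < 1, or a prefix longer than k.
    DegenerateInputError
        No valid window exists on either strand of any record.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if partition.prefix_length > k:
        raise ValueError("partition prefix longer than k")

    table = KmerCountTable(k=k, partition=partition)
    skipped = 0
    for rec in records:
        fwd = rec.residues
        for strand in (fwd, reverse_complement(fwd)):
            _, s = _count_strand(strand, k, partition.prefix, table.counts)
            skipped += s
    table.skipped_by_prefix = skipped
    if table.total_instances + skipped == 0:
        raise DegenerateInputError(
            f"no valid length-{k} windows in input (records too short or all-ambiguous)"
        )
    return table
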