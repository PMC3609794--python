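"""Shannon entropy of the k-substring spectrum and the relative entropy loss.

With N substring instances distributed over classes with counts c_i,

    H      = -sum_i (c_i / N) * log10(c_i / N)
    H_max  = log10(N)                    (attained when every c_i = 1)
    dH     = (H_max - H) / H_max         (relative entropy loss)

Base-10 logarithms throughout.  dH is stored as a fraction in [0, 1];
rendering as a percentage happens only at the I/O layer.  dH > 0.01 (1%)
is the conventional flag for repeat content severe enough to cripple
de novo assembly from reads of length k.

Entropy is additive over any disjoint split of the classes, which is
what makes the prefix-partitioned computation exact:

    H = sum_partitions sum_{i in partition} (c_i / N) * (log10 N - log10 c_i)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, DegenerateInputError
from .fasta_io import SequenceRecord
from .kmer_counting import (
    KmerCountTable,
    count_kmers,
    partition_prefixes,
)

_H_TOLERANCE = 1e-9


@dataclass(frozen=True)
class EntropyResult:
    """Entropy summary of one target sequence set at one read length.

    Attributes
    ----------
    k:
        Read (substring) length in bp.
    H:
        Entropy of the substring distribution, log10 units.
    H_max:
        Maximum attainable entropy log10(total_instances).
    delta_H:
        Relative entropy loss (H_max - H) / H_max, a fraction in [0, 1].
    repeat_fraction:
        Fraction of substring instances whose k-mer occurs >= 2 times.
    total_instances, n_distinct:
        Multiset instance count and number of distinct k-mers.
    """

    k: int
    H: float
    H_max: float
    delta_H: float
    repeat_fraction: float
    total_instances: int
    n_distinct: int


def substring_entropy(table: KmerCountTable) -> float:
    """Shannon entropy (log10) of the normalized count distribution."""
    total = table.total_instances
    if total < 1:
        raise DegenerateInputError("empty k-mer table")
    if table.n_distinct == total:
        # all counts 1: H equals H_max exactly, avoid summation round-off
        return math.log10(total)
    counts = np.fromiter(table.counts.values(), dtype=np.float64, count=len(table.counts))
    p = counts / total
    return float(-np.sum(p * np.log10(p)))


def max_entropy(total_instances: int) -> float:
    """log10 of the instance count: the entropy if every instance were unique."""
    if total_instances < 1:
        raise ValueError(f"total_instances must be >= 1, got {total_instances}")
    return math.log10(total_instances)


def relative_entropy_loss(H: float, H_max: float) -> float:
    """(H_max - H) / H_max, clamped to [0, 1] against round-off.

    Raises
    ------
    ConsistencyError
        If H exceeds H_max beyond floating-point tolerance, or H_max <= 0.
    """
    if H_max <= 0:
        raise ConsistencyError(f"H_max must be > 0, got {H_max}")
    if H > H_max + _H_TOLERANCE:
        raise ConsistencyError(f"H={H} exceeds H_max={H_max}")
    return min(1.0, max(0.0, (H_max - H) / H_max))


def repeat_fraction(table: KmerCountTable) -> float:
    """Fraction of instances belonging to k-mers with count >= 2."""
    total = table.total_instances
    if total < 1:
        raise DegenerateInputError("empty k-mer table")
    repeated = sum(c for c in table.counts.values() if c >= 2)
    return repeated / total


def _repeat_instances(table: KmerCountTable) -> int:
    return sum(c for c in table.counts.values() if c >= 2)


def _partial_entropy_sum(table: KmerCountTable, global_total: int) -> float:
    """-sum (c/N) log10(c/N) over this partition's classes, N global."""
    if not table.counts:
        return 0.0
    counts = np.fromiter(table.counts.values(), dtype=np.float64, count=len(table.counts))
    p = counts / global_total
    return float(-np.sum(p * np.log10(p)))


def _check_disjoint(tables: Sequence[KmerCountTable]) -> None:
    prefixes = [t.partition.prefix or "" for t in tables]
    for i, a in enumerate(prefixes):
        for b in prefixes[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise ConsistencyError(
                    f"partition prefixes overlap: {a or '<all>'} vs {b or '<all>'}"
                )


def entropy_from_partitions(
    partial_tables: Sequence[KmerCountTable],
    global_total: int,
) -> EntropyResult:
    """Assemble a full EntropyResult from prefix-disjoint partial tables.

    Each table contributes -sum (c / global_total) * log10(c / global_total)
    to H; n_distinct and the repeat count add likewise.  Numerically
    identical to the unpartitioned computation.

    Raises
    ------
    ConsistencyError
        Overlapping prefixes, or partial totals not summing to global_total.
    """
    if not partial_tables:
        raise ConsistencyError("no partial tables supplied")
    ks = {t.k for t in partial_tables}
    if len(ks) != 1:
        raise ConsistencyError(f"mixed k values in partitions: {sorted(ks)}")
    _check_disjoint(partial_tables)
    summed = sum(t.total_instances for t in partial_tables)
    if summed != global_total:
        raise ConsistencyError(
            f"partition totals sum to {summed}, expected global_total {global_total}"
        )
    if global_total < 1:
        raise DegenerateInputError("no substring instances")

    k = partial_tables[0].k
    H = 0.0
    n_distinct = 0
    repeated = 0
    for table in partial_tables:
        H += _partial_entropy_sum(table, global_total)
        n_distinct += table.n_distinct
        repeated += _repeat_instances(table)
    H_max = max_entropy(global_total)
    if repeated == 0:
        # every substring unique: H attains H_max exactly (no round-off)
        H = H_max
    if global_total == 1:
        # one instance: zero entropy and zero maximum; dH undefined
        raise DegenerateInputError("single substring instance; entropy loss undefined")
    return EntropyResult(
        k=k,
        H=H,
        H_max=H_max,
        delta_H=relative_entropy_loss(H, H_max),
        repeat_fraction=repeated / global_total,
        total_instances=global_total,
        n_distinct=n_distinct,
    )


def assess(
    records: Iterable[SequenceRecord],
    k: int,
    prefix_length: int = 0,
) -> EntropyResult:
    """Full entropy assessment of a pooled sequence set at read length k.

    With ``prefix_length`` m = 0 the whole multiset is counted in one
    pass.  With m > 0 the input is re-scanned once per length-m prefix
    (4^m passes); resident memory is bounded by the largest prefix
    class, at the cost of time.  The result is identical either way.

    Raises
    ------
    DegenerateInputError
        No valid windows in any record.
    """
    records = list(records)
    m = min(prefix_length, k)
    if m == 0:
        table = count_kmers(records, k)
        return entropy_from_partitions([table], table.total_instances)
    specs = partition_prefixes(m)
    tables = [count_kmers(records, k, spec) for spec in specs]
    global_total = tables[0].global_total_instances
    return entropy_from_partitions(tables, global_total)
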