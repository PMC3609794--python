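import math
from collections import Counter

import pytest

from readentropy import (
    ConsistencyError,
    DegenerateInputError,
    SequenceRecord,
    assess,
    count_kmers,
    entropy_from_partitions,
    max_entropy,
    partition_prefixes,
    relative_entropy_loss,
    repeat_fraction,
    substring_entropy,
)
from readentropy.kmer_counting import KmerCountTable, PartitionSpec

import oracle


def table_from(counts: dict, k: int) -> KmerCountTable:
    return KmerCountTable(k=k, counts=Counter(counts))


class TestSubstringEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"AC": 1, "GT": 1}, math.log10(2)),  # two equiprobable outcomes
            ({"AC": 6}, 0.0),  # single outcome
            ({"AA": 2, "CC": 1, "GG": 1}, 0.5 * math.log10(2) + 0.5 * math.log10(4)),
        ],
    )
    def test_known_distributions(self, counts, expected):
        assert substring_entropy(table_from(counts, 2)) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_degenerate(self):
        with pytest.raises(DegenerateInputError):
            substring_entropy(table_from({}, 2))


class TestMaxEntropy:
    @pytest.mark.parametrize("n,expected", [(1, 0.0), (1000, 3.0)])
    def test_log_of_instances(self, n, expected):
        assert max_entropy(n) == pytest.approx(expected)

    def test_below_one_rejected(self):
        with pytest.raises(ValueError):
            max_entropy(0)


class TestRelativeEntropyLoss:
    def test_published_bac_pair(self):
        # high-repeat BAC insert: H=4.99782, H_max=5.344746 -> 6.49% loss
        assert relative_entropy_loss(4.99782, 5.344746) == pytest.approx(0.0649, abs=5e-5)

    def test_bounds(self):
        assert relative_entropy_loss(2.5, 2.5) == 0.0
        assert relative_entropy_loss(0.0, 3.0) == 1.0

    def test_h_above_hmax_rejected(self):
        with pytest.raises(ConsistencyError):
            relative_entropy_loss(2.0 + 1e-6, 2.0)

    def test_tiny_float_excess_clamped(self):
        assert relative_entropy_loss(2.0 + 1e-12, 2.0) == 0.0


class TestRepeatFraction:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"AA": 3, "TT": 3}, 1.0),
            ({"AC": 1, "GG": 1, "TA": 1}, 0.0),
            ({"AA": 2, "CC": 1, "GG": 1}, 0.5),
        ],
    )
    def test_instance_weighted(self, counts, expected):
        assert repeat_fraction(table_from(counts, 2)) == expected


class TestEntropyFromPartitions:
    def test_single_partition_equals_direct(self, random_seq):
        t = count_kmers([SequenceRecord("g", random_seq(400))], 9)
        res = entropy_from_partitions([t], t.total_instances)
        assert res.H == pytest.approx(substring_entropy(t), abs=1e-15)

    def test_wrong_global_total_rejected(self, random_seq):
        t = count_kmers([SequenceRecord("g", random_seq(100))], 5)
        with pytest.raises(ConsistencyError):
            entropy_from_partitions([t], t.total_instances + 1)

    def test_overlapping_prefixes_rejected(self):
        a = KmerCountTable(3, Counter({"AAA": 1}), PartitionSpec(1, "A"))
        b = KmerCountTable(3, Counter({"AAT": 1}), PartitionSpec(2, "AA"))
        with pytest.raises(ConsistencyError):
            entropy_from_partitions([a, b], 2)

    def test_mixed_k_rejected(self):
        a = KmerCountTable(3, Counter({"AAA": 1}), PartitionSpec(1, "A"))
        b = KmerCountTable(4, Counter({"CCCC": 1}), PartitionSpec(1, "C"))
        with pytest.raises(ConsistencyError):
            entropy_from_partitions([a, b], 2)


class TestAssess:
    def test_palindromic_four_mer(self):
        res = assess([SequenceRecord("a", "ACGT")], 4)
        assert res.H == 0.0
        assert res.H_max == pytest.approx(math.log10(2))
        assert res.delta_H == 1.0
        assert res.repeat_fraction == 1.0

    def test_unique_kmers_give_zero_loss(self, random_seq):
        # a 1 kb random sequence is collision-free at k = 21 w.h.p.
        rec = SequenceRecord("g", random_seq(1000))
        res = assess([rec], 21)
        assert res.delta_H == 0.0
        assert res.repeat_fraction == 0.0
        assert res.n_distinct == res.total_instances

    def test_too_short_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            assess([SequenceRecord("a", "ACG")], 10)

    def test_records_pooled_without_chimeric_windows(self):
        # two records never form windows across the boundary
        joint = assess([SequenceRecord("a", "ACGTACGT"), SequenceRecord("b", "GGGTTT")], 4)
        expected = oracle.entropy_stats(["ACGTACGT", "GGGTTT"], 4)
        assert joint.H == pytest.approx(expected[0], abs=1e-12)
        assert joint.total_instances == expected[4]

    def test_duplicated_segment_closed_form(self, random_seq):
        """If the multiset holds d doubletons and the rest singletons,
        H = log10 N - (2d/N) log10 2."""
        k = 15
        unit = random_seq(40)
        seq = random_seq(300) + unit + random_seq(200) + unit + random_seq(300)
        res = assess([SequenceRecord("g", seq)], k)
        t = count_kmers([SequenceRecord("g", seq)], k)
        assert set(t.counts.values()) == {1, 2}
        d = sum(1 for c in t.counts.values() if c == 2)
        N = res.total_instances
        assert res.H == pytest.approx(math.log10(N) - (2 * d / N) * math.log10(2), abs=1e-12)
        assert res.delta_H == pytest.approx(
            (2 * d / N) * math.log10(2) / math.log10(N), abs=1e-12
        )

    def test_homopolymer_closed_form(self):
        L, k = 200, 12
        res = assess([SequenceRecord("a", "A" * L)], k)
        assert res.H == pytest.approx(math.log10(2), abs=1e-12)
        assert res.H_max == pytest.approx(math.log10(2 * (L - k + 1)), abs=1e-12)

    @pytest.mark.parametrize("m", [0, 1, 2, 3, 4])
    def test_partitioned_equals_direct(self, random_seq, m):
        rec = SequenceRecord("g", random_seq(2000))
        direct = assess([rec], 21, prefix_length=0)
        part = assess([rec], 21, prefix_length=m)
        assert part.H == pytest.approx(direct.H, rel=1e-12)
        assert part.delta_H == pytest.approx(direct.delta_H, abs=1e-12)
        assert part.total_instances == direct.total_instances
        assert part.n_distinct == direct.n_distinct
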