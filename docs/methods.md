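# Methods

## Model

The package treats sequencing as the idealized process of drawing
error-free, fixed-length substrings uniformly from both strands of a
target sequence set. For a target of records r₁…r_j (windows never cross
record boundaries) the observable object at read length k is the multiset
S_k of all length-k windows of every record and of every record's reverse
complement, pooled without canonicalization — a k-mer and its reverse
complement are distinct classes, each carrying its own count. For a
single ambiguity-free linear record of length L, S_k has exactly
N = 2·(L − k + 1) instances.

With class counts c(x) and p(x) = c(x)/N, the statistics are

    H      = − Σ p(x) · log10 p(x)          (spectrum entropy)
    H_max  = log10 N                        (all instances unique)
    ΔH     = (H_max − H) / H_max            (relative entropy loss)

plus a repeat fraction: the share of instances whose k-mer occurs ≥ 2
times. ΔH = 0 iff no repeat of length ≥ k exists; a duplicated segment of
length R ≥ k with copy number c contributes 2·(R − k + 1) classes of count
c and hence c·log10(c) per class to the loss sum, giving the closed form
ΔH = [Σ c·log10 c] / (N · log10 N) over repeated classes.

Logarithms are base 10. This is fixed by the published BAC validation
values bundled in `refdata.py`: the published maximum entropies equal
log10(2·(L − 29)) to ~1e-5, which simultaneously pins the base, the
two-strand pooling and the no-canonicalization convention.

### Assumptions and conventions

- **Error-free reads.** No sequencing-error model; ΔH measures the
  information ceiling of the read length itself.
- **Linear topology.** No wraparound windows, including for prokaryotic
  chromosomes; the effect at genome scale is below reporting precision.
- **Ambiguity codes.** Any window containing a non-ACGT character is
  excluded from both counts and the instance total (the window is
  unobservable, not zero-information). An N invalidates exactly the
  windows covering it on each strand.
- **Multi-record pooling.** All records of one FASTA file are one target;
  chromosomes of one organism are pooled into one score, but no chimeric
  cross-record windows are fabricated.
- **Case folding.** Input is upper-cased before counting; soft-masked
  repeats are ordinary sequence, since the statistic is content-only.
- **Exactness at zero.** When every class has count 1, H is set to
  log10 N exactly rather than accumulated, so "ΔH = 0 iff all substrings
  unique" holds without floating-point leakage. Otherwise accumulation is
  plain double-precision summation (error ≪ 1e-12 at genome scale, far
  below the 1e-6 reporting precision); no compensated summation.

## Prefix-partitioned computation

Entropy is additive over any disjoint split of the classes:

    H = Σ_partitions Σ_{x in partition} (c(x)/N) · (log10 N − log10 c(x))

`assess(records, k, prefix_length=m)` splits S_k into the 4^m classes of
k-mers sharing a length-m prefix (the prefix of the k-mer itself, after
strand expansion — a k-mer and its reverse complement may land in
different partitions, which is correct because the split is by substring
identity). Each partition re-scans the input and holds only its own
distinct k-mers, bounding resident memory at the cost of 4^m passes; the
partial sums combine to a result bit-identical in structure and equal to
the direct computation within 1e-12 relative (asserted by tests at
m = 0…4). Partitions are processed sequentially in lexicographic order;
they are disjoint and combine by summation, so concurrent execution would
be valid. Default m = 0 (direct counting); m = 4–5 is appropriate for
gigabase genomes.

## Decision rules

- **Severity threshold.** ΔH is stored as a fraction and compared against
  0.01; the 1 % default marks the regime where published assembly
  coverage degrades severely. Thresholds are configurable.
- **Minimal read length.** Smallest grid k with ΔH strictly below the
  threshold; no interpolation between grid points; "not reached" if the
  profile never crosses. Default grid 20–120 bp step 10.
- **Insert-size suggestion.** [4·k_min, 6·k_min], a heuristic from the
  observation that short inserts barely spanning the dominant repeats
  resolve local ambiguity better than kilobase inserts. Advisory only.
- **Repeat fraction definition.** Instances belonging to classes with
  count ≥ 2, over the pooled two-strand multiset. This quantity has no
  single canonical definition in the literature; the chosen one is
  monotone with ΔH and reproduces the qualitative pattern of the BAC
  validation set, but its published values are not used as binding
  checks.
- **Survey conventions.** One FASTA file = one replicon; default read
  lengths {125, 500, 3000} bp (short-read, pyrosequencing and
  single-molecule platforms). Quartiles by linear interpolation between
  order statistics (recorded in the output metadata); "above threshold"
  counts use ≥, "nonzero" uses > 0 beyond 1e-15. Outlier ranking sorts by
  ΔH descending with ties broken by replicon id.
- **Degenerate inputs.** No valid windows, or a single instance, raises a
  distinct degenerate status rather than reporting ΔH = 0; sweeps and
  surveys record the marker per grid point / per replicon and continue.

## Synthetic genomes

`simdata` generates i.i.d. random backgrounds with configurable GC
content (P(G) = P(C) = gc/2) using numpy's PCG64 generator (stable,
documented algorithm; the seed is recorded in a key=value sidecar next to
every FASTA written). Repeat families are planted by rejection-sampled
non-overlapping placement: a random unit of chosen length copied a chosen
number of times, verbatim (direct) or with copies ≥ 2 reverse-
complemented (inverted), optionally adjacent (tandem array). Ns can be
injected at a given per-position rate. Placement failure after 1000
rejection attempts raises a parameter error (footprint too dense).

`expected_entropy_loss` predicts ΔH analytically under the collision-free
background assumption (4^k ≫ L², comfortably true for k ≥ 21 and
L ≤ 10⁵): every repeated class must involve a window overlapping a
planted block, so enumerating exactly those windows — with their true
flanking context, which matters at tandem-array junctions and when a
flank base coincidentally extends a repeat — gives the exact multiplicity
profile, and ΔH follows from the closed form above. Agreement with the
measured pipeline is at machine precision on the tested sizes; the 1e-5/
1e-6 tolerances in tests leave room only for genuine background
collisions.

What the generator does *not* emulate: repeat families with internal
divergence (real LINEs/SINEs are rarely exact copies), segmental
duplication length distributions, GC heterogeneity along the genome, and
sequencing error. Passing tests therefore demonstrate that the statistic
and its implementation are exact on known repeat structure, not that ΔH
of a real genome can be predicted without computing it.

## Problem sizes

The test suite and acceptance script run entirely on synthetic and
published-table inputs: random-sequence oracle checks at ≤ 1 kb
(k = 2–12), partition invariance at 2–2.5 kb (m ≤ 4), parameter recovery
on 50 genomes of 10–100 kb (k = 21–31), sweeps and surveys at 2–20 kb.
These sizes make every statistic checkable against brute-force or
closed-form oracles at machine precision. Whole-genome validation values
(bacterial chromosomes to human) are reproduced by the same code paths
via `scripts/validate_public_genomes.py` on locally downloaded FASTA
files; entropy at m = 0 on a bacterial genome takes seconds to minutes,
and the m = 4–5 partitioned mode trades time for bounded memory on
gigabase targets.

## Known limitations

- The instance total of the partitioned mode is reconstructed from any
  one partition's kept + skipped tally; inputs mutated between passes
  would go undetected (inputs are in-memory and immutable in practice).
- `expected_entropy_loss` requires ambiguity_rate = 0; with injected Ns
  the instance total becomes stochastic and only the measured pipeline
  applies.
- Tandem arrays of a unit shorter than k are fully resolved only when k
  exceeds the whole array, not the unit — the closed form handles this,
  but single-number summaries ("repeat length") do not apply to arrays.
- ΔH is a property of the substring spectrum; it bounds reconstructability
  but does not model a specific assembler's contig algorithm.
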