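# Methods

## Problem and model

A read `Y` of length `M` is mapped to the reference `W` (length `N`) by
nearest-neighbor search over the library `{X_i}` of all `N − M + 1`
contiguous `M`-mers of `W`, under Hamming distance. The search structure is a
set of `J` arrays, each holding the library start positions sorted by the
`M`-mer *after* applying one uniformly random permutation `π⁽ʲ⁾` of the `M`
positions. Permuted `M`-mers are never materialized persistently: an index is
the reference, a permutation, and an order array, so `J` indexes cost
`J · |library|` integers plus the permutation codes.

Permutations use the gather convention — `apply(s)[j] = s[order[j]]` — fixed
by a unit test against a printed example of the convention. Internally all
coordinates are 0-based half-open; 1-based numbers appear only in printed
codes, the permutation manifest, the truth table, and SAM.

Per read and index, the permuted read's *lexicographical position* (leftmost
insertion rank) is found by binary search (`O(log N)` `M`-mer comparisons,
lazily materialized from `W`), and the `2K + 1` surrounding entries form its
*neighborhood*. Unioning neighborhoods over `J` indexes (and both read
orientations) gives the candidate set; each candidate's *hit count* is the
number of lookups that proposed it. Candidates with fewer than `min_hits`
hits are discarded; the rest are Hamming-ranked against the reference and
reported sorted by (distance, −hit count, position, strand). The per-read
budget is `O(J(log N + K))` comparisons, asserted by an instrumented counter.

## Success-probability calculus

With `p` mismatches between read and true nearest neighbor and resolution
length `L` (the shortest prefix its permuted `M`-mer shares with at most `K`
library entries), a single lookup succeeds whenever the random permutation
moves all `p` mismatches out of the first `L` output positions:

    PrGoodPerm(p, L, M) = (M−L)!/(M−L−p)! · (M−p)!/M!
    PrSuccess(p, L, M, J) ≥ 1 − (1 − PrGoodPerm)^J

Both are lower bounds (the searched neighborhood is at least as wide as the
length-`L` prefix block). `PrGoodPerm` is evaluated in log-gamma space (stable
to `M` of a few hundred) with an exact-`Fraction` variant used for
enumeration tests; when `p > M − L` the value is 0 by pigeonhole — the
analysis otherwise assumes `p < M − L`, and this is the forced extension.
`required_iterations` inverts the bound for a target probability and raises
when the target is unattainable. `resolution_profile` reports the empirical
`L` distribution of a seeded sample of library positions; `L` does vary
across permutations, and we report the spread rather than model it.

## Design choices

- **Ordering and ties.** Lexicographic order A < C < G < T; duplicate
  `M`-mers are retained (no uniqueness assumption) with ties broken by
  ascending genome position; binary search uses leftmost-insertion
  semantics; `resolution_length` returns the sentinel `M + 1` for duplicated
  `M`-mers. Neighborhoods clamp at array boundaries rather than wrap —
  wrap-around would join lexicographically distant strings.
- **N handling.** Inputs are case-folded; non-ACGTN characters become N. N
  mismatches everything, including N, so masked regions never match; library
  positions whose `M`-mer would contain N are excluded at construction.
  Multi-FASTA references are concatenated with ≥ M Ns between sequences so
  no `M`-mer spans two sequences; a reference map converts coordinates back.
- **Strands.** Indexes are forward-only; each read is searched as-is and
  reverse-complemented, with candidates labeled by strand. Indexing the
  reverse complement instead would double memory to halve lookups; searching
  both orientations keeps the index minimal.
- **Defaults.** `J = 8`, `K = 20`, `min_hits = 1`, `max_report = 5`,
  sliding-window stride `⌊M/2⌋`. These are deliberately conservative
  operating points for the genome scales the tests exercise (`PrSuccess`
  at `p = 2`, `L = 10`, `M = 100`, `J = 8` is ≈ 0.9999); all are
  overridable, and `permalign plan` recommends `J` for a target probability.
  "Choose J of the random permutations" is realized as building exactly `J`
  i.i.d. indexes and using all of them — equivalent in distribution to
  subsetting a larger pool.
- **Index construction.** The default build packs each permuted `M`-mer into
  ⌈M/32⌉ 64-bit words (2 bits/base; valid because library `M`-mers are
  N-free) and stable-radix-sorts them, so construction is a few vectorized
  passes. A comparison-counting pure-Python sort path backs the
  `O(n log n)` construction contract test. Rebuilding from (reference,
  manifest) is bit-for-bit reproducible, and the persisted form stores only
  the header (m, seed, reference checksum, manifest) plus order arrays.
- **Long reads.** Reads longer than `M` are aligned by the sliding-window
  mode: each `M`-long window at offsets `0, stride, …` (last window clamped
  to the read end) is searched and votes for the window-adjusted start, so
  hit counts accumulate and one index acts almost like several. Reads
  shorter than `M` are rejected (reported unaligned in batch mode).

## Paired-end alignment and rescue

Mates are aligned independently; a pair is *concordant* when some pair of
"reasonable" candidates (Hamming distance ≤ ⌈0.1·read length⌉, configurable)
lies on opposite strands in forward/reverse layout with start-to-start
separation inside `[insert_min, insert_max]`; the best combination by summed
distance wins. Requiring reasonableness on both sides prevents a random
far-distance candidate that happens to fall in the insert window from
preempting rescue. Otherwise the better-aligned mate anchors a rescue: its
candidates are tried in ascending distance, and for each the expected window
(insert bounds ± band, oriented by the anchor strand) is scanned for the
other mate.

The scan is an exhaustive semi-global edit-distance DP over the whole
window, vectorized row-by-row in numpy (the left-gap dependency is resolved
with a running minimum), rather than the seed-and-extend shortcut one would
use at chromosome scale: at window sizes of a few hundred bases the full
scan is exact and takes well under a millisecond, so a seeding heuristic
would add failure modes without measurable benefit. The minimizing end
position is refined to a start, distance, and transcript by a banded global
DP (`bounded_edit_distance`): unit costs, paths restricted to `|i − j| ≤
band`, exact whenever the true distance is at most the band (an upper bound
beyond it; with `band = 0` it degenerates to Hamming distance at the
offset). Transcripts are extended CIGARs (`= X I D`) written directly into
SAM. A rescue is accepted when the distance is at most
`max_rescue_distance` (default 10); the first acceptable rescue wins.

## Simulator

`generate_genome` draws i.i.d. uniform bases. `mutate_haplotype` makes each
base a variant site independently with probability `mutation_rate`; a site
is a substitution with probability `1 − indel_fraction`, else a single-base
insertion or deletion with equal odds (indels are length 1; longer indels
are out of scope). The haplotype carries a per-base map to reference
coordinates, through which read truth positions are reported. `sample_reads`
draws uniform starts and strands and flips each base independently with
probability `error_rate`; `sample_pairs` additionally draws the mate
start-to-start separation from Normal(`insert_mean`, `insert_sd`), truncated
positive, in forward/reverse layout with the mate order randomized.
Defaults (length-100 reads, 0.1% mutation rate, 15% indel fraction, 2% error
rate) are the simulation conditions the package's end-to-end tests target.

What the simulator does *not* emulate: position-dependent error profiles,
quality scores (a constant placeholder is written), GC or coverage bias,
repetitive genome structure, and multi-base indels. Passing the end-to-end
tests therefore demonstrates correctness of the search machinery under the
stated generative model, not performance on real repetitive genomes, where
the duplicate-`M`-mer tie-breaking and multi-candidate reporting matter
more.

`evaluate` scores a read correct when *any* reported alignment (primary or
secondary) lies on the truth strand within a tolerance (default ±5
positions, since indels shift coordinates) of the truth start; reads whose
truth window is N-masked are excluded from the denominator when a reference
is supplied. Multi-candidate output thus counts a truth-locus hit anywhere
in the report, and the tolerance is always stated alongside results.

## Problem sizes and determinism

The test suite runs everything end to end at reduced scale, chosen so the
whole suite completes in a few minutes on one core: the classic toy setting
(20 000-base genome, `M = 15`) for completeness and planted-mismatch checks;
a 1 Mb genome with 10⁴ length-100 reads for the scaled simulation (measured
recovery ≈ 99.5% at ±5, against the ≥ 95% requirement); 200 kb and 2 000
pairs for paired rescue (measured concordant-correct rate 100%). Every
source of randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds and parameters give byte-identical
output, including SAM.

## Known limitations

- Hamming ranking only for single-end reads: a mid-read indel defeats the
  single-end search unless the read is long enough for sliding windows to
  anchor its flanks; paired-end rescue is the supported indel path.
- One index set per `M`: reads of mixed lengths share indexes only via the
  sliding-window mode.
- `MAPQ` is not calibrated (written as 255/unavailable); hit counts and tie
  lists are the confidence signal.
- The whole reference and its order arrays live in memory; batch/index-at-a-
  time streaming over larger references than memory is not implemented.
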