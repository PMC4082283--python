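# Methods

`honeysv` detects structural variants (SVs) from noisy multi-kilobase
reads aligned to a reference, using two complementary signals: reads
whose best alignment is *interrupted* at an SV breakpoint, and reads
that *span* an SV and absorb it into their alignment as a local excess
of errors.  A bundled simulator produces datasets in which both signals
are known exactly, which is how the package validates itself.

## Interrupted mappings ("tails")

A long read crossing a breakpoint the aligner cannot bridge is
truncated, leaving the unaligned remainder as a soft-clipped tail in
the CIGAR.  Tails strictly longer than `min_tail_length` (default
200 bp) are extracted in original read orientation — a 5' *prolog*
and/or a 3' *epilog* — and remapped independently.  Each read's initial
alignment plus at most one tail alignment forms a *piece-alignment*; if
both tails map, the higher-mapping-quality one is kept (exact tie: the
prolog, deterministically).  Piece-alignments with three or more
informative components are rare enough that the pair model covers the
useful cases.

Each piece-alignment with a tail implies a breakpoint pair: `pos_a`,
where the initial alignment stopped, and `pos_b`, the tail's proximal
alignment endpoint (the 5' end of an epilog, the 3' end of a prolog,
resolved through the tail's strand).  Two pieces support the same event
when both coordinates agree within a `buffer` (default 200 bp) *and*
their orientation signatures — the ordered pair of strands plus tail
side — are identical, which is what separates, say, an inversion from a
deletion sharing the same 5' breakpoint.

Clusters are the connected components (transitive closure) of that
pairwise predicate, computed with union-find per (reference pair,
signature) group after sorting by `pos_a` (with an early exit once the
sorted gap reaches the buffer).  The closure is order-independent and
is exactly what the brute-force linkage oracle in the test suite
computes; a consequence accepted deliberately is that a chain of
mutually-close pieces can give a cluster whose total span exceeds twice
the buffer.  Clustering uses the raw `(pos_a, pos_b)` frame, which is
consistent within a signature group; coordinates are normalized
(`bp_a <= bp_b`) only when a call is reported.

Annotation from the signature and geometry, on one reference:

| strands  | tail proximal end vs. interruption (read order) | call |
|----------|--------------------------------------------------|------|
| equal    | beyond the interruption (sequence skipped)        | deletion |
| equal    | at or before it (mapping pushed back)             | insertion |
| opposite | any                                               | inversion |

Different references always mean translocation.  The distance-zero tie
goes to insertion.  Breakpoints are the arithmetic means of member
positions, rounded half-up; size is `|bp_b - bp_a|` for deletions and
inversions and is not estimated for insertions (tail geometry does not
measure inserted length) or translocations.

Calls are kept when they have at least `min_reads` = 3 supporting
piece-alignments, average component mapping quality (over initial and
tail alignments of all members) of at least 100 on the Phred scale, and
at least 2 distinct source molecules.  Molecule identity comes from the
`movie/zmw/qstart_qend` read-name convention; two subreads of one
sequencing well are re-reads of the same molecule, so requiring
distinct wells guards against library chimeras.  When names do not
follow the convention each read is its own molecule and the filter is
subsumed by the read-count minimum.

## Intra-read discordance ("spots")

A variant small relative to read length may not interrupt the mapping
at all: a 500 bp deletion inside a 10 kb read adds 500 "errors" to the
~1,500 already expected at a 15% error rate.  Such hidden variants are
found by counting, at every reference position, coverage plus three
error channels — mismatches, insertions, deletions — into a 4xG integer
array.  Conventions: deleted reference positions count as covered (the
read spans them), which keeps the deletion rate bounded by 1; an
insertion of length L between positions i and i+1 credits L to
position i, keeping the array shape 3xG; soft clips contribute nothing.

The channels are normalized to rates `E = A / C` (zero where coverage
is zero, so uncovered regions stay silent), smoothed with a centered
mean window of length `2B+1` (truncated at the reference edges), and
convolved with a slope kernel

    S[j,i] = (1/B) * ( sum M[j,i-B..i-1] - sum M[j,i+1..i+B] ),

defined only where both windows fit (zero within B of an edge).  A step
increase in discordance makes S negative, a decrease positive.  With
per-channel mean and population standard deviation of M taken over the
whole reference sequence, runs of `S < -N*sigma` and `S > +N*sigma`
(default N = 5) become negative and positive peaks.  Each negative peak
is paired with the nearest following positive peak (its run starting
after the negative run ends, apexes within `max_pair_distance`); the
pair yields boundary triplets `(start_out, start, start_in)` and
`(end_in, end, end_out)` with the exact breakpoints at the apexes of
extreme |S| (leftmost position on a tie).  Calls with mean coverage
below `min_coverage` (default 5) over `[start, end]`, or — for the
deletion and mismatch channels — size below `min_size`, are dropped;
unpaired peaks are discarded with a logged count.

Counting dominates runtime on real data, so the integer arrays can be
persisted to an HDF5 state file (one group per reference: `channels`
3xG and `coverage` G, with window/threshold/version attributes) and the
kernel/calling stages rerun with different B or N; a replay from state
reproduces a fresh run byte-identically, and raising N can only remove
calls.

### Parameters and scales

* **B (window half-width), default 400 bp.**  The smoothed profile of
  an event of length L is a trapezoid whose apex localization is sharp
  when `L >= 2B`: the slope extrema then sit at the event edges.  For
  `L < 2B` the extremum flattens into a plateau of width ~`2B - L` and
  breakpoint precision degrades to that order, so small-event analyses
  should lower B (the 327 bp validation scenario uses B = 150).  Larger
  B buys noise suppression on deep, long-event data.
* **N (threshold), default 5 sigma** of the smoothed track; the
  downsampling-robust default.
* **min_coverage, default 5**; below this the rate estimates are too
  unstable to threshold.
* **min_size, default 50 bp**: below the scale where the slope pairing
  localizes events meaningfully against the error floor.
* **max_pair_distance, default 100 kb**: an upper bound on single-event
  extent to stop pathological pairings across unrelated peaks.

## Simulator

The generator emulates a PacBio-style run: lognormal read lengths with
mean 6,100 bp (shape 0.55), 40x default coverage, and 15% total
per-base error split 2% mismatch / 10% insertion / 3% deletion —
substitutions and indels drawn independently per position, insertions
as single-base events, with no homopolymer bias or quality model.
"Accuracy" here means error operations per reference-consuming
alignment operation, whose expectation is exactly one minus the total
rate.  The reference is i.i.d. with configurable GC; SVs (deletion,
insertion, inversion, translocation via a two-contig donor) are
implanted at least 1 kb apart and from edges, with an optional SV-free
second haplotype mixed in for sub-unit allele fractions.

Alignments are produced analytically from the known sample-to-reference
segment map rather than by running an aligner: a read falling inside
unchanged (or inverted) sequence gets a contiguous CIGAR carrying its
injected errors; junctions up to `span_clip_threshold` (default
1,000 bp) are absorbed as mid-CIGAR D/I operations (the spots regime);
larger junctions, and all inversion/translocation junctions, split the
read exactly at the breakpoint into its longest piece (the initial
alignment, soft-clipped) plus adjacent-piece tail alignments named
`<read>/<side>` (the tails regime).  Boundary D/I operations are
trimmed the way aligners do.  Mapping quality is a deterministic
function of aligned length (length/10, capped at 254).  All randomness
flows from one seed; a fixed seed reproduces every output byte.

Because breakpoints are placed analytically, passing recovery tests
demonstrates the engines' signal processing and geometry, not
robustness to real aligner behaviour: reference repeats, ambiguous clip
placement, chimeric reads, and systematic error hotspots are not
modelled, and translocation recovery is exercised only at the geometry
level.

## Validation scales and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen so each scenario is statistically comfortable: kernel oracles on
10 kb random tracks; the hidden-variant scenario as a 327 bp homozygous
deletion on a 60 kb reference at 40x (50 seeded replicates; expected
recovery with breakpoints within B and size within 20%); the
interrupted-mapping scenario as a 5 kb deletion plus a 2 kb inversion
on 80 kb at 30x (50 replicates, breakpoints within the 200 bp buffer);
a transitive-closure clustering oracle on random piece sets of up to
12; and a zero-error, zero-SV negative control that must stay silent.

Numerical conventions, all deterministic: mean breakpoints round half
up; apex ties take the leftmost position; equal-quality prolog/epilog
ties keep the prolog; smoothing truncates windows at edges while the
slope is zero there; kernel sums use cumulative sums (agreement with
direct summation is at the 1e-12 level on unit-scale tracks).
Coordinates are 0-based half-open internally, 1-based inclusive in TSV
reports, 0-based half-open in BED.

## Known limitations

Insertion size is never estimated (neither engine measures it without
reassembling the inserted sequence); genotyping is out of scope; the
spots engine reports channel-typed intervals rather than resolved
alleles; clustering does not merge the strand-mirrored signatures of
one event, so a well-covered SV typically yields one call per
signature class.  These mirror the mapping-first design: calls are
meant to identify supporting reads for downstream reassembly, not to
fully resolve events.
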