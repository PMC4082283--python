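# honeysv

Structural-variant discovery from noisy long reads (PacBio-style:
multi-kilobase, ~15% per-base error), for resequencing analyses where
short-read callers lose power — repeat-dense regions, kilobase-scale
deletions, inversions, translocations.  `honeysv` consumes standard
SAM/BAM alignments and emits annotated SV calls through two
complementary engines:

* **tails** — interrupted mappings.  A read crossing a breakpoint the
  aligner cannot bridge is truncated, leaving a soft-clipped tail.
  Tails longer than 200 bp are extracted and remapped; each read's
  initial + tail alignment pair (a *piece-alignment*) implies a
  breakpoint pair.  Piece-alignments are clustered when their
  breakpoints agree within a 200 bp buffer *and* share internal
  orientation, then annotated as deletion / insertion / inversion /
  translocation with breakpoints averaged over members, and filtered
  (≥ 3 reads, average MapQ ≥ 100, ≥ 2 distinct sequencing wells).

* **spots** — intra-read discordance.  A variant small relative to
  read length hides inside the error noise of a spanning read.  Per
  reference position, coverage and three error channels (mismatch,
  insertion, deletion) are counted into a 4×G array A; rates
  `E_ji = A_ji / C_i` are smoothed over a `2B+1` window,

      M_ji = (1/(2B+1)) Σ_{k=i−B..i+B} E_jk,

  and convolved with a slope kernel

      S_ji = (1/B) ( Σ_{k=i−B..i−1} M_jk − Σ_{k=i+1..i+B} M_jk ),

  so rises in discordance go negative and falls positive.  Runs beyond
  N·σ (default N = 5, σ per channel over the whole reference) become
  peaks; a negative peak paired with the next positive peak yields a
  call with boundary triplets `(start_out, start, start_in)` /
  `(end_in, end, end_out)` and a type given by the channel.  The
  integer arrays persist to HDF5 so thresholds can be retuned without
  recounting.

A bundled simulator generates reference + SV-bearing sample + noisy
reads with *analytically exact* alignments (soft clips exactly at
unspanned breakpoints, small SVs absorbed into CIGARs), providing
ground truth for parameter-recovery tests.

## Worked example

Simulate 40× coverage of a 60 kb reference carrying a 327 bp deletion
that reads span (the hidden-variant regime), then call it:

```sh
$ honey sim --out demo --seed 7 --ref-length 60000 --coverage 40 \
      --sv deletion:ref1:30000-30327
392 reads, 392 alignments, 0 tail alignments -> demo

$ cd demo && honey spots --sam alignments.sam -B 150 \
      --hdf5-out spots_state.h5 --out-prefix spot_calls
2 spot calls -> spot_calls.tsv / spot_calls.bed

$ cat spot_calls.tsv
#ref  start_out start start_in end_in end   end_out type      size  support
ref1  292       370   441      29955  29994 30036   insertion 29624 33.92
ref1  29868     30001 30106    30222  30327 30460   deletion  326   32.00
```

The deletion is recovered at 30001–30327 (1-based; truth 30000–30327
0-based) with size 326 of 327 and mean supporting coverage 32×.  The
insertion-channel row is a low-coverage edge excursion paired across
the genome — the kind of call the σ-threshold is for.  Reprocess from
the saved state at N = 7 without recounting:

```sh
$ honey spots --hdf5-in spots_state.h5 -B 150 -e 7 --out-prefix spot_calls_e7
1 spot calls -> spot_calls_e7.tsv / spot_calls_e7.bed
```

leaving only the deletion.  For SVs too large to span, the tails
engine takes over (5 kb deletion + 2 kb inversion at 30×):

```sh
$ honey sim --out demo2 --seed 7 --ref-length 60000 --coverage 30 \
      --sv deletion:ref1:20000-25000 --sv inversion:ref1:40000-42000
$ cd demo2 && honey tails --sam alignments.sam --tails-sam tails.sam \
      --out-prefix tail_calls
9 tail calls -> tail_calls.tsv / tail_calls.bed

$ head -3 tail_calls.tsv
#ref_a bp_a  ref_b bp_b  sv_type  n_reads n_molecules avg_mapq size_estimate
ref1   20001 ref1  25001 deletion 12      12          208.96   5000
ref1   20001 ref1  25001 deletion 5       5           199.10   5000
```

Both events are recovered at the exact implanted breakpoints (one call
per orientation class of supporting reads: read strand × which flank
held the longer piece).  With real data the tail alignments come from
remapping the extracted tail FASTA (`honey tails --sam in.bam
--tail-fasta-out tails.fasta`, remap, rerun with `--tails-sam`), or
via `--aligner-cmd 'minimap2 -a ref.fa {fasta}'`.

As a library, the same pipelines are three calls each — e.g.
`spots.count_channels` → `spots.spots_pipeline`, or
`sam_io.assemble_piece_alignments` → `tails.call_tails`.

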