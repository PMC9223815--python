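# Methods

## Model and assumptions

The reconstruction model treats a circRNA as an ordered chain of
genomic exons inside its back-splice junction (BSJ) interval
`[start, end]`, and treats the chimeric alignments of BSJ-spanning
reads as the only sequence-level evidence of that chain. Three
assumptions follow:

- **Evidence is read-driven.** Only exons that some spanning read
  covers with an M block (or that an annotated exon overlapping such a
  block supplies) enter the result. Annotated exons inside the BSJ
  interval that no read touches are *not* imputed; an unobserved exon
  is absent from the assembly.
- **One sequence per BSJ.** Evidence from all spanning reads of one
  circRNA is pooled; alternative isoforms sharing a BSJ collapse into
  a single exon set. The skip-exon rule resolves conflicts: an
  interval covered by an M block in one read and spanned by an N gap
  in another is a skip exon and is deleted. This is a deliberate,
  asymmetric tie-break — intron evidence vetoes exon evidence — and
  means the method reconstructs the *splice-skipping* form whenever
  both forms are present.
- **Genome-derived sequence.** Assembled bases come from the reference
  genome at the final exon coordinates, not from read bases; read
  sequencing errors therefore do not propagate into the output, but
  genomic variants absent from the reference are invisible.

## Coordinates

Everything internal is 1-based inclusive `[start, end]`; the interval
recurrence `e_i = s_i + n_i − 1` only makes sense in that convention.
Conversions (BED12 blocks, CIRCexplorer-style 0-based starts, BED
dumps) happen exclusively in `io.py`.

## CIGAR handling

M and N consume reference and emit exon/intron blocks; S, H and I
consume none. D (deletion from the reference) is by default also
treated as consuming none — the method's published recurrence walks
M/N blocks contiguously — which shifts downstream blocks left by the
deletion length relative to strict SAM semantics. A
`d_advances_reference` switch (CLI `--strict-sam-d`) restores strict
semantics; on typical short-read data deletions are rare and short, so
the difference is a few bases at most.

## Annotation snap

A CIGAR exon intersecting ≥1 annotated exon adopts the annotated
coordinates; the largest-overlap exon wins, ties going to the smaller
start. Snapping runs before skip-exon detection, so snapped
coordinates are what get trimmed. The snap also repairs ragged read
ends (alignments that start a few bases inside the true exon).

## BSJ clipping

Final exons are intersected with `[start, end]`. If the outermost
retained evidence comes within `snap_bp` (default 10) of a BSJ
coordinate, the terminal exon is forced flush with it: circRNA
sequences begin and end exactly at the back-splice site, and read ends
are ragged by a few bases. A circRNA with no exon evidence inside its
BSJ interval is reported "not assembled" and stays in the denominator
of the reconstruction rate.

## Similarity criteria and match count

The published similarity test has two criteria: >95% identity, and a
match-count/length condition printed as `M − mean(l_A, l_B) < 10`. As
printed the second is vacuous (M never exceeds the shorter sequence,
hence never the mean), so the implementation reads it as
`|mean(l_A, l_B) − M| < 10`; the literal reading is available behind
`literal_criteria2=True`. The two criteria are combined with AND by
default (`combine="or"` available). Identity is `100·M / mean(l_A,
l_B)`, consistent with the mean used in criterion 2.

`M` itself is defined here as the number of matched columns in a
global alignment scored match +1, mismatch −1, gap −1, with ties in
score resolved toward more matches. The tie-break makes M
well-defined: it is computed exactly by a dynamic programme over the
composite objective `score·K + matches` (K exceeding any possible
match count), which is additive per alignment column and therefore
optimal-substructure-safe. The DP is vectorized per row in numpy;
cost is O(|A|·|B|), fine for circRNA-scale sequences (10²–10³ nt).
Sequences are compared as linearized at the BSJ — both short-read and
long-read pipelines anchor their output there — so no rotational
alignment is attempted; a reference sequence rotated to a different
start would not be matched.

Predictions are matched to references by their `chrom:start|end`
identifier first (falling back to an all-vs-all similarity scan when
the identifier is absent); `match_mode="all"` forces the scan.

## Metrics

Precision `= 100·TP/(TP+FP)`, sensitivity `= 100·TP/(TP+FN)`, F1 the
harmonic mean computed on fractions, reconstruction rate
`= 100·NRS/NSC`. FN is only defined relative to a competing method's
verified set; without one, FN and sensitivity are reported as absent
(`None`), never as 0. Zero denominators likewise yield absent values.
Reported tables round percentages to 2 decimals and F1 to 4.

## Synthetic bundles

The simulator plants non-overlapping multi-exon circRNA loci on a
uniform-random ACGT genome and emits every input file the pipeline
reads plus the truth. Defaults, chosen once as a small but
structurally complete experiment: 2 chromosomes × 100 kb, 20
circRNAs, 2–5 exons of 60–200 bp, introns of 80–500 bp, internal
exons skipped with probability 0.3, 4 spanning reads per circRNA,
error-free bases. Each spanning read is a chimeric pair sharing a
QNAME: one segment realizes the whole exon chain from the BSJ start
(so every intron gap is observed), the other the chain's tail, with
the far side soft-clipped — the suffix+prefix structure of a genuine
BSJ-crossing read. When a circRNA carries planted skips, alternate
reads include the skipped exon as an M block and span it inside an N
gap, so the skip-exon veto is genuinely exercised. The outermost read
ends are left 0–4 bp ragged to give the annotation snap work. Reads
realize the full planted structure rather than a fixed sequencer read
length: the recovery property needs structural coverage guarantees,
not read-length realism.

What the simulator does **not** emulate: sequencer error profiles and
quality strings, fragment-length variation, multi-isoform loci,
overlapping genes, repeats/homology (so no ambiguous alignments), and
long-read (Nanopore) data. Passing the round-trip recovery test
therefore shows the pipeline's interval logic and assembly are exact
on clean structural evidence; it does not certify behaviour under
alignment ambiguity or annotation mismatch on real data.
`corrupt_reads` degrades SAM base calls without touching coordinates,
which is useful for exercising the similarity thresholds, not for
realistic error modelling.

## Numerical and degenerate-input conventions

- Interval merge coalesces overlapping *and* bookended (gap 0)
  intervals; subtraction may split an exon in two.
- Single-base circRNAs (`start == end`) and single-base exons are
  legal throughout.
- A circRNA list line with no read names is kept (it may gain reads
  from the junction table) with a warning.
- All simulator randomness flows through one seeded
  `numpy.random.Generator`; identical configs give byte-identical
  bundles.

## Known limitations

- One assembled sequence per BSJ; no isoform enumeration or
  rolling-circle copy-number estimation.
- Minus-strand output is genome-forward unless `revcomp_minus` is set.
- The skip-exon veto is absolute: a single spurious N gap (e.g. an
  intron-retaining misalignment) deletes exon bases supported by many
  reads.
- Sensitivity is only measurable against a named competing method, by
  construction of the FN definition.
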