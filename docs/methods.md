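# Methods

This note documents the models, rules and numerical choices behind
`lncprofile`, and what the synthetic-data generator does and does not
emulate.

## Coordinate model

All internal coordinates are 0-based half-open. GTF (1-based inclusive) is
converted on read and write; BED passes through unchanged. A transcript's
TSS is its first transcribed base: the start of the first exon on `+`, the
last exon's `end − 1` on `−`. Interval queries return transcripts whose
exon hull overlaps the query by ≥ 1 base, ordered by
(chrom, start, transcript_id) so all downstream reports are reproducible.
Biotype is resolved from the `gene_biotype` GTF attribute, falling back to
`transcript_type`, then `"unknown"`.

## Differential expression

* **Quantile normalization** maps every sample column onto the mean of the
  sorted columns. Ties within a column receive the mean of the target
  values their positions span, preserving within-column ranks. The
  transform is idempotent.
* **Above background**: intensity ≥ floor (default 32, linear scale) in
  *all* replicates of *at least one* condition. Array vendors use
  proprietary flags for this call; the all-replicates rule is this
  package's own deterministic formalization and matches the
  stage-specific expression the workflow is designed to detect.
* **Fold change** is computed on linear-scale group means of normalized
  intensities and reported signed (+A/N up, −N/A down; equal means → +1.0,
  a tie-break that can never reach significance). The paired t-test runs
  on per-pair log2 ratios, where the normality assumption is more
  plausible. Zero-variance pair differences make the t statistic
  undefined; such probes get a NaN p-value and are excluded from
  significance calls. Note that quantile normalization maps any noise
  small enough to preserve within-column ranks onto *identical* replicate
  values per group, so the degenerate case covers not just noise-free
  input but every sub-rank noise level.
* **Call**: up/down iff |FC| ≥ 5, p ≤ 0.05 and above background. No
  multiple-testing correction enters the call (the classic filter uses raw
  p plus a strong fold-change threshold); a BH-adjusted column is emitted
  for information only.

## Genomic context

Precedence ladder, first match wins: exonic (any lncRNA exon overlaps any
protein-coding exon ≥ 1 base) > intronic (span overlap, no exon overlap) >
bidirectional (divergent head-to-head TSSs, TSS-to-TSS distance strictly
< 1,000 bp) > intergenic. Sense/antisense by strand equality; when a lncRNA
overlaps both same- and opposite-strand partners at the same rung, the
sense label wins and all partners are reported. Distance for bidirectional
pairs is measured TSS-to-TSS (not gap-between-spans); "intronic" requires
no exon overlap within the gene span rather than containment in a single
intron — both points are deliberate resolutions of genuinely ambiguous
conventions, chosen because they are the simplest rules that make the six
labels a total partition. Single-exon genes have no reachable intronic
rung: span overlap without exon overlap is impossible there. miRNA overlap
is span-based, any strand by default (a strand-matched mode exists).

## Promoter CpG and chromatin state

Promoters span offsets −500..+2000 from the TSS in the direction of
transcription (2,500 bp; clipped-and-flagged at chromosome ends, and
clipped promoters stay in all tallies). The HCP scan slides 500-bp windows
at step 1 (2,001 windows — exhaustive and cheap, which removes the window
step as a free parameter). A window passes at GC ≥ 0.55 and CpG O/E ≥ 0.6
with O/E = (N_CpG · L_eff)/(N_C · N_G); N bases reduce L_eff and all
counts, and O/E is defined 0 when N_C or N_G is 0. The best window
maximizes (O/E, then GC), ties to the smallest offset. CpG is a
strand-symmetric dinucleotide, so full-window counts are invariant under
reverse complement (asserted as a property test). A promoter is "marked"
by H3K4me3/H3K27me3 when ≥ 1 peak with score ≥ `min_score` (default 0,
i.e. any overlap) intersects it; bivalent = both marks. Summary
percentages are integers rounded half-up and always recomputable from the
emitted numerator/denominator columns.

## Conservation

Conserved bases per lncRNA = |union of elements ∩ assessed intervals|;
input elements are merged first so duplicated or overlapping elements never
double count. Assessed intervals are the exons by default ("its sequence"
read as the spliced transcript), with a `span` mode for sensitivity
analysis. Flags: overlaps_any (≥ 1 base) and passes_20 (≥ 20 bases).

## Validation statistics

* **2^−ΔΔCt**: ΔCt = mean(ct_target − ct_reference) per group; the
  construction is invariant to uniform reference-gene shifts. No
  amplification-efficiency correction is applied.
* **Spearman rho** is the Pearson correlation of average ranks; for
  n ≤ 9 the two-sided p-value is an exact permutation tail (n! orderings,
  vectorized), because t-approximations are unreliable at the panel sizes
  typical for qPCR validation (n = 8). Concordance is computed on the
  signed fold changes exactly as reported, not on magnitudes or logs.
* **Enrichment**: one-sided hypergeometric tail P(X ≥ k) per term
  (plain Fisher, no EASE penalty), BH adjustment across all tested terms.
  Both raw and adjusted p are emitted; the significance flag defaults to
  raw p < 0.05, matching how such tables are conventionally printed.

## Synthetic data generator

The generator emulates a two-condition (N vs A), three-replicate paired
one-color array study. Randomness fans out from one root seed into named
substreams (annotation, expression, noise, promoters, peaks, conservation,
qPCR), so adding a generator never shifts existing outputs, and all files
are byte-identical for a fixed seed.

* **Annotation**: units (a background gene, a host gene plus its lncRNA,
  or a lone intergenic lncRNA) are laid out with > 10 kb gaps across three
  chromosomes, alternating strands. Each of the six context labels is
  planted by construction — e.g. bidirectional lncRNAs at TSS distances
  drawn from [100, 999], intergenic lncRNAs > 10 kb from any gene — and
  verified by the classifier itself in the tests. miRNAs (80 bp) are
  nested inside the first exon of a configurable fraction (default 0.25)
  of lncRNAs. Chromosome sizes are auto-fitted unless given, in which case
  undersized chromosomes raise an error stating the required minimum.
* **Expression**: probes are planted in balanced (+m, −m) pairs sharing a
  baseline drawn from log2-Uniform(8, 12), with magnitudes cycling through
  the palette (default {2, 8}, straddling the |FC| = 5 threshold), plus
  planted nulls. This balance makes the noise-free sample columns exact
  permutations of one another, so quantile normalization is an exact
  identity and planted fold changes survive the full pipeline to machine
  precision — the property the noise-free recovery test asserts at 1e−9.
  Replicate noise is i.i.d. Normal(0, 0.25) on the log2 scale — a standard
  assumption, not an inference about any particular platform. A planted
  fraction (default 0.2) of probes sits ≥ 3 noise SDs below the background
  floor in both conditions.
* **Promoters**: 2,500-bp sequences. Non-HCP promoters contain no CpG
  dinucleotide at all (O/E = 0 in every window — a guaranteed, if
  stylized, negative). HCP promoters embed one 500-bp block rejection-
  sampled to GC ≥ 0.60 and O/E ≥ 0.80, comfortably inside the thresholds
  so the planted class is robust to window-step choices.
* **Peaks/elements**: marked promoters receive one overlapping scored
  peak; the > 10 kb unit spacing guarantees unmarked promoters have no
  peak within 5 kb. Conserved elements are placed inside exons so each
  lncRNA's exonic conserved-base total equals its planted value exactly
  (palette default {0, 10, 60, 150}, straddling the 20-base rule).
* **qPCR**: Ct values planted so 2^−ΔΔCt recovers the planted fold change,
  with 0.05-cycle replicate noise and a constant-Ct reference gene.

What the generator does **not** emulate: realistic genome composition
(isochores, repeats), probe cross-hybridization, dye or spatial artifacts,
overlapping gene models, and peak-width/score distributions of real
ChIP-seq. Passing the planted-truth tests therefore demonstrates
correctness of the decision rules and arithmetic, not robustness to the
messiness of real annotations or arrays.

## Problem sizes and determinism

Default test/acceptance runs use 24 lncRNAs (4 per context), 32
protein-coding genes and 56 probes; oracle-equivalence suites run 100
randomized instances per operation and the null calibration uses 2,000
planted-null probes — sizes chosen to exercise every code path while
keeping the whole suite in seconds. The paired-t null calibration lands in
[0.03, 0.07] at p ≤ 0.05, consistent with a calibrated test at df = 2.
Pipeline reruns with the same config and seed are byte-identical; reports
embed every threshold used.

## Known limitations

* The six-way classifier reports the label of the highest rung only; a
  lncRNA that is, say, exonic to one gene and bidirectional to another is
  counted once as exonic.
* Background correction beyond flooring is out of scope (vendor-software
  territory); inputs are assumed positive after flooring.
* The exact permutation p-value enumerates n! orderings and is capped at
  n ≤ 9; larger panels switch to the t-approximation.
* GTF support is limited to the Ensembl-style exon/attribute dialect; no
  GFF3 aliasing, BED12 blocks, or liftover.
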