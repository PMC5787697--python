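# Methods

This note documents the models, conventions and numerical choices behind
`clipshift`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and strand conventions

All coordinates are 0-based half-open internally; GTF files are written and
read 1-based inclusive, with the conversion confined to the I/O layer. BED
files keep the internal convention. Mismatch records on reads are stored in
sense (transcript) orientation: a crosslink conversion on a minus-strand
read is a T-to-C in transcript space even though it appears as A-to-G in
reference coordinates, and the SAM reader performs that flip (offsets
reversed, bases complemented). All conversion counting downstream is
sense-strand.

## Peak calling

Reads are grouped by chains of ≥1-bp same-strand overlaps (abutting reads
do not merge); grouping is strand-separated because the conversion evidence
is sense-strand-defined. A read counts as *converted* iff it carries at
least one sense T-to-C mismatch and at most one mismatch in total; a
collapsed read with copy count *c* contributes *c* to every tally, since
PCR-duplicate collapsing happens upstream and counts must reflect evidence.
A group becomes a binding-site peak iff (1) converted reads / all reads
≥ 0.25, (2) it contains more than five (i.e. ≥ 6) converted reads, and
(3) conversions occur at ≥ 2 distinct genomic positions. Peaks span the
union of member reads. No kernel-density site refinement is applied: the
three criteria fully define the filter. The peak *anchor* is the conversion
site supported by the most converted reads, ties broken leftmost for
determinism.

## Feature assignment

Assignment is by the anchor base only (the crosslink-supported position),
one category per peak, with precedence 5′UTR > 3′UTR > CDS-exon > promoter
> intron > intergenic. The UTRs outrank "exon" because "exon" is read as
CDS exon — otherwise the UTR categories would be empty. Assignment is
same-strand only; an anchor antisense to the only overlapping gene is
intergenic, because sense-strand RNA evidence cannot come from the
antisense gene. The promoter is 1 000 bp upstream of the TSS
(configurable); 1 kb is a conventional promoter width, not a derived
number. Intergenic peaks are rescued if within 10 kb downstream of a CDS
stop codon or 10 kb upstream of a CDS start codon (same strand);
equidistant ties go to the stop codon, preferring the
3′UTR-extension interpretation. The cumulative count-versus-distance table
behind the rescue is emitted for plotting.

## k-mer enrichment

k-mer occurrences are counted on the sense strand in a 20-nt window over
each binding site plus 20-nt flanks (or in fifths of the peak span in
percentile mode). Frequencies use a pseudocount of 0.5 per k-mer per table
(Jeffreys-style smoothing; avoids log of zero), and the score is
log2(freq_region / freq_background). The background is built by
composition-preserving (mononucleotide) shuffling of the annotation's
protein-coding ORFs, pooled over a configurable number of shuffles
(scaled down from the conventional 10 000 in tests for runtime); a
dinucleotide-preserving Altschul–Erickson shuffle is available as an
option.

Two estimator artifacts matter here and drove the window-placement
defaults. The crosslinked base is a uridine by chemistry, so windows
centered on conversion anchors contain a guaranteed T; worse, the anchor is
*selected* as the most-converted position, which favours neighbourhoods
with few competing Ts and hence T-depleted windows. Site windows therefore
default to peak-midpoint centering, which is free of both artifacts;
anchor centering remains available, in which case k-mers covering the
crosslinked base are masked by default. Under completely unbiased site
placement the maximum |score| over all 4-mers stays below 0.5 at ≥ 2 000
peaks, which is the calibration the null tests assert.

## Boundary metaprofiles

Unique exon–intron (EI) and intron–exon (IE) boundaries come from
protein-coding transcripts only, deduplicated per the strand-resolved rule
(exon 3′-end locations for EI, exon 5′-start locations for IE; terminal
exons contribute no EI/IE at the transcript ends). Offsets are
transcript-oriented with the first intronic base at offset 0 and the exon
side negative; profiles cover 100 exonic and 300 intronic bases. Coverage
counts intervals overlapping a base, copy-count-weighted, with no
truncation at nearby features (double-counting between close boundaries is
accepted, matching a naive per-boundary scan). Two backgrounds: re-placing
exons per chromosome while preserving their count and sizes (reads stay
fixed), and uniform random regions (default 150 000 × 5 000 bp, scalable
down) whose starts act as EI and ends as IE boundaries, half each.

## Splicing maps

Events are classified as enhanced (p ≤ 0.05, FDR ≤ 0.05, ΔPSI ≥ +0.1),
silenced (ΔPSI ≤ −0.1, same significance), background (FDR > 0.5), or
excluded. Maps cover four regions of 50 bp exon flank + 250 bp intron
window around the cassette trio; densities count events-with-a-peak
(binary per event per position) so a single peak-rich event cannot
dominate, then apply a 50-bp centered moving average. Significance per
position is a one-sided permutation p-value against background events
bootstrap-resampled (always with replacement) to the target class size,
with the add-one rule so p is never zero. With-replacement resampling was
chosen after a calibration study: subsampling without replacement from a
finite background pool understates the target's sampling variance and
inflated the null rate to ~11%; the bootstrap brings it to ~6% at a 5%
nominal level (residual inflation reflects the finite pool and smoothing
correlation). The region geometry is configurable; the defaults follow the
convention of positional splicing-map analyses.

## Gel-shift quantitation

The single-step n-mer model is fitted in log-log space by ordinary least
squares of ln(bound/free) on ln[P]total, with [P]total standing in for
[P]free in the trace-ligand regime. Points are restricted to the 20–80%
saturation window — the classical Hill-plot convention — because a
simulation study showed that keeping near-saturated lanes biases the
fitted stoichiometry downward by ~20% for steep isotherms: additive
quantitation noise near 0/1, clipped and excluded when it crosses the
boundary, censors the log-odds asymmetrically. Within the window the
residual bias is below 3% for both parameter regimes tested (n ≈ 1.75 and
n ≈ 3.31 at noise sd 0.03). If noise leaves fewer than three points in the
window, the fit falls back to all interior points. K = exp(ln Kn / n)
converts the intercept to the monomer-equivalent association constant
(the reciprocal midpoint concentration); uncertainties are OLS standard
errors, with a seeded case-resampling bootstrap available.

The competition ratio is computed per lane as
([PmD]/[D]free)·P^(n−m)/([PnR]/[R]free) with [PmD] = ([D]0 − [D]free)·m,
using only lanes where both free fractions lie inside a 5% band-
quantitation window (a band or its disappearance smaller than 5% of total
is treated as unquantifiable on a phosphor image). The per-lane ratios are
fitted linearly against [P] over all quantifiable lanes and the intercept
at [P] = 0 is reported. The RNA-preference direction K_RNA/K_DNA is
obtained by refitting with the species roles exchanged rather than by
inverting the intercept: the reciprocal of a noisy intercept is itself
skew-biased, while each orientation's own fit is unbiased. Measured
recovery bias across independent 200-replicate batches is ≤ 3.5% for a
25-fold DNA preference and ≤ 1.6% for a 7-fold RNA preference.

## Synthetic-data generator

The generator's defaults define the simulated study conditions:

- **Genome**: i.i.d. uniform sequence; 2 chromosomes × 300 kb, 30 genes
  (70% mRNA, 15% lincRNA, 7.5% each miRNA/snRNA), 3–6 exons of 120–300 bp,
  introns 300–1 500 bp, fixed-width UTRs. These sizes are desk-scale
  stand-ins chosen so every stage has hundreds of features to work with.
- **Reads**: lengths 16–23 nt with frequencies matching the empirical
  read-length table of the sequenced crosslink library (mode 20 nt);
  conversions occur with probability 0.8 at a uniformly chosen sense T of
  a site-derived read, one mismatch maximum; 10% of reads are uniform
  background.
- **Sites**: 20-nt windows placed across exon-boundary flanks, intron
  bodies and intergenic space with configurable weights; with GC bias b,
  site bases are redrawn with per-base G/C probability e^b/(1+e^b), so
  b = 0 recovers the uniform background (the simplest null against which
  GC enrichment is detectable).
- **Splice events**: cassette trios with enhanced / silenced classes at
  |ΔPSI| uniform in [0.1, 0.5] and FDR ≤ 0.05, background at FDR > 0.5;
  the planted class travels with the event as hidden truth.
- **Isotherms**: the exact single-step model on a 12-point linear grid,
  0.05–2.5 µM protein with 0.05 µM ligand, plus additive Gaussian noise
  (sd 0.03) on measured fractions, clipped to [0, 1] — modelling how
  fractions are quantified from gel images without modelling the imager.
  Competition simulations are parameterized by the affinity *ratio*; the
  absolute scale centers the two species geometrically on 10⁶ M⁻¹, which
  keeps both free-fraction curves inside the quantifiable range over the
  default grid (single-titration experiments in this system report
  monomer-equivalent affinities of that order).

What the generator deliberately omits: sequencing errors beyond the single
crosslink mismatch, quality scores, PCR duplicates (collapsed reads are
assumed), transcript isoform diversity, expression-level variation among
genes, and correlated band-intensity (multiplicative) noise on gels.
Passing tests therefore demonstrate that the estimators and counting
procedures are correct and calibrated under the stated statistical
structure — not that they are robust to alignment artifacts, annotation
errors or image-quantitation systematics in real libraries.

## Problem sizes used in tests

The default test and acceptance runs use 4 000–80 000 reads on 0.6–1.8 Mb
toy genomes, 100–200 permutations for map significance, tens of ORF
shuffles for k-mer backgrounds, 2 000 random background regions for
metaprofiles, and 200 replicates for the estimator-recovery studies.
These sizes were chosen so each statistical check has adequate power at
desk scale (e.g. >2 000 peaks for the k-mer null calibration, where the
0.5-bit bound needs per-k-mer counts in the hundreds).

## Known limitations

- Feature assignment ignores overlap fractions; a peak spanning a
  boundary is classified by its anchor alone.
- The intergenic-rescue distance scan is linear in the number of coding
  genes; adequate at toy scale, it would want an interval index for a
  full genome.
- The permutation test's residual ~1% null inflation vanishes only as the
  background pool grows large relative to the target class.
- The competition analysis assumes independent single-step binding of the
  two ligands in the trace regime; ligand depletion and ternary complexes
  are out of model.
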