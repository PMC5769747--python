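# Methods

This note documents the models and procedures implemented in
`antisense_scope`, the choices made where the underlying procedure was
genuinely open, and what the synthetic data can and cannot show.

## Signal model and quantification

Two signal semantics coexist. NET-seq tracks store single-position 3'-end
tags (one count per read, per nucleotide, per strand), reflecting the
position of the elongating polymerase; RNA-seq tracks store full per-base
read coverage. Both live in the same container (`StrandedTrack`), and
`total_tags` is carried as library metadata rather than recomputed from the
vectors, because multi-base coverage breaks the "track sum = read count"
identity.

Per-feature quantities, always over exactly the annotated span on the
chosen strand:

* **RPKM** = tags_in_span x 10^9 / (span_length x total_tags).
* **Coverage fraction** = proportion of span positions with >= 1 tag,
  computed per replicate and aggregated as the **minimum** across
  replicates. This is the strictest reading of "covered in each
  replicate"; the per-replicate values are also exposed. RPKM is
  aggregated as the replicate mean.
* Antisense signal for a gene is measured over the annotated gene span on
  the opposite strand; 3' read-through regions are not part of calling.

## Threshold calibration and antisense calling

Transcription thresholds are derived from a reference set of the
`n_reference_genes` (default 50) least-transcribed protein-coding genes.
Genes whose control-track (total-RNA input) mean density falls below a
mappability floor (default 0.01 tags/nt) are excluded first — a
quantitative stand-in for manual curation of repeat-rich loci, which has no
published quantitative rule. The derived threshold is the smallest value on
a fixed grid (0.1 RPKM; 1% coverage) strictly greater than both twice the
reference median and the reference maximum; the grids make the derivation
deterministic where the published criteria leave the rounding open. A
strand is called transcribed when mean RPKM **and** aggregate coverage both
exceed their thresholds.

Convergence: two genes are a convergent pair when their strands oppose
tail-to-tail, the 3'-3' distance is under 500 nt, and at least 50 positions
(not necessarily contiguous — the criterion is an overlap extent, not a
run) carry >= 1 tag/nt on both strands in every replicate. TSS overlap uses
an inclusive +/-100 nt window (201 positions, clipped at contig edges,
which shrinks the denominator) and requires > 80% antisense coverage in
every replicate. Antisense-coverage bins are fixed-width fifths of [0, 1]
with the top bin closed.

## Metagene profiles

Gene bodies are rescaled to 1000 virtual positions by degree-1
(piecewise-linear) interpolation sampled on [0, L-1] — the published
"polynomial interpolation" does not state a degree, and degree 1 is
monotone and endpoint-preserving. Flanks (default 500 nt, configurable; no
published width exists) are unscaled; minus-strand genes are reversed so
the TSS is leftmost. Stranded profiles are aggregated on a log2(x+1) scale;
chromatin-mark profiles use per-nucleotide log2((mark+1)/(H3+1)) with
strands summed. The 95% CI is the normal approximation
mean +/- 1.96 sd/sqrt(n) (collapsing to the mean at n = 1); a seeded
bootstrap (1000 resamples) is available since the original interval
estimator is unspecified.

## Segmentation into XUTs

Replicate decay-mutant libraries are pooled per strand and transformed as
log2(c+1); the pseudocount handles zero positions and keeps them below the
smallest threshold (1.44). The signal is smoothed with a centred moving
mean (even widths use the asymmetric-centre convention
[i - ceil(w/2) + 1, i + floor(w/2)]; edges use truncated means — neither is
specified upstream). Maximal runs strictly above the threshold become
segments; those under 200 nt or sharing >= 1 nt with a same-strand ORF are
dropped.

The window x threshold grid is 10–200 nt by 10 and 1.44–216 by 1.44 (3000
combinations). "Best compromise between XUT and mRNA detection" is
operationalized as the harmonic mean of (a) mRNA recall — the fraction of
annotated mRNAs matched by a pre-ORF-filter segment at >= 50% reciprocal
overlap — and (b) candidate yield normalized by its grid maximum. Ties go
to the smaller window, then the smaller threshold. The differential filter
runs after selection only, so the grid scan stays cheap.

Candidate counts are recomputed from the raw per-condition tracks over each
segment span, normalized by sn(o)RNA-anchored size factors (median anchor
ratio to a reference sample), and tested with a two-condition
negative-binomial likelihood-ratio test: a common dispersion is
moment-estimated across all segments (median per-feature excess variance,
floored at 1e-8), rates are fitted by bounded 1-D likelihood maximization
with size-factor offsets, and the statistic is referred to chi-squared with
1 df. The published pipeline delegated this step to DESeq; the contract
(fold > 2 on pseudocounted normalized means, BH-adjusted p < 0.05) is what
is specified, not the engine, so an in-repo test keeps the dependency
surface small; it is cross-checked against an independent statsmodels GLM
fit in the tests. Retained segments are classed antisense when they overlap
an opposite-strand mRNA by >= 50 nt (else solo) and novel when they share
no nucleotide with a previously annotated lncRNA. Exosome-mutant
sensitivity is flagged by a density ratio (mut + 0.01)/(WT + 0.01) > 2.

## Time-course statistics

Per-pair Pearson correlations are computed from per-time-point mean signal
(replicates averaged) over >= 3 points; pairs with a zero-variance series
are skipped as undefined. The response classifier contrasts every later
time point against the first with the same NB test (unit size factors),
applies BH within each contrast, and flags a feature responsive when any
contrast passes fold > 2 and adjusted p < 0.05, reporting the first such
point. RPKM tables are converted to pseudo-counts (x10, rounded) before
testing, since the NB model needs count-scale data.

## Synthetic data: what it emulates and what it does not

The generator plants every quantity the analysis recovers:

* **Genome and annotation** — 2 x 500 kb, 500 non-overlapping genes
  (700–1500 nt) with mRNA + inset ORF, 40% in tail-to-tail convergent
  pairs (3'-3' gap drawn from [50, 800] nt, so pairs beyond the 500 nt
  calling limit exist by design), 30 snoRNAs, 6 centromeric-repeat blocks,
  60 untranscribed genes (8 of them unmappable, i.e. zero control signal)
  to populate the reference set.
* **NET-seq** — per-nt Poisson tags at a log-normal sense rate (median 3
  tags/nt, sigma 0.8), exponential 3' read-through (mean 150 nt, capped at
  300), plus planted antisense regions on 60% of genes (3'-anchored for
  convergent pairs, covering 20–50% of the gene; broadly placed otherwise,
  30–95%). Coupling is generative: the sense rate is multiplied by
  exp(-beta x a) with beta = 2, so the sense/antisense anti-correlation is
  planted truth, not selection.
* **Decay-mutant RNA-seq** — mRNA coverage ~ log-normal (median 15
  tags/nt), XUTs at low WT coverage (median 1.2 tags/nt) multiplied by
  2^fold in the mutant with fold ~ N(2.5, 0.6) clipped at 1.2 (so every
  planted linear fold exceeds 2), snoRNAs condition-invariant, mRNAs
  mildly elevated (x1.2) in the mutant.
* **Time course** — 600 asXUT/mRNA pairs (annotated pairs first, padded
  with standalone pairs, mirroring that the meiosis data are a separate
  dataset), half responsive: rising antisense (3–6 fold by the last
  point) with coupled declining mRNA (to ~0.6x). The additive noise scale
  is solved by seeded Monte-Carlo bisection so the **median sample
  Pearson r** over the five time points equals the configured target
  (default -0.5); the small-sample distribution of r over 5 fixed design
  points is not the iid bivariate-normal one, which is why the
  calibration is numerical. Zero noise yields r = -1 exactly.
* **ChIP** — H3 at 20 fragments/nt; the mark at 0.5x over a 300 nt
  promoter window and 1.3x over the body of antisense genes.
* **Small RNA** — repeat-derived reads with a 22–23 nt mode; sparse
  background spanning 15–35 nt so the 18–30 filter is exercised; no reads
  planted in XUT regions.

Each stage derives its own RNG from (seed, stage id), so identical configs
are byte-identical and stages are independently reproducible.

Not emulated: sequence content and mappability structure, intron signal,
fragment-length artifacts of library protocols, UTR/isoform heterogeneity,
biological covariation between genes beyond the planted couplings. Passing
recovery tests therefore demonstrates the correctness of the analysis
logic under the stated generative assumptions, not performance on real
libraries.

## Numerical conventions and degenerate inputs

log2 pseudocounts are 1 for signal tracks and 0.5 per side for fold
changes; the exosome-ratio pseudocount is 0.01 tags/nt. Threshold grids
snap strictly upward (an exact grid value is pushed one step up).
Coverage-bin boundaries use a 1e-9 tolerance against binary-float drift.
Wilcoxon p-values are exact by enumeration for pooled n <= 20 without
ties, otherwise normal with tie and continuity corrections. The
chi-squared test applies no continuity correction (the published variant
is unstated; the uncorrected Pearson statistic is reported). Empty
segment lists, all-zero references, zero-variance series and single-gene
aggregations all take defined paths (empty tables, smallest grid step,
skipped pairs, CI collapsing to the mean). Benjamini-Hochberg adjustment
is monotone, capped at 1 and inflationary under re-application; it is not
idempotent in the strict sense (no step-up adjustment is).

## Problem sizes

Defaults were chosen so a full run — simulation, calling, the complete
3000-point grid, differential testing and the time course — completes in
well under a minute on one CPU, while keeping >= 90% recovery power for
every planted class; the full test suite runs in about a minute.
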