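# antisense-scope

Strand-specific analysis of antisense transcription for compact fungal
genomes, built around the kind of question raised by NET-seq studies in
fission yeast: how much of the genome is transcribed antisense to
protein-coding genes, how does that antisense activity relate to sense
transcription, and which of the resulting antisense lncRNAs are cryptic
unstable transcripts that only become visible when cytoplasmic 5'–3' RNA
decay (Xrn1/Exo2) is removed?

The package is aimed at computational biologists who want the downstream
analysis of such a study as tested, composable library code: everything
after read alignment, from per-nucleotide stranded tracks to annotated
unstable transcripts and the associated statistics.

## What it computes

* **Strand-aware quantification** — per-feature RPKM
  (tags x 10^9 / (length x total tags)) and coverage fraction (share of
  positions with >= 1 tag, minimum across replicates), measured on either
  strand of any annotated feature; sn(o)RNA-anchored size factors for
  decay-mutant normalization.
* **Threshold-calibrated antisense calling** — transcription thresholds
  derived from the 50 least-transcribed genes (strictly above 2x their
  median and above their maximum, on 0.1-RPKM / 1%-coverage grids), then
  per-gene calls: transcribed, antisense-transcribed, convergent
  (tail-to-tail, 3'-3' gap < 500 nt, >= 50 doubly-covered positions in
  every replicate), TSS-overlapped (> 80% antisense coverage in a
  +/-100 nt window), and antisense-coverage quintile.
* **Metagene profiles** — gene bodies rescaled to 1000 virtual nt by
  piecewise-linear interpolation, unscaled flanks, 95% CI; a log2(mark/H3)
  ratio mode for chromatin marks.
* **XUT annotation by segmentation** — pooled decay-mutant coverage,
  log2(c+1), sliding-window smoothing, thresholded segments over a
  20 x 150 parameter grid (windows 10–200 nt, thresholds 1.44–216),
  length/ORF filters, a negative-binomial differential filter
  (fold > 2, BH-adjusted p < 0.05) and antisense/solo + novelty
  classification.
* **The inferential layer** — Wilcoxon rank-sum (exact for small
  tie-free samples), Spearman, Pearson chi-squared on 2x2 tables,
  Benjamini-Hochberg adjustment, per-pair time-course Pearson
  correlations and an "up in at least one time point" response
  classifier.
* **A synthetic-data generator** — annotations, stranded tracks, count
  matrices and time courses with planted truth labels for every recovered
  quantity (antisense flags, sense-suppression coupling, XUT folds,
  pair correlations), so the whole pipeline is testable offline.

## Worked example

```python
from antisense_scope import (
    SimulationConfig, generate_annotation, simulate_netseq,
    simulate_netseq_input, simulate_decay_tracks, call_genes,
    segment_xuts, spearman,
)

cfg = SimulationConfig(seed=7)           # 2 x 500 kb, 500 genes, 200 XUTs
ann = generate_annotation(cfg)
netseq = simulate_netseq(ann, cfg)       # two NET-seq replicates
control = simulate_netseq_input(ann, cfg)

calls, (rpkm_thr, cov_thr) = call_genes(ann.genes, netseq, control, None)
print(f"thresholds: RPKM > {rpkm_thr}, coverage > {cov_thr}")
print(f"antisense-transcribed genes: {int(calls.antisense_transcribed.sum())}/{len(calls)}")

as_genes = calls.index[calls.antisense_transcribed]
rho = spearman(calls.loc[as_genes, "sense_rpkm"],
               calls.loc[as_genes, "antisense_coverage"])
print(f"Spearman(sense RPKM, antisense coverage) = {rho:.2f}")

decay = simulate_decay_tracks(ann, cfg)  # WT x2 vs decay-mutant x2
res = segment_xuts(decay["exo2"], decay["wt"], mrnas=ann.mrnas,
                   orfs=ann.orfs, snornas=ann.of_kind("snoRNA"),
                   prior_lncrnas=ann.of_kind("lncRNA"))
n_anti = sum(1 for x in res.xuts if x.klass == "antisense")
print(f"selected window={res.window_w} nt, threshold={res.threshold_theta}")
print(f"XUTs: {len(res.xuts)} ({n_anti} antisense)")
```

Output:

```
thresholds: RPKM > 2.5, coverage > 0.01
antisense-transcribed genes: 300/500
Spearman(sense RPKM, antisense coverage) = -0.27
selected window=120 nt, threshold=1.44
XUTs: 199 (149 antisense)
```

Reading this: the thresholds were calibrated on the synthetic
untranscribed reference set; 300 of 500 genes are called
antisense-transcribed (exactly the planted fraction); their sense
transcription anti-correlates with antisense coverage, recovering the
sign of the planted suppression; and the grid-selected segmentation
recovers 199 of the 200 planted unstable transcripts with their
antisense/solo split.

A command-line layer wraps the same functions
(`antisense-scope simulate|quantify|call-antisense|metagene|segment|diffexpr|correlate|run`);
`antisense-scope run --seed 3 --outdir out/` executes every stage on
synthetic data and writes a JSON run report whose counts and percentages
are recomputed on every run.

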