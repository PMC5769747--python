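"""Threshold calibration and per-gene antisense classification.

The transcription thresholds are derived from a reference set of the
least-transcribed protein-coding genes: a region counts as transcribed when
its RPKM and coverage both exceed values that are more than twice the
reference median and above the reference maximum, snapped up to fixed grids
(0.1 RPKM, 1% coverage) to keep the derivation deterministic.  Each gene is
then called on both strands, classified for tail-to-tail convergence with a
neighbouring transcription unit, for antisense overlap of its TSS, and
binned by antisense coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Feature, StrandedTrack, opposite
from .quantify import FeatureSignal, feature_signal

CONVERGENCE_CLASSES = ("convergent_overlap", "nonconvergent_antisense", "no_antisense")


@dataclass
class AnalysisParameters:
    """Every calling constant in one place.

    ``rpkm_threshold``/``coverage_threshold`` are the fallback thresholds
    when no reference set is supplied; :func:`derive_thresholds` replaces
    them with data-driven values.
    """

    rpkm_threshold: float = 1.0
    coverage_threshold: float = 0.10
    n_reference_genes: int = 50
    convergence_max_gap: int = 500
    convergence_min_overlap: int = 50
    convergence_min_depth: float = 1.0
    tss_window_halfwidth: int = 100
    tss_overlap_fraction: float = 0.80
    n_coverage_bins: int = 5
    antisense_min_overlap: int = 50
    xut_min_length: int = 200
    fold_threshold: float = 2.0
    alpha: float = 0.05
    rrp6_ratio: float = 2.0
    mappability_floor: float = 0.01  # control-track mean tags/nt
    rpkm_grid: float = 0.1
    coverage_grid: float = 0.01

    def __post_init__(self) -> None:
        for name in ("rpkm_threshold", "coverage_threshold", "convergence_min_depth",
                     "fold_threshold", "rrp6_ratio", "rpkm_grid", "coverage_grid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("coverage_threshold", "tss_overlap_fraction", "alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class AntisenseCall:
    gene_id: str
    transcribed: bool
    antisense_transcribed: bool
    convergence_class: str
    coverage_bin: int | None
    tss_overlapped: bool

    def __post_init__(self) -> None:
        if self.convergence_class not in CONVERGENCE_CLASSES:
            raise ValueError(f"unknown convergence class {self.convergence_class!r}")
        if (self.coverage_bin is not None) != self.antisense_transcribed:
            raise ValueError("coverage_bin must be set iff antisense_transcribed")
        if (self.convergence_class == "no_antisense") == self.antisense_transcribed:
            raise ValueError("convergence class inconsistent with antisense call")


def select_reference_genes(
    signals: list[FeatureSignal],
    control_density: dict[str, float],
    params: AnalysisParameters,
) -> list[str]:
    """The ``n_reference_genes`` least-transcribed mappable genes.

    Genes whose control-track mean density falls below the mappability
    floor are excluded first (a quantitative stand-in for manual curation
    of repeat-rich loci); the remainder are ranked by mean sense RPKM
    ascending with ties broken by gene id.
    """
    candidates = [
        s for s in signals
        if control_density.get(s.feature_id, 0.0) >= params.mappability_floor
    ]
    if len(candidates) < params.n_reference_genes:
        raise ValueError(
            f"only {len(candidates)} mappable candidate genes, "
            f"need {params.n_reference_genes}"
        )
    ranked = sorted(candidates, key=lambda s: (s.mean_rpkm, s.feature_id))
    return [s.feature_id for s in ranked[: params.n_reference_genes]]


def _grid_above(value: float, step: float) -> float:
    """Smallest grid multiple strictly greater than ``value``."""
    k = math.floor(value / step + 1e-9) + 1
    return round(k * step, 10)


def derive_thresholds(
    reference_signals: list[FeatureSignal], params: AnalysisParameters | None = None
) -> tuple[float, float]:
    """Thresholds strictly above twice the reference median and its maximum.

    RPKM on a 0.1 grid, coverage on a 1% grid.
    """
    params = params or AnalysisParameters()
    if not reference_signals:
        raise ValueError("reference set is empty")
    rpkm = np.array([s.mean_rpkm for s in reference_signals])
    cov = np.array([s.aggregate_coverage for s in reference_signals])
    rpkm_thr = _grid_above(max(2.0 * float(np.median(rpkm)), float(rpkm.max())),
                           params.rpkm_grid)
    cov_thr = _grid_above(max(2.0 * float(np.median(cov)), float(cov.max())),
                          params.coverage_grid)
    return rpkm_thr, cov_thr


def call_gene(
    sense: FeatureSignal,
    antisense: FeatureSignal,
    params: AnalysisParameters,
    thresholds: tuple[float, float] | None = None,
) -> tuple[bool, bool]:
    """(transcribed, antisense_transcribed) for one gene.

    A strand is transcribed iff mean RPKM exceeds the RPKM threshold AND
    the aggregate (min-across-replicates) coverage exceeds the coverage
    threshold.
    """
    rpkm_thr, cov_thr = thresholds or (params.rpkm_threshold, params.coverage_threshold)
    transcribed = sense.mean_rpkm > rpkm_thr and sense.aggregate_coverage > cov_thr
    anti = antisense.mean_rpkm > rpkm_thr and antisense.aggregate_coverage > cov_thr
    return transcribed, anti


def classify_convergent(
    gene_a: Feature,
    gene_b: Feature,
    tracks: list[StrandedTrack],
    params: AnalysisParameters,
) -> bool:
    """Tail-to-tail convergence with overlapping nascent signal.

    True iff the strands oppose in tail-to-tail orientation, the 3'-3'
    distance is below ``convergence_max_gap``, and at least
    ``convergence_min_overlap`` positions (not necessarily contiguous)
    carry >= ``convergence_min_depth`` tags on BOTH strands in EVERY
    replicate.
    """
    if gene_a.chrom != gene_b.chrom or gene_a.strand == gene_b.strand:
        return False
    plus, minus = (gene_a, gene_b) if gene_a.strand == "+" else (gene_b, gene_a)
    # tail-to-tail: the plus-strand unit lies upstream of the minus-strand one
    if not (plus.start < minus.start and plus.end < minus.end):
        return False
    if abs(minus.start - plus.end) >= params.convergence_max_gap:
        return False
    lo = min(plus.start, minus.start)
    hi = max(plus.end, minus.end)
    ok = None
    for t in tracks:
        both = (t.array(gene_a.chrom, "+")[lo:hi] >= params.convergence_min_depth) & (
            t.array(gene_a.chrom, "-")[lo:hi] >= params.convergence_min_depth
        )
        ok = both if ok is None else (ok & both)
    return ok is not None and int(ok.sum()) >= params.convergence_min_overlap


def tss_overlap(
    gene: Feature, tracks: list[StrandedTrack], params: AnalysisParameters
) -> bool:
    """Antisense coverage > 80% in a +/-100 nt window around the sense TSS.

    The window is inclusive on both ends (201 positions), clipped at the
    chromosome edges (which shrinks the denominator), and the fraction must
    exceed the cutoff in every replicate.
    """
    arrs = [t.array(gene.chrom, opposite(gene.strand)) for t in tracks]
    n = len(arrs[0])
    lo = max(0, gene.tss - params.tss_window_halfwidth)
    hi = min(n, gene.tss + params.tss_window_halfwidth + 1)
    if hi <= lo:
        return False
    return all(
        float((a[lo:hi] >= 1).mean()) > params.tss_overlap_fraction for a in arrs
    )


def assign_coverage_bin(coverage: float, n_bins: int = 5) -> int:
    """Fixed-width antisense-coverage bin: [0,0.2) -> 1 ... [0.8,1.0] -> 5."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    width = 1.0 / n_bins
    return min(int(math.floor(coverage / width + 1e-9)) + 1, n_bins)


def call_genes(
    genes: list[Feature],
    tracks: list[StrandedTrack],
    control_track: StrandedTrack | None,
    params: AnalysisParameters | None = None,
    convergence_partners: list[Feature] | None = None,
    derive: bool = True,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Call every gene and classify its antisense status.

    Returns a table with one row per gene (transcribed,
    antisense_transcribed, convergence_class, coverage_bin, tss_overlapped,
    plus the underlying RPKM/coverage aggregates) and the thresholds used.
    ``convergence_partners`` defaults to the genes themselves; pass a wider
    TU list (snoRNAs, lncRNAs, ...) to allow convergence to any annotated
    unit.
    """
    params = params or AnalysisParameters()
    sense = {g.id: feature_signal(tracks, g, "sense") for g in genes}
    anti = {g.id: feature_signal(tracks, g, "antisense") for g in genes}

    thresholds = (params.rpkm_threshold, params.coverage_threshold)
    if derive:
        if control_track is None:
            raise ValueError("threshold derivation requires a control track")
        control_density = {
            g.id: feature_signal([control_track], g, "sense").density for g in genes
        }
        ref_ids = select_reference_genes(list(sense.values()), control_density, params)
        thresholds = derive_thresholds([sense[i] for i in ref_ids], params)

    partners = genes if convergence_partners is None else convergence_partners
    by_chrom: dict[str, list[Feature]] = {}
    for p in partners:
        by_chrom.setdefault(p.chrom, []).append(p)

    rows = []
    for g in genes:
        transcribed, anti_called = call_gene(sense[g.id], anti[g.id], params, thresholds)
        if anti_called:
            convergent = False
            for cand in by_chrom.get(g.chrom, []):
                if cand.id == g.id:
                    continue
                # only neighbours within reach of the 3'-3' gap rule matter
                if cand.start > g.end + params.convergence_max_gap:
                    continue
                if cand.end < g.start - params.convergence_max_gap:
                    continue
                if classify_convergent(g, cand, tracks, params):
                    convergent = True
                    break
            klass = "convergent_overlap" if convergent else "nonconvergent_antisense"
            cov_bin = assign_coverage_bin(
                anti[g.id].aggregate_coverage, params.n_coverage_bins
            )
        else:
            klass = "no_antisense"
            cov_bin = None
        rows.append(
            dict(
                gene_id=g.id,
                transcribed=transcribed,
                antisense_transcribed=anti_called,
                convergence_class=klass,
                coverage_bin=cov_bin,
                tss_overlapped=tss_overlap(g, tracks, params),
                sense_rpkm=sense[g.id].mean_rpkm,
                sense_coverage=sense[g.id].aggregate_coverage,
                antisense_rpkm=anti[g.id].mean_rpkm,
                antisense_coverage=anti[g.id].aggregate_coverage,
            )
        )
    calls = pd.DataFrame(rows).set_index("gene_id")
    return calls, thresholds
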