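"""Sliding-window segmentation of decay-mutant RNA-seq into XUT annotations.

The procedure mirrors coverage-based transcript assembly for unstable
lncRNAs: replicate mutant libraries are pooled per strand, the per-nt
signal is log2(c+1)-transformed, smoothed with a centred sliding window,
and maximal runs above a threshold become segments.  Segments shorter than
200 nt or overlapping a same-strand ORF are discarded; the survivors are
tested for differential expression (mutant vs WT, negative-binomial
likelihood-ratio test, BH-adjusted) and those with fold > 2 and adjusted
p < 0.05 are retained as XUTs, classed antisense (>= 50 nt opposite-strand
mRNA overlap) or solo, and flagged novel unless they touch a previously
annotated lncRNA.

A window x threshold grid (10-200 nt by 10; 1.44-216 by 1.44; 3000
combinations) is scanned and the parameterization with the best compromise
between mRNA detection (control segmentation) and XUT yield — harmonic mean
of mRNA recall and max-normalized candidate yield — is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .antisense_caller import AnalysisParameters
from .io_formats import Feature, StrandedTrack, opposite
from .quantify import snorna_size_factors
from .stats import nb_differential

DEFAULT_WINDOWS = tuple(range(10, 201, 10))
DEFAULT_THETAS = tuple(round(1.44 * k, 6) for k in range(1, 151))


@dataclass
class Segment:
    chrom: str
    strand: str
    start: int
    end: int
    window_w: int | None = None
    threshold_theta: float | None = None
    mean_smoothed: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("segment must span >= 1 nt")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class XutAnnotation:
    segment: Segment
    wt_counts: list[float]
    mut_counts: list[float]
    fold_change: float
    p_adj: float
    klass: str  # "antisense" or "solo"
    novel: bool


@dataclass
class GridResult:
    table: pd.DataFrame  # window_w, threshold_theta, n_segments, mrna_recall, score
    selected: int

    @property
    def selected_params(self) -> tuple[int, float]:
        row = self.table.iloc[self.selected]
        return int(row["window_w"]), float(row["threshold_theta"])


# ---------------------------------------------------------------------------
# Signal transforms
# ---------------------------------------------------------------------------

def pooled_log_signal(tracks: list[StrandedTrack]) -> dict[str, dict[str, np.ndarray]]:
    """Pool replicate tracks and log2(c+1)-transform per strand."""
    if not tracks:
        raise ValueError("need at least one track to pool")
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom in tracks[0].values:
        out[chrom] = {}
        for strand in ("+", "-"):
            pooled = np.sum([t.array(chrom, strand) for t in tracks], axis=0)
            out[chrom][strand] = np.log2(pooled + 1.0)
    return out


def smooth(signal: np.ndarray, w: int) -> np.ndarray:
    """Centred moving mean over ``w`` positions, truncated at the edges.

    The window at position i covers [i - ceil(w/2) + 1, i + floor(w/2)]
    (the asymmetric-centre convention for even widths); near the edges the
    mean runs over the available positions only.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(signal, dtype=float)
    n = len(x)
    left = math.ceil(w / 2) - 1
    right = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def extract_segments(
    smoothed: np.ndarray,
    theta: float,
    min_len: int = 200,
    chrom: str | None = None,
    strand: str | None = None,
    window: int | None = None,
) -> list[Segment]:
    """Maximal runs of smoothed signal strictly above ``theta``, >= min_len."""
    mask = np.asarray(smoothed) > theta
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(mask)]))
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out.append(
                Segment(
                    chrom=chrom or "", strand=strand or "+", start=int(s), end=int(e),
                    window_w=window, threshold_theta=theta,
                    mean_smoothed=float(np.mean(smoothed[s:e])),
                )
            )
    return out


def filter_orf_overlap(segments: list[Segment], orfs: list[Feature]) -> list[Segment]:
    """Drop segments sharing >= 1 nt with a same-strand ORF."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for o in orfs:
        by_key.setdefault((o.chrom, o.strand), []).append((o.start, o.end))
    for spans in by_key.values():
        spans.sort()
    kept = []
    for seg in segments:
        spans = by_key.get((seg.chrom, seg.strand), [])
        if not any(s < seg.end and e > seg.start for s, e in spans):
            kept.append(seg)
    return kept


# ---------------------------------------------------------------------------
# Differential filter and classification
# ---------------------------------------------------------------------------

def segment_counts(
    segments: list[Segment], tracks: list[StrandedTrack]
) -> np.ndarray:
    """Signal sum over each segment span, per track (n_segments x n_tracks)."""
    out = np.zeros((len(segments), len(tracks)))
    for i, seg in enumerate(segments):
        for j, t in enumerate(tracks):
            out[i, j] = t.array(seg.chrom, seg.strand)[seg.start:seg.end].sum()
    return out


def differential_filter(
    segments: list[Segment],
    wt_counts: np.ndarray,
    mut_counts: np.ndarray,
    size_factors: tuple[np.ndarray, np.ndarray],
    params: AnalysisParameters | None = None,
) -> tuple[list[Segment], pd.DataFrame]:
    """Retain segments with fold > 2 and BH-adjusted NB p < 0.05.

    ``size_factors`` holds the per-replicate WT and mutant scaling factors
    (sn(o)RNA-anchored).  Returns the retained segments and the full test
    table.  Raises with a single replicate per condition.
    """
    params = params or AnalysisParameters()
    if not segments:
        table = pd.DataFrame(
            columns=["wt_mean", "mut_mean", "fold_change", "pvalue", "p_adj", "retained"]
        )
        return [], table
    table = nb_differential(
        np.rint(wt_counts), np.rint(mut_counts), size_factors[0], size_factors[1],
        fold_threshold=params.fold_threshold, alpha_level=params.alpha,
    )
    kept = [seg for seg, keep in zip(segments, table["retained"]) if keep]
    return kept, table


def classify_segment(
    segment: Segment, mrnas: list[Feature], prior_lncrnas: list[Feature]
) -> tuple[str, bool]:
    """(klass, novel): antisense iff >= 50 nt opposite-strand mRNA overlap;
    novel iff zero overlap with any previously annotated lncRNA."""
    best_as = 0
    for m in mrnas:
        if m.chrom == segment.chrom and m.strand == opposite(segment.strand):
            ov = min(m.end, segment.end) - max(m.start, segment.start)
            best_as = max(best_as, ov)
    klass = "antisense" if best_as >= 50 else "solo"
    novel = True
    for l in prior_lncrnas:
        if l.chrom == segment.chrom and l.strand == segment.strand:
            if min(l.end, segment.end) - max(l.start, segment.start) >= 1:
                novel = False
                break
    return klass, novel


def rrp6_flag(
    wt_density: float, mut_density: float,
    params: AnalysisParameters | None = None,
    pseudocount: float = 0.01,
) -> bool:
    """Exosome-mutant sensitivity: (mut + p) / (WT + p) ratio above cutoff."""
    params = params or AnalysisParameters()
    return (mut_density + pseudocount) / (wt_density + pseudocount) > params.rrp6_ratio


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def _orf_prefix_masks(orfs: list[Feature], chrom_lengths: dict[str, int]) -> dict:
    masks = {}
    for (chrom, clen) in chrom_lengths.items():
        for strand in ("+", "-"):
            m = np.zeros(clen + 1)
            masks[(chrom, strand)] = m
    for o in orfs:
        key = (o.chrom, o.strand)
        if key in masks:
            # mark covered positions; converted to prefix sums below
            masks[key][o.start:o.end] += 1.0
    return {k: np.concatenate(([0.0], np.cumsum(v[:-1]))) for k, v in masks.items()}


def _mrna_recall(segments_by_key: dict, mrnas: list[Feature]) -> float:
    if not mrnas:
        return 0.0
    hit = 0
    for m in mrnas:
        segs = segments_by_key.get((m.chrom, m.strand), [])
        mlen = m.length
        for s, e in segs:
            if s >= m.end:
                break
            ov = min(e, m.end) - max(s, m.start)
            if ov >= 0.5 * mlen and ov >= 0.5 * (e - s):
                hit += 1
                break
    return hit / len(mrnas)


def grid_search(
    mutant_tracks: list[StrandedTrack],
    mrnas: list[Feature],
    orfs: list[Feature],
    params: AnalysisParameters | None = None,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    thetas: tuple[float, ...] = DEFAULT_THETAS,
) -> GridResult:
    """Scan the window x threshold grid and pick the best compromise.

    For each combination, segments are extracted on both strands; mRNA
    recall (fraction of mRNAs matched by a segment at >= 50% reciprocal
    overlap, before ORF filtering) measures control-detection quality, and
    the ORF-filtered candidate count measures XUT yield.  The score is the
    harmonic mean of recall and max-normalized yield; ties go to the
    smaller window, then the smaller threshold.
    """
    params = params or AnalysisParameters()
    pooled = pooled_log_signal(mutant_tracks)
    chrom_lengths = mutant_tracks[0].chrom_lengths
    orf_prefix = _orf_prefix_masks(orfs, chrom_lengths)
    sorted_mrnas = sorted(mrnas, key=lambda m: (m.chrom, m.strand, m.start))

    rows = []
    for w in windows:
        smoothed = {
            (chrom, strand): smooth(pooled[chrom][strand], w)
            for chrom in pooled for strand in ("+", "-")
        }
        peak = max((float(a.max()) for a in smoothed.values() if a.size), default=0.0)
        for theta in thetas:
            if theta >= peak:
                rows.append(dict(window_w=w, threshold_theta=theta, n_segments=0,
                                 mrna_recall=0.0))
                continue
            seg_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
            n_candidates = 0
            for key, arr in smoothed.items():
                segs = extract_segments(arr, theta, min_len=params.xut_min_length)
                spans = [(s.start, s.end) for s in segs]
                seg_spans[key] = spans
                pref = orf_prefix[key]
                for s, e in spans:
                    if pref[e] - pref[s] == 0:
                        n_candidates += 1
            recall = _mrna_recall(seg_spans, sorted_mrnas)
            rows.append(dict(window_w=w, threshold_theta=theta,
                             n_segments=n_candidates, mrna_recall=recall))
    table = pd.DataFrame(rows)
    max_yield = table["n_segments"].max()
    norm_yield = table["n_segments"] / max_yield if max_yield > 0 else 0.0
    denom = table["mrna_recall"] + norm_yield
    score = np.where(denom > 0, 2.0 * table["mrna_recall"] * norm_yield / denom, 0.0)
    table["score"] = score
    # argmax with ties to smaller window then smaller threshold: the table is
    # already in (window, theta) ascending order, so first strict max wins
    selected = int(np.argmax(table["score"].to_numpy()))
    return GridResult(table=table, selected=selected)


# ---------------------------------------------------------------------------
# End-to-end XUT annotation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    grid: GridResult | None
    window_w: int
    threshold_theta: float
    candidates: list[Segment]
    xuts: list[XutAnnotation]
    table: pd.DataFrame = field(repr=False)
    size_factors: pd.Series | None = None


def segment_xuts(
    mutant_tracks: list[StrandedTrack],
    wt_tracks: list[StrandedTrack],
    mrnas: list[Feature],
    orfs: list[Feature],
    snornas: list[Feature],
    prior_lncrnas: list[Feature] | None = None,
    params: AnalysisParameters | None = None,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    thetas: tuple[float, ...] = DEFAULT_THETAS,
    fixed: tuple[int, float] | None = None,
) -> SegmentationResult:
    """Full pipeline: grid-select parameters, segment, filter, test, classify.

    ``fixed=(window, theta)`` skips the grid.  Size factors for the
    differential test are sn(o)RNA-anchored, computed from the same tracks.
    """
    params = params or AnalysisParameters()
    prior_lncrnas = prior_lncrnas or []
    grid = None
    if fixed is not None:
        w, theta = fixed
    else:
        grid = grid_search(mutant_tracks, mrnas, orfs, params, windows, thetas)
        w, theta = grid.selected_params

    pooled = pooled_log_signal(mutant_tracks)
    candidates: list[Segment] = []
    for chrom in sorted(pooled):
        for strand in ("+", "-"):
            segs = extract_segments(
                smooth(pooled[chrom][strand], w), theta,
                min_len=params.xut_min_length, chrom=chrom, strand=strand, window=w,
            )
            candidates.extend(segs)
    candidates = filter_orf_overlap(candidates, orfs)

    all_tracks = list(wt_tracks) + list(mutant_tracks)
    if snornas:
        sno_feats = snornas
        sno_counts = pd.DataFrame(
            {
                t.sample_id: [
                    t.array(f.chrom, f.strand)[f.start:f.end].sum() for f in sno_feats
                ]
                for t in all_tracks
            },
            index=[f.id for f in sno_feats],
        ).round().astype(np.int64)
        sf = snorna_size_factors(sno_counts, list(sno_counts.index))
        sf_wt = sf[[t.sample_id for t in wt_tracks]].to_numpy()
        sf_mut = sf[[t.sample_id for t in mutant_tracks]].to_numpy()
    else:
        sf = None
        sf_wt = np.ones(len(wt_tracks))
        sf_mut = np.ones(len(mutant_tracks))
    # size factors scale counts to the reference sample: divide by 1/factor
    sf_wt = 1.0 / sf_wt
    sf_mut = 1.0 / sf_mut

    wt_counts = segment_counts(candidates, wt_tracks)
    mut_counts = segment_counts(candidates, mutant_tracks)
    retained, table = differential_filter(
        candidates, wt_counts, mut_counts, (sf_wt, sf_mut), params
    )
    xuts = []
    for i, seg in enumerate(candidates):
        if len(table) == 0 or not bool(table["retained"].iloc[i]):
            continue
        klass, novel = classify_segment(seg, mrnas, prior_lncrnas)
        xuts.append(
            XutAnnotation(
                segment=seg,
                wt_counts=list(wt_counts[i]),
                mut_counts=list(mut_counts[i]),
                fold_change=float(table["fold_change"].iloc[i]),
                p_adj=float(table["p_adj"].iloc[i]),
                klass=klass,
                novel=novel,
            )
        )
    return SegmentationResult(
        grid=grid, window_w=w, threshold_theta=theta, candidates=candidates,
        xuts=xuts, table=table, size_factors=sf,
    )
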