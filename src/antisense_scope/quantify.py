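"""Per-feature, strand-aware signal statistics.

RPKM (reads per kilobase per million uniquely mapped reads), coverage
fraction (proportion of a feature's nucleotides covered by >= 1 tag in each
replicate, aggregated as the minimum across replicates), tag densities,
sn(o)RNA anchor size factors and small-RNA summaries.

Strand semantics: ``strand="sense"`` measures tags on the feature's own
strand, ``strand="antisense"`` on the opposite strand, always over exactly
the annotated feature span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Feature, StrandedTrack, opposite

MEASURED_STRANDS = ("sense", "antisense")


@dataclass
class FeatureSignal:
    """Per-feature, per-replicate signal on one measured strand."""

    feature_id: str
    measured_strand: str
    rpkm: list[float]
    coverage_fraction: list[float]
    density: float  # mean tags per nt across replicates

    @property
    def mean_rpkm(self) -> float:
        return float(np.mean(self.rpkm))

    @property
    def aggregate_coverage(self) -> float:
        """Minimum coverage fraction across replicates (strictest reading
        of 'covered in each replicate')."""
        return float(min(self.coverage_fraction))


def _measured_array(track: StrandedTrack, feature: Feature, strand: str) -> np.ndarray:
    if strand not in MEASURED_STRANDS:
        raise ValueError(f"strand must be 'sense' or 'antisense', got {strand!r}")
    phys = feature.strand if strand == "sense" else opposite(feature.strand)
    arr = track.array(feature.chrom, phys)
    if feature.end > len(arr):
        raise ValueError(f"feature {feature.id!r} extends beyond {feature.chrom}")
    return arr[feature.start:feature.end]


def compute_rpkm(track: StrandedTrack, feature: Feature, strand: str = "sense") -> float:
    """RPKM = tags_in_span * 1e9 / (span_length * total_tags)."""
    if track.total_tags <= 0:
        raise ValueError("track.total_tags must be > 0 to compute RPKM")
    tags = float(_measured_array(track, feature, strand).sum())
    return tags * 1e9 / (feature.length * track.total_tags)


def compute_coverage_fraction(
    tracks: list[StrandedTrack], feature: Feature, strand: str = "sense"
) -> float:
    """Fraction of span positions with >= 1 tag, minimum across replicates."""
    if not tracks:
        raise ValueError("need at least one replicate track")
    return min(
        float((_measured_array(t, feature, strand) >= 1).mean()) for t in tracks
    )


def feature_signal(
    tracks: list[StrandedTrack], feature: Feature, strand: str = "sense"
) -> FeatureSignal:
    """Bundle per-replicate RPKM and coverage plus mean tag density."""
    if not tracks:
        raise ValueError("need at least one replicate track")
    rpkm = [compute_rpkm(t, feature, strand) for t in tracks]
    cov = [float((_measured_array(t, feature, strand) >= 1).mean()) for t in tracks]
    dens = float(
        np.mean([_measured_array(t, feature, strand).mean() for t in tracks])
    )
    return FeatureSignal(
        feature_id=feature.id,
        measured_strand=strand,
        rpkm=rpkm,
        coverage_fraction=cov,
        density=dens,
    )


def snorna_size_factors(
    matrix: pd.DataFrame, anchor_ids: list[str], reference: str | None = None
) -> pd.Series:
    """Per-sample scaling factors from decay-insensitive sn(o)RNA anchors.

    factor(sample) = median over anchors of
    (anchor count in reference sample / anchor count in sample); applying
    the factors makes anchor-ratio medians 1.  Anchors with zero count in
    the reference sample are excluded; if none survive this is an error.
    """
    reference = matrix.columns[0] if reference is None else reference
    anchors = [a for a in anchor_ids if a in matrix.index]
    sub = matrix.loc[anchors]
    sub = sub[sub[reference] > 0]
    if len(sub) == 0:
        raise ValueError("all anchors have zero count in the reference sample")
    if len(sub) < 3:
        raise ValueError("need >= 3 anchors with nonzero reference counts")
    ref = sub[reference].to_numpy(dtype=float)
    factors = {}
    with np.errstate(divide="ignore"):
        for col in matrix.columns:
            ratios = ref / sub[col].to_numpy(dtype=float)
            factors[col] = float(np.median(ratios))
    out = pd.Series(factors, name="size_factor")
    if not np.all(np.isfinite(out)) or (out <= 0).any():
        raise ValueError("non-positive or non-finite size factor")
    return out


def _overlap_counts(reads: pd.DataFrame, feature: Feature, stranded: bool) -> int:
    sub = reads[reads["chrom"] == feature.chrom]
    if stranded and "strand" in reads.columns:
        sub = sub[sub["strand"] == feature.strand]
    starts = sub["start"].to_numpy()
    ends = starts + sub["length"].to_numpy()
    return int(((starts < feature.end) & (ends > feature.start)).sum())


def smallrna_filter_and_density(
    reads: pd.DataFrame,
    features: list[Feature],
    length_range: tuple[int, int] = (18, 30),
    stranded: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Filter reads to the given length range (inclusive) and summarize.

    Returns per-feature density (retained tags overlapping the feature /
    feature length) and the retained-length histogram over the range.
    """
    lo, hi = length_range
    if (reads["length"] <= 0).any():
        raise ValueError("read lengths must be positive")
    kept = reads[(reads["length"] >= lo) & (reads["length"] <= hi)]
    hist = (
        kept["length"].value_counts().reindex(range(lo, hi + 1), fill_value=0).sort_index()
    )
    hist.name = "n_reads"
    rows = [
        dict(
            feature_id=f.id,
            n_reads=_overlap_counts(kept, f, stranded),
            density=_overlap_counts(kept, f, stranded) / f.length,
        )
        for f in features
    ]
    dens = pd.DataFrame(rows).set_index("feature_id") if rows else pd.DataFrame(
        columns=["n_reads", "density"]
    )
    return dens, hist


def overlapped_vs_solo_density(
    mrna: Feature,
    asxut: Feature,
    reads: pd.DataFrame,
    length_range: tuple[int, int] = (18, 30),
) -> tuple[float | None, float]:
    """Small-RNA density over the asXUT-overlapped vs 'solo' parts of an mRNA.

    The mRNA span is partitioned into its intersection with the
    opposite-strand antisense transcript and the remainder; a read is
    counted in every sub-span it overlaps.  With no intersection the
    overlapped density is undefined (None) and the solo density covers the
    whole mRNA.
    """
    lo, hi = length_range
    kept = reads[(reads["length"] >= lo) & (reads["length"] <= hi)]
    kept = kept[kept["chrom"] == mrna.chrom]
    if "strand" in kept.columns:
        kept = kept[kept["strand"] == mrna.strand]
    ov_start = max(mrna.start, asxut.start)
    ov_end = min(mrna.end, asxut.end)

    def density_over(spans: list[tuple[int, int]]) -> float:
        total_len = sum(e - s for s, e in spans)
        if total_len == 0:
            return 0.0
        starts = kept["start"].to_numpy()
        ends = starts + kept["length"].to_numpy()
        n = 0
        for s, e in spans:
            n += int(((starts < e) & (ends > s)).sum())
        return n / total_len

    if ov_start >= ov_end:
        return None, density_over([(mrna.start, mrna.end)])
    solo_spans = []
    if mrna.start < ov_start:
        solo_spans.append((mrna.start, ov_start))
    if ov_end < mrna.end:
        solo_spans.append((ov_end, mrna.end))
    return density_over([(ov_start, ov_end)]), density_over(solo_spans)
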