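"""Readers and writers for annotation and signal formats.

Internal coordinates are 0-based half-open on every type in this package.
GFF3 uses 1-based closed coordinates and is converted at the I/O boundary;
BED and bedGraph are already 0-based half-open and pass through unchanged.

The two central containers are :class:`Feature` (an annotated stranded
interval: gene, mRNA, ORF, ncRNA, snoRNA, XUT, ...) and
:class:`StrandedTrack` (dense per-nucleotide, per-strand tag-count vectors
for one sequencing sample).  Count tables travel as plain
:class:`pandas.DataFrame` objects (features x samples, non-negative
integers).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from gffutils.feature import feature_from_line

STRANDS = ("+", "-")

#: Feature kinds used throughout the package.
KNOWN_KINDS = frozenset(
    {"gene", "mRNA", "ORF", "ncRNA", "snoRNA", "tRNA", "lncRNA", "XUT", "repeat"}
)

#: Mapping from GFF3 ``type`` column values to internal kinds.  Unknown
#: types are preserved verbatim so no annotation information is lost.
DEFAULT_KIND_MAP = {
    "gene": "gene",
    "mRNA": "mRNA",
    "CDS": "ORF",
    "ORF": "ORF",
    "ncRNA": "ncRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snoRNA",
    "tRNA": "tRNA",
    "lncRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
    "XUT": "XUT",
    "repeat": "repeat",
    "repeat_region": "repeat",
}

#: Inverse mapping used when emitting GFF3 ``type`` values.
_KIND_TO_GFF = {"ORF": "CDS", "repeat": "repeat_region"}

ASSAYS = ("netseq_ip", "netseq_input", "rnaseq", "chip", "smallrna")


class GFFError(ValueError):
    """Raised on malformed GFF3 input."""


class TrackError(ValueError):
    """Raised on malformed bedGraph input or inconsistent track data."""


def opposite(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise ValueError(f"not a strand: {strand!r}")


@dataclass
class Feature:
    """An annotated genomic interval in 0-based half-open coordinates.

    The transcription start site (TSS) of a minus-strand feature is its
    ``end - 1`` position, and its termination site (TTS) is ``start``;
    plus-strand features are the mirror image.
    """

    id: str
    kind: str
    chrom: str
    start: int
    end: int
    strand: str
    parent: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"feature {self.id!r}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Position of the transcription start site (biological 5' end)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Position of the transcription termination site (biological 3' end)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class StrandedTrack:
    """Dense per-nucleotide, per-strand signal for one sample.

    ``values`` maps chromosome name to ``{"+": vector, "-": vector}``;
    vectors are float arrays of tag counts (NET-seq: one 3'-end tag per
    read; RNA-seq: per-position read coverage).  ``total_tags`` is library
    metadata (uniquely assigned tags), not recomputed from the vectors,
    because multi-nucleotide coverage breaks the sum-equals-reads identity.
    """

    sample_id: str
    replicate: int
    assay: str
    values: dict[str, dict[str, np.ndarray]]
    total_tags: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        peak = 0.0
        for chrom, per_strand in self.values.items():
            if set(per_strand) != set(STRANDS):
                raise TrackError(f"{chrom}: expected exactly one vector per strand")
            n_plus = len(per_strand["+"])
            if len(per_strand["-"]) != n_plus:
                raise TrackError(f"{chrom}: strand vectors differ in length")
            for strand in STRANDS:
                arr = np.asarray(per_strand[strand], dtype=float)
                if arr.size and arr.min() < 0:
                    raise TrackError(f"{chrom}{strand}: negative signal value")
                per_strand[strand] = arr
                if arr.size:
                    peak = max(peak, float(arr.max()))
        if self.total_tags < peak:
            raise TrackError("total_tags is below the maximum single-position value")

    def array(self, chrom: str, strand: str) -> np.ndarray:
        return self.values[chrom][strand]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v["+"]) for c, v in self.values.items()}


def validate_features(features: list[Feature]) -> None:
    """Check parent resolution and ORF-within-mRNA containment."""
    by_id = {f.id: f for f in features}
    for f in features:
        if f.parent is not None and f.parent not in by_id:
            raise GFFError(f"feature {f.id!r} references unknown parent {f.parent!r}")
        if f.kind == "ORF" and f.parent is not None:
            par = by_id[f.parent]
            if par.kind == "mRNA" and not (
                par.chrom == f.chrom
                and par.strand == f.strand
                and par.start <= f.start
                and f.end <= par.end
            ):
                raise GFFError(
                    f"ORF {f.id!r} is not contained in its parent mRNA {par.id!r}"
                )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path, kind_map: dict[str, str] | None = None) -> list[Feature]:
    """Read a GFF3 file into a list of :class:`Feature`.

    1-based closed GFF3 coordinates are converted to 0-based half-open.
    Parent links (``Parent=`` attribute) are resolved and validated.
    """
    kind_map = DEFAULT_KIND_MAP if kind_map is None else kind_map
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GFFError(
                    f"{path}: malformed GFF3 at line {lineno}: expected 9 columns"
                )
            try:
                rec = feature_from_line(line)
            except Exception as exc:  # bad ints, bad attribute syntax, ...
                raise GFFError(f"{path}: malformed GFF3 at line {lineno}: {exc}") from exc
            if rec.end < rec.start:
                raise GFFError(f"{path}: line {lineno}: end < start")
            if rec.strand not in STRANDS:
                raise GFFError(
                    f"{path}: line {lineno}: strand must be + or -, got {rec.strand!r}"
                )
            attrs = {k: (v[0] if len(v) == 1 else list(v)) for k, v in rec.attributes.items()}
            fid = attrs.pop("ID", f"{rec.featuretype}:{lineno}")
            parent = attrs.pop("Parent", None)
            features.append(
                Feature(
                    id=fid,
                    kind=kind_map.get(rec.featuretype, rec.featuretype),
                    chrom=rec.seqid,
                    start=rec.start - 1,
                    end=rec.end,
                    strand=rec.strand,
                    parent=parent,
                    attributes=attrs,
                )
            )
    validate_features(features)
    return features


def _fmt_attributes(f: Feature) -> str:
    parts = [f"ID={f.id}"]
    if f.parent is not None:
        parts.append(f"Parent={f.parent}")
    for key in sorted(f.attributes):
        parts.append(f"{key}={f.attributes[key]}")
    return ";".join(parts)


def write_gff3(
    features: list[Feature], path, chrom_lengths: dict[str, int] | None = None
) -> None:
    """Write features as GFF3 (1-based closed), sorted by (chrom, start, id)."""
    validate_features(features)
    ordered = sorted(features, key=lambda f: (f.chrom, f.start, f.id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom in sorted(chrom_lengths):
                fh.write(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}\n")
        for f in ordered:
            gff_type = _KIND_TO_GFF.get(f.kind, f.kind)
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "antisense_scope",
                        gff_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        _fmt_attributes(f),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def _read_bedgraph_file(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    arrays = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if df.empty:
        return arrays
    if (df["value"] < 0).any():
        raise TrackError(f"{path}: negative bedGraph value")
    if (df["start"] >= df["end"]).any():
        raise TrackError(f"{path}: interval with start >= end")
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in arrays:
            raise TrackError(f"{path}: unknown chromosome {chrom!r}")
        sub = sub.sort_values("start")
        if (sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]).any():
            raise TrackError(f"{path}: overlapping intervals on {chrom}")
        if sub["end"].max() > chrom_lengths[chrom]:
            raise TrackError(f"{path}: interval beyond end of {chrom}")
        arr = arrays[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s:e] = v
    return arrays


def read_stranded_bedgraph(
    path_plus,
    path_minus,
    *,
    chrom_lengths: dict[str, int],
    sample_id: str = "sample",
    replicate: int = 1,
    assay: str = "netseq_ip",
    total_tags: float,
) -> StrandedTrack:
    """Read one bedGraph file per strand into a dense :class:`StrandedTrack`.

    Positions not covered by any interval are 0.  ``total_tags`` is taken
    from the caller's sample metadata, never recomputed from the signal.
    """
    plus = _read_bedgraph_file(path_plus, chrom_lengths)
    minus = _read_bedgraph_file(path_minus, chrom_lengths)
    values = {c: {"+": plus[c], "-": minus[c]} for c in chrom_lengths}
    return StrandedTrack(
        sample_id=sample_id,
        replicate=replicate,
        assay=assay,
        values=values,
        total_tags=total_tags,
    )


def _write_bedgraph_array(fh, chrom: str, arr: np.ndarray) -> None:
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_stranded_bedgraph(track: StrandedTrack, path_plus, path_minus) -> None:
    """Write a track as one run-length-encoded bedGraph file per strand."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for chrom in sorted(track.values):
                _write_bedgraph_array(fh, chrom, track.values[chrom][strand])


# ---------------------------------------------------------------------------
# BED6 segments
# ---------------------------------------------------------------------------

def write_bed(segments: list[Feature], path) -> None:
    """Write features as BED6 (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for f in segments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def read_bed(path, kind: str = "XUT") -> list[Feature]:
    """Read a BED6 file written by :func:`write_bed`."""
    out: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise TrackError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = cols[:6]
            out.append(
                Feature(
                    id=name, kind=kind, chrom=chrom, start=int(start), end=int(end), strand=strand
                )
            )
    return out


# ---------------------------------------------------------------------------
# Count tables and config
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> pd.DataFrame:
    """Read a TSV count table (first column feature id) into a DataFrame.

    Cells must be non-negative integers; duplicated feature ids are an
    error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(
            np.equal(np.mod(vals, 1), 0)
        ):
            raise ValueError(f"{path}: non-integer count in column {col!r}")
        if (vals < 0).any():
            raise ValueError(f"{path}: negative count in column {col!r}")
    return df.astype(np.int64)


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_chrom_lengths(path) -> dict[str, int]:
    """Read chromosome lengths from a YAML mapping ``{name: length}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): int(v) for k, v in raw.items()}


def write_chrom_lengths(chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({str(k): int(v) for k, v in chrom_lengths.items()}, fh)
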