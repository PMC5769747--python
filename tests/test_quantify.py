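"""RPKM/coverage/density oracles and normalization factors."""

import numpy as np
import pandas as pd
import pytest

from antisense_scope.io_formats import Feature
from antisense_scope.quantify import (
    compute_coverage_fraction,
    compute_rpkm,
    feature_signal,
    overlapped_vs_solo_density,
    smallrna_filter_and_density,
    snorna_size_factors,
)
from conftest import make_track


def _span_track(tag_positions, length=2000, total_tags=1e6, strand="+"):
    arr = np.zeros(length)
    for p in tag_positions:
        arr[p] += 1
    other = np.zeros(length)
    values = {"c": {"+": arr if strand == "+" else other,
                    "-": other if strand == "+" else arr}}
    return make_track(values, total_tags=total_tags)


GENE = Feature(id="g", kind="gene", chrom="c", start=0, end=1000, strand="+")


@pytest.mark.parametrize(
    "n_tags,span,total,expected",
    [
        (0, 1000, 1e6, 0.0),
        (100, 1000, 1e6, 100.0),
        (5, 500, 2e6, 5.0),
    ],
)
def test_rpkm_formula(n_tags, span, total, expected):
    gene = Feature(id="g", kind="gene", chrom="c", start=0, end=span, strand="+")
    track = _span_track(range(n_tags), length=span + 10, total_tags=total)
    assert compute_rpkm(track, gene) == pytest.approx(expected)


def test_rpkm_requires_positive_total():
    track = _span_track([], total_tags=1.0)
    track.total_tags = 0
    with pytest.raises(ValueError):
        compute_rpkm(track, GENE)


def test_rpkm_invariant_under_library_scaling(rng):
    arr = rng.poisson(1.0, 1000).astype(float)
    t1 = make_track({"c": {"+": arr, "-": np.zeros(1000)}}, total_tags=5e5)
    t2 = make_track({"c": {"+": 3 * arr, "-": np.zeros(1000)}}, total_tags=1.5e6)
    assert compute_rpkm(t1, GENE) == pytest.approx(compute_rpkm(t2, GENE))


def test_coverage_minimum_across_replicates():
    gene = Feature(id="g", kind="gene", chrom="c", start=0, end=10, strand="+")
    rep1 = _span_track(range(6), length=10)       # 6/10 covered
    rep2 = _span_track(range(4), length=10)       # 4/10 covered
    assert compute_coverage_fraction([rep1, rep2], gene) == pytest.approx(0.4)
    zero = _span_track([], length=10)
    assert compute_coverage_fraction([zero, zero], gene) == 0.0
    full = _span_track(range(10), length=10)
    assert compute_coverage_fraction([full, full], gene) == 1.0


def test_coverage_monotone_under_adding_tags(rng):
    gene = Feature(id="g", kind="gene", chrom="c", start=0, end=500, strand="+")
    for _ in range(20):
        base = rng.poisson(0.3, 600).astype(float)
        more = base + rng.poisson(0.3, 600)
        t1 = make_track({"c": {"+": base, "-": np.zeros(600)}})
        t2 = make_track({"c": {"+": more, "-": np.zeros(600)}})
        assert compute_coverage_fraction([t2], gene) >= compute_coverage_fraction(
            [t1], gene
        )


def test_density_rpkm_consistency(rng):
    arr = rng.poisson(2.0, 1200).astype(float)
    track = make_track({"c": {"+": arr, "-": np.zeros(1200)}}, total_tags=2.5e6)
    gene = Feature(id="g", kind="gene", chrom="c", start=100, end=1100, strand="+")
    sig = feature_signal([track], gene)
    assert sig.rpkm[0] == pytest.approx(sig.density * 1e9 / track.total_tags)


def test_antisense_strand_measured_on_opposite_strand():
    arr = np.zeros(100)
    arr[10:20] = 1.0
    track = make_track({"c": {"+": np.zeros(100), "-": arr}})
    gene = Feature(id="g", kind="gene", chrom="c", start=0, end=100, strand="+")
    assert compute_rpkm(track, gene, "antisense") > 0
    assert compute_rpkm(track, gene, "sense") == 0.0


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def _anchor_matrix(ref_counts, sample_counts):
    return pd.DataFrame(
        {"ref": ref_counts, "s": sample_counts},
        index=[f"a{i}" for i in range(len(ref_counts))],
    )


def test_size_factor_identity_and_inverse_scale():
    m = _anchor_matrix([10, 20, 30], [10, 20, 30])
    sf = snorna_size_factors(m, list(m.index))
    assert sf["s"] == pytest.approx(1.0)
    m2 = _anchor_matrix([10, 20, 30], [20, 40, 60])
    assert snorna_size_factors(m2, list(m2.index))["s"] == pytest.approx(0.5)


def test_size_factor_median_oracle():
    m = _anchor_matrix([10, 20, 30], [20, 30, 90])
    sf = snorna_size_factors(m, list(m.index))
    assert sf["s"] == pytest.approx(np.median([0.5, 20 / 30, 30 / 90]))
    assert sf["s"] == pytest.approx(0.5)


def test_size_factor_zero_reference_anchors():
    m = _anchor_matrix([0, 10, 20, 30], [5, 20, 30, 90])
    sf = snorna_size_factors(m, list(m.index))  # first anchor excluded
    assert sf["s"] == pytest.approx(0.5)
    m_all_zero = _anchor_matrix([0, 0, 0], [1, 2, 3])
    with pytest.raises(ValueError):
        snorna_size_factors(m_all_zero, list(m_all_zero.index))


# ---------------------------------------------------------------------------
# Small RNA
# ---------------------------------------------------------------------------

def _reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "length", "strand"])


def test_smallrna_out_of_range_discarded():
    feat = Feature(id="f", kind="XUT", chrom="c", start=0, end=100, strand="+")
    reads = _reads([("c", 10, 35, "+"), ("c", 50, 35, "+")])
    dens, hist = smallrna_filter_and_density(reads, [feat])
    assert dens.loc["f", "density"] == 0.0
    assert hist.sum() == 0


def test_smallrna_density_counting_oracle():
    feat = Feature(id="f", kind="XUT", chrom="c", start=0, end=100, strand="+")
    reads = _reads([("c", i, 22, "+") for i in range(10)])
    dens, hist = smallrna_filter_and_density(reads, [feat])
    assert dens.loc["f", "density"] == pytest.approx(0.1)
    assert hist[22] == 10


def test_smallrna_inclusive_bounds():
    feat = Feature(id="f", kind="XUT", chrom="c", start=0, end=100, strand="+")
    reads = _reads([("c", 0, 18, "+"), ("c", 5, 30, "+"), ("c", 9, 17, "+"),
                    ("c", 9, 31, "+")])
    dens, hist = smallrna_filter_and_density(reads, [feat])
    assert int(dens.loc["f", "n_reads"]) == 2
    assert hist[18] == 1 and hist[30] == 1


def test_overlapped_vs_solo_density():
    mrna = Feature(id="m", kind="mRNA", chrom="c", start=0, end=200, strand="+")
    asxut = Feature(id="x", kind="XUT", chrom="c", start=150, end=400, strand="-")
    reads = _reads([("c", 150 + i, 20, "+") for i in range(5)])
    over, solo = overlapped_vs_solo_density(mrna, asxut, reads)
    assert over == pytest.approx(5 / 50)
    assert solo == 0.0


def test_overlapped_vs_solo_no_overlap_flagged():
    mrna = Feature(id="m", kind="mRNA", chrom="c", start=0, end=200, strand="+")
    far = Feature(id="x", kind="XUT", chrom="c", start=500, end=800, strand="-")
    reads = _reads([("c", 10, 22, "+")])
    over, solo = overlapped_vs_solo_density(mrna, far, reads)
    assert over is None
    assert solo == pytest.approx(1 / 200)


def test_overlapped_vs_solo_uniform_reads_equal():
    mrna = Feature(id="m", kind="mRNA", chrom="c", start=0, end=200, strand="+")
    asxut = Feature(id="x", kind="XUT", chrom="c", start=100, end=200, strand="-")
    reads = _reads([("c", i, 1, "+") for i in range(200)])
    over, solo = overlapped_vs_solo_density(mrna, asxut, reads)
    assert over == pytest.approx(solo)
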