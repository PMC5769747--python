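"""Threshold derivation grids, calling rules, convergence and TSS overlap."""

import numpy as np
import pytest

from antisense_scope.antisense_caller import (
    AnalysisParameters,
    assign_coverage_bin,
    call_gene,
    classify_convergent,
    derive_thresholds,
    select_reference_genes,
    tss_overlap,
)
from antisense_scope.io_formats import Feature
from antisense_scope.quantify import FeatureSignal
from conftest import make_track

PARAMS = AnalysisParameters()


def _sig(gid, rpkm, coverage=0.0):
    return FeatureSignal(
        feature_id=gid, measured_strand="sense", rpkm=[rpkm, rpkm],
        coverage_fraction=[coverage, coverage], density=rpkm / 100.0,
    )


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def test_threshold_from_low_reference_set():
    # reference distribution spanning 0.07-0.89 with median 0.45: the RPKM
    # cutoff lands on 1.0 (strictly above both 2x median = 0.90 and the max)
    vals = np.concatenate([np.linspace(0.07, 0.45, 25), np.linspace(0.45, 0.89, 25)])
    ref = [_sig(f"g{i}", v, coverage=0.001) for i, v in enumerate(vals)]
    rpkm_thr, cov_thr = derive_thresholds(ref)
    assert rpkm_thr == pytest.approx(1.0)


def test_threshold_all_zero_reference_is_one_grid_step():
    ref = [_sig(f"g{i}", 0.0, 0.0) for i in range(50)]
    rpkm_thr, cov_thr = derive_thresholds(ref)
    assert rpkm_thr == pytest.approx(0.1)
    assert cov_thr == pytest.approx(0.01)


def test_threshold_grid_rule_max_dominates():
    # 2x median = 1.2 but the max 1.5 dominates; next 0.1 grid point is 1.6
    vals = [0.6] * 49 + [1.5]
    ref = [_sig(f"g{i}", v) for i, v in enumerate(vals)]
    rpkm_thr, _ = derive_thresholds(ref)
    assert rpkm_thr == pytest.approx(1.6)


def test_threshold_exact_grid_value_is_excluded():
    # thresholds are strictly greater: a max of exactly 1.0 pushes to 1.1
    vals = [0.2] * 49 + [1.0]
    ref = [_sig(f"g{i}", v) for i, v in enumerate(vals)]
    assert derive_thresholds(ref)[0] == pytest.approx(1.1)


# ---------------------------------------------------------------------------
# Reference selection
# ---------------------------------------------------------------------------

def test_reference_selection_returns_all_when_exact():
    sigs = [_sig(f"g{i:03d}", float(i)) for i in range(50)]
    ctrl = {s.feature_id: 1.0 for s in sigs}
    assert select_reference_genes(sigs, ctrl, PARAMS) == [s.feature_id for s in sigs]


def test_reference_selection_excludes_unmappable():
    sigs = [_sig(f"g{i:03d}", float(i)) for i in range(60)]
    ctrl = {s.feature_id: 1.0 for s in sigs}
    ctrl["g000"] = 0.0  # below the mappability floor despite lowest RPKM
    chosen = select_reference_genes(sigs, ctrl, PARAMS)
    assert "g000" not in chosen
    assert len(chosen) == 50


def test_reference_selection_sort_oracle(rng):
    rpkms = rng.lognormal(1.0, 1.0, size=200)
    sigs = [_sig(f"g{i:03d}", r) for i, r in enumerate(rpkms)]
    ctrl = {s.feature_id: 1.0 for s in sigs}
    chosen = select_reference_genes(sigs, ctrl, PARAMS)
    expected = [s.feature_id for s in sorted(sigs, key=lambda s: (s.mean_rpkm,
                                                                  s.feature_id))][:50]
    assert chosen == expected


def test_reference_selection_too_few_candidates():
    sigs = [_sig(f"g{i}", 1.0) for i in range(10)]
    with pytest.raises(ValueError):
        select_reference_genes(sigs, {s.feature_id: 1.0 for s in sigs}, PARAMS)


# ---------------------------------------------------------------------------
# Calling rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rpkm,cov,expected",
    [(2.0, 0.25, True), (2.0, 0.05, False), (0.5, 0.25, False), (0.0, 0.0, False)],
)
def test_call_gene_joint_rule(rpkm, cov, expected):
    sense = _sig("g", 10.0, 0.9)
    anti = _sig("g", rpkm, cov)
    transcribed, anti_called = call_gene(sense, anti, PARAMS)
    assert transcribed is True
    assert anti_called is expected


def test_calling_monotone_under_adding_signal():
    sense = _sig("g", 10.0, 0.9)
    anti_low = _sig("g", 1.2, 0.12)
    _, called_low = call_gene(sense, anti_low, PARAMS)
    anti_high = _sig("g", 2.4, 0.30)  # strictly more signal everywhere
    _, called_high = call_gene(sense, anti_high, PARAMS)
    assert called_low is True and called_high is True


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------

def _pair_tracks(gap, n_double, length=3000):
    """Two replicate tracks where n_double positions are covered on both
    strands inside the pair locus."""
    plus = np.zeros(length)
    minus = np.zeros(length)
    plus[100:1100] = 2.0  # gene A body
    minus[1100 + gap:2100 + gap] = 2.0  # gene B body
    # doubly covered positions at A's 3' end
    minus[1100 - n_double:1100] = 1.0
    values = {"c": {"+": plus, "-": minus}}
    return [make_track(values, replicate=1), make_track(values, replicate=2)]


def _pair_genes(gap):
    a = Feature(id="A", kind="gene", chrom="c", start=100, end=1100, strand="+")
    b = Feature(id="B", kind="gene", chrom="c", start=1100 + gap, end=2100 + gap,
                strand="-")
    return a, b


def test_convergent_same_strand_false():
    a = Feature(id="A", kind="gene", chrom="c", start=100, end=1100, strand="+")
    b = Feature(id="B", kind="gene", chrom="c", start=1200, end=2200, strand="+")
    assert classify_convergent(a, b, _pair_tracks(100, 60), PARAMS) is False


def test_convergent_gap_and_overlap_rules():
    a, b = _pair_genes(100)
    assert classify_convergent(a, b, _pair_tracks(100, 60), PARAMS) is True
    assert classify_convergent(a, b, _pair_tracks(100, 40), PARAMS) is False
    a600, b600 = _pair_genes(600)
    assert classify_convergent(a600, b600, _pair_tracks(600, 200), PARAMS) is False


def test_convergent_requires_depth_in_every_replicate():
    a, b = _pair_genes(100)
    tracks = _pair_tracks(100, 60)
    # wipe the double coverage in replicate 2 only
    tracks[1].values["c"]["-"][1040:1100] = 0.0
    assert classify_convergent(a, b, tracks, PARAMS) is False


def test_convergent_symmetric_in_argument_order():
    a, b = _pair_genes(100)
    tracks = _pair_tracks(100, 60)
    assert classify_convergent(a, b, tracks, PARAMS) == classify_convergent(
        b, a, tracks, PARAMS
    )


# ---------------------------------------------------------------------------
# TSS overlap
# ---------------------------------------------------------------------------

def _tss_tracks(n_covered, tss=1000, length=3000):
    minus = np.zeros(length)
    # cover n_covered positions of the 201-nt window centred on the TSS
    minus[tss - 100:tss - 100 + n_covered] = 1.0
    values = {"c": {"+": np.zeros(length), "-": minus}}
    return [make_track(values, replicate=1), make_track(values, replicate=2)]


@pytest.mark.parametrize("n_covered,expected", [(0, False), (170, True), (160, False)])
def test_tss_overlap_fraction(n_covered, expected):
    gene = Feature(id="g", kind="gene", chrom="c", start=1000, end=2000, strand="+")
    assert tss_overlap(gene, _tss_tracks(n_covered), PARAMS) is expected


def test_tss_window_clipped_at_chromosome_start():
    # TSS at position 30: window is [0, 131), denominator shrinks to 131
    gene = Feature(id="g", kind="gene", chrom="c", start=30, end=500, strand="+")
    minus = np.zeros(600)
    minus[0:131] = 1.0
    tracks = [make_track({"c": {"+": np.zeros(600), "-": minus}})]
    assert tss_overlap(gene, tracks, PARAMS) is True


# ---------------------------------------------------------------------------
# Coverage bins
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cov,expected",
    [(0.0, 1), (0.19, 1), (0.2, 2), (0.4, 3), (0.6, 4), (0.85, 5), (1.0, 5)],
)
def test_coverage_bins(cov, expected):
    assert assign_coverage_bin(cov) == expected


def test_coverage_bin_rejects_out_of_range():
    with pytest.raises(ValueError):
        assign_coverage_bin(1.2)
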