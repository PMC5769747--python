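"""Smoothing, segment extraction, ORF/differential filters and the grid."""

import numpy as np
import pytest

from antisense_scope.antisense_caller import AnalysisParameters
from antisense_scope.io_formats import Feature
from antisense_scope.segmentation import (
    DEFAULT_THETAS,
    DEFAULT_WINDOWS,
    Segment,
    classify_segment,
    differential_filter,
    extract_segments,
    filter_orf_overlap,
    grid_search,
    pooled_log_signal,
    rrp6_flag,
    smooth,
)
from conftest import make_track

PARAMS = AnalysisParameters()


# ---------------------------------------------------------------------------
# pooled_log_signal
# ---------------------------------------------------------------------------

def test_pooled_log_signal_closed_forms():
    n = 100
    t1 = make_track({"c": {"+": np.zeros(n), "-": np.zeros(n)}})
    pooled = pooled_log_signal([t1, t1])
    np.testing.assert_allclose(pooled["c"]["+"], 0.0)
    arr = np.zeros(n)
    arr[0] = 1.0
    arr[1] = 3.0
    t2 = make_track({"c": {"+": arr, "-": np.zeros(n)}})
    pooled = pooled_log_signal([t2])
    assert pooled["c"]["+"][0] == pytest.approx(1.0)
    assert pooled["c"]["+"][1] == pytest.approx(2.0)


def test_pooled_log_signal_matches_bruteforce(rng):
    a = rng.poisson(1.0, 500).astype(float)
    b = rng.poisson(2.0, 500).astype(float)
    t1 = make_track({"c": {"+": a, "-": b}})
    t2 = make_track({"c": {"+": b, "-": a}})
    pooled = pooled_log_signal([t1, t2])
    np.testing.assert_allclose(pooled["c"]["+"], np.log2(a + b + 1.0))
    np.testing.assert_allclose(pooled["c"]["-"], np.log2(a + b + 1.0))


# ---------------------------------------------------------------------------
# smooth
# ---------------------------------------------------------------------------

def test_smooth_constant_unchanged():
    np.testing.assert_allclose(smooth(np.full(300, 2.5), 20), 2.5)


def test_smooth_unit_impulse_interior():
    x = np.zeros(200)
    x[100] = 1.0
    out = smooth(x, 10)
    covered = np.flatnonzero(out > 0)
    assert len(covered) == 10
    np.testing.assert_allclose(out[covered], 0.1)


def _smooth_bruteforce(x, w):
    import math

    left = math.ceil(w / 2) - 1
    right = w // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo = max(0, i - left)
        hi = min(len(x), i + right + 1)
        out[i] = x[lo:hi].mean()
    return out


@pytest.mark.parametrize("w", [1, 2, 7, 10, 15, 200])
def test_smooth_matches_enumeration_at_edges(rng, w):
    x = rng.normal(size=333)
    np.testing.assert_allclose(smooth(x, w), _smooth_bruteforce(x, w), atol=1e-10)


# ---------------------------------------------------------------------------
# extract_segments
# ---------------------------------------------------------------------------

def brute_force_segments(values, theta, min_len):
    segs, i, n = [], 0, len(values)
    while i < n:
        if values[i] > theta:
            j = i
            while j < n and values[j] > theta:
                j += 1
            if j - i >= min_len:
                segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def test_extract_segments_basic_rules():
    below = np.full(1000, 0.5)
    assert extract_segments(below, 1.44) == []
    run = np.zeros(1000)
    run[100:400] = 2.0
    segs = extract_segments(run, 1.44)
    assert [(s.start, s.end) for s in segs] == [(100, 400)]
    short = np.zeros(1000)
    short[100:250] = 2.0
    assert extract_segments(short, 1.44) == []


def test_extract_segments_strictly_above():
    x = np.zeros(500)
    x[100:350] = 1.44  # exactly at the threshold: not a segment
    assert extract_segments(x, 1.44) == []


def test_extract_segments_matches_bruteforce(rng):
    for _ in range(30):
        n = int(rng.integers(50, 3000))
        x = rng.normal(1.0, 1.0, n).cumsum() / 10.0
        theta = float(rng.uniform(x.min(), x.max()))
        min_len = int(rng.choice([1, 20, 200]))
        got = [(s.start, s.end) for s in extract_segments(x, theta, min_len)]
        assert got == brute_force_segments(x, theta, min_len)


def test_extract_segments_theta_monotonicity(rng):
    x = smooth(rng.poisson(1.0, 5000).astype(float), 50)
    prev = None
    for theta in np.linspace(x.min(), x.max(), 10):
        total = sum(s.length for s in extract_segments(x, theta, min_len=1))
        if prev is not None:
            assert total <= prev
        prev = total


# ---------------------------------------------------------------------------
# ORF filter and classification
# ---------------------------------------------------------------------------

def _seg(start, end, strand="+"):
    return Segment(chrom="c", strand=strand, start=start, end=end)


def test_filter_orf_overlap_rules():
    segs = [_seg(100, 400), _seg(600, 900)]
    assert filter_orf_overlap(segs, []) == segs
    # 1 nt same-strand overlap drops the segment
    orf_touch = Feature(id="o", kind="ORF", chrom="c", start=399, end=500, strand="+")
    assert filter_orf_overlap(segs, [orf_touch]) == [segs[1]]
    # opposite-strand overlap is ignored
    orf_opp = Feature(id="o", kind="ORF", chrom="c", start=0, end=1000, strand="-")
    assert filter_orf_overlap(segs, [orf_opp]) == segs


@pytest.mark.parametrize("overlap,expected", [(50, "antisense"), (49, "solo")])
def test_classify_segment_antisense_boundary(overlap, expected):
    seg = _seg(1000, 1400, strand="+")
    mrna = Feature(id="m", kind="mRNA", chrom="c", start=1400 - overlap, end=2000,
                   strand="-")
    klass, novel = classify_segment(seg, [mrna], [])
    assert klass == expected
    assert novel is True


def test_classify_segment_prior_lncrna_single_nt():
    seg = _seg(1000, 1400)
    prior = Feature(id="l", kind="lncRNA", chrom="c", start=1399, end=1600, strand="+")
    _, novel = classify_segment(seg, [], [prior])
    assert novel is False
    # opposite-strand prior annotation does not de-novelize
    prior_opp = Feature(id="l", kind="lncRNA", chrom="c", start=1399, end=1600,
                        strand="-")
    assert classify_segment(seg, [], [prior_opp])[1] is True


# ---------------------------------------------------------------------------
# Differential filter
# ---------------------------------------------------------------------------

def _two_group_segments(wt, mut):
    segs = [_seg(i * 1000, i * 1000 + 300) for i in range(len(wt))]
    return segs, np.asarray(wt, float), np.asarray(mut, float)


def test_differential_filter_identical_counts_not_retained():
    segs, wt, mut = _two_group_segments([[50, 60]] * 10, [[50, 60]] * 10)
    kept, table = differential_filter(segs, wt, mut, (np.ones(2), np.ones(2)))
    assert kept == []
    np.testing.assert_allclose(table["fold_change"], 1.0, atol=0.05)


def test_differential_filter_strong_enrichment_retained():
    wt = [[2, 3]] + [[50, 60]] * 9
    mut = [[40, 50]] + [[55, 58]] * 9
    segs, wt, mut = _two_group_segments(wt, mut)
    kept, table = differential_filter(segs, wt, mut, (np.ones(2), np.ones(2)))
    assert kept == [segs[0]]
    assert table["fold_change"].iloc[0] > 2
    assert table["p_adj"].iloc[0] < 0.05


def test_differential_filter_mutant_zero_not_retained():
    wt = [[40, 50]] + [[50, 60]] * 9
    mut = [[0, 0]] + [[55, 58]] * 9
    segs, wt, mut = _two_group_segments(wt, mut)
    kept, table = differential_filter(segs, wt, mut, (np.ones(2), np.ones(2)))
    assert kept == []
    assert table["fold_change"].iloc[0] < 1


def test_differential_filter_single_replicate_errors():
    segs = [_seg(0, 300)]
    with pytest.raises(ValueError):
        differential_filter(segs, np.array([[5.0]]), np.array([[50.0]]),
                            (np.ones(1), np.ones(1)))


def test_nb_pvalue_against_statsmodels_glm_oracle():
    """LRT p from the in-repo NB fit matches an independent IRLS fit."""
    import statsmodels.api as sm
    from scipy.stats import chi2

    from antisense_scope.stats import nb_test

    alpha = 0.05
    wt = np.array([2.0, 3.0])
    mut = np.array([40.0, 50.0])
    p_ours = nb_test(wt, mut, np.ones(2), np.ones(2), alpha)

    y = np.concatenate([wt, mut])
    x = np.column_stack([np.ones(4), [0, 0, 1, 1]])
    fam = sm.families.NegativeBinomial(alpha=alpha)
    full = sm.GLM(y, x, family=fam).fit()
    null = sm.GLM(y, np.ones((4, 1)), family=fam).fit()
    p_oracle = float(chi2.sf(2 * (full.llf - null.llf), 1))
    assert p_ours == pytest.approx(p_oracle, rel=1e-3)
    assert p_ours < 0.05


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def test_default_grid_dimensions():
    assert len(DEFAULT_WINDOWS) == 20
    assert len(DEFAULT_THETAS) == 150
    assert DEFAULT_WINDOWS[0] == 10 and DEFAULT_WINDOWS[-1] == 200
    assert DEFAULT_THETAS[0] == pytest.approx(1.44)
    assert DEFAULT_THETAS[-1] == pytest.approx(216.0)


def _toy_tracks(rng, n=6000):
    sig = np.zeros(n)
    sig[1000:2000] = 6.0  # an mRNA
    sig[3000:3500] = 4.0  # a candidate transcript
    noise = rng.poisson(0.01, n)
    values = {"c": {"+": sig + noise, "-": np.zeros(n)}}
    return [make_track(values, replicate=1, assay="rnaseq"),
            make_track(values, replicate=2, assay="rnaseq")]


def test_grid_search_combination_counts(rng):
    tracks = _toy_tracks(rng)
    mrna = Feature(id="m", kind="mRNA", chrom="c", start=1000, end=2000, strand="+")
    orf = Feature(id="o", kind="ORF", chrom="c", start=1100, end=1900, strand="+")
    g1 = grid_search(tracks, [mrna], [orf], windows=(10,), thetas=(1.44,))
    assert len(g1.table) == 1
    g4 = grid_search(tracks, [mrna], [orf], windows=(10, 20), thetas=(1.44, 2.88))
    assert len(g4.table) == 4
    w, theta = g4.selected_params
    assert w in (10, 20) and theta in (1.44, 2.88)


def test_grid_search_finds_both_feature_types(rng):
    tracks = _toy_tracks(rng)
    mrna = Feature(id="m", kind="mRNA", chrom="c", start=1000, end=2000, strand="+")
    orf = Feature(id="o", kind="ORF", chrom="c", start=1100, end=1900, strand="+")
    g = grid_search(tracks, [mrna], [orf], windows=(10, 50),
                    thetas=(1.44, 2.88, 4.32))
    best = g.table.iloc[g.selected]
    assert best["mrna_recall"] == 1.0
    assert best["n_segments"] >= 1  # the ORF-free candidate


def test_grid_search_tie_breaks_to_smaller_parameters(rng):
    # flat zero signal: every combination scores 0, the first (smallest
    # window, smallest theta) must win
    values = {"c": {"+": np.zeros(2000), "-": np.zeros(2000)}}
    tracks = [make_track(values, total_tags=1.0)]
    g = grid_search(tracks, [], [], windows=(10, 20), thetas=(1.44, 2.88))
    assert g.selected_params == (10, 1.44)


# ---------------------------------------------------------------------------
# Rrp6 ratio flag
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "wt,mut,expected",
    [(0.7, 0.7, False), (0.5, 1.2, True), (0.0, 0.0, False)],
)
def test_rrp6_flag(wt, mut, expected):
    assert rrp6_flag(wt, mut) is expected
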