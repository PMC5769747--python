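"""The inferential layer: rank tests, correlations, NB differential tests.

Contains the shared two-condition negative-binomial likelihood-ratio test
with a moment-estimated common dispersion (used both by the segmentation
differential filter and the time-course response classifier),
Benjamini-Hochberg adjustment, Wilcoxon rank-sum and Spearman wrappers, a
plain Pearson chi-squared for 2x2 tables, and per-pair time-course
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

_MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------------------
# Classic tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum p-value.

    Exact by enumeration when the pooled sample size is <= 20 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    stat, p, _dof, _exp = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Negative-binomial two-condition test
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts_a: np.ndarray, counts_b: np.ndarray, sf_a: np.ndarray, sf_b: np.ndarray
) -> float:
    """Moment estimate of a common NB dispersion across features.

    For each feature the within-condition variance of normalized counts in
    excess of the mean gives a per-feature alpha (var = mu + alpha mu^2);
    the median across features, floored at a tiny positive value, is the
    common dispersion.
    """
    za = np.asarray(counts_a, dtype=float) / np.asarray(sf_a, dtype=float)
    zb = np.asarray(counts_b, dtype=float) / np.asarray(sf_b, dtype=float)
    alphas = []
    for z in (za, zb):
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        ok = m > 0
        alphas.append((v[ok] - m[ok]) / m[ok] ** 2)
    pooled = np.concatenate(alphas)
    if pooled.size == 0:
        return _MIN_DISPERSION
    return float(max(np.median(pooled), _MIN_DISPERSION))


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= _MIN_DISPERSION:
        return float(sps.poisson.logpmf(counts, mu).sum())
    n = 1.0 / alpha
    p = n / (n + mu)
    return float(sps.nbinom.logpmf(counts, n, p).sum())


def _fit_rate(counts: np.ndarray, sf: np.ndarray, alpha: float) -> float:
    """MLE of a common rate q with per-sample offsets (mu_i = q * s_i)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    q0 = total / sf.sum()

    def nll(logq: float) -> float:
        return -_nb_loglik(counts, np.exp(logq) * sf, alpha)

    res = minimize_scalar(
        nll, bounds=(np.log(q0) - 8.0, np.log(q0) + 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def nb_test(
    counts_a: np.ndarray, counts_b: np.ndarray,
    sf_a: np.ndarray, sf_b: np.ndarray,
    dispersion: float,
) -> float:
    """Likelihood-ratio p-value for a two-condition NB rate difference.

    Null: one common rate across all samples; alternative: one rate per
    condition.  The dispersion is held fixed; the statistic is referred to
    chi-squared with 1 df.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    all_counts = np.concatenate([counts_a, counts_b])
    all_sf = np.concatenate([sf_a, sf_b])
    q0 = _fit_rate(all_counts, all_sf, dispersion)
    qa = _fit_rate(counts_a, sf_a, dispersion)
    qb = _fit_rate(counts_b, sf_b, dispersion)
    ll_null = _nb_loglik(all_counts, np.maximum(q0 * all_sf, 1e-12), dispersion)
    ll_alt = _nb_loglik(counts_a, np.maximum(qa * sf_a, 1e-12), dispersion) + _nb_loglik(
        counts_b, np.maximum(qb * sf_b, 1e-12), dispersion
    )
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return float(sps.chi2.sf(stat, df=1))


def nb_differential(
    wt_counts: np.ndarray,
    mut_counts: np.ndarray,
    sf_wt: np.ndarray,
    sf_mut: np.ndarray,
    fold_threshold: float = 2.0,
    alpha_level: float = 0.05,
    pseudocount: float = 0.5,
    index=None,
) -> pd.DataFrame:
    """Two-condition NB differential test over a feature x replicate matrix.

    Returns a table with normalized means, fold change (mutant/WT with a
    pseudocount on each side), raw and BH-adjusted p-values, and the
    retained flag (fold > fold_threshold AND p_adj < alpha_level).
    Requires >= 2 replicates per condition (dispersion is unidentifiable
    otherwise).
    """
    wt = np.atleast_2d(np.asarray(wt_counts, dtype=float))
    mut = np.atleast_2d(np.asarray(mut_counts, dtype=float))
    if wt.shape[1] < 2 or mut.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    sf_wt = np.asarray(sf_wt, dtype=float)
    sf_mut = np.asarray(sf_mut, dtype=float)
    disp = estimate_dispersion(wt, mut, sf_wt, sf_mut)
    wt_mean = (wt / sf_wt).mean(axis=1)
    mut_mean = (mut / sf_mut).mean(axis=1)
    fold = (mut_mean + pseudocount) / (wt_mean + pseudocount)
    pvals = np.array(
        [nb_test(wt[i], mut[i], sf_wt, sf_mut, disp) for i in range(len(wt))]
    )
    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        dict(
            wt_mean=wt_mean,
            mut_mean=mut_mean,
            fold_change=fold,
            pvalue=pvals,
            p_adj=padj,
            retained=(fold > fold_threshold) & (padj < alpha_level),
        ),
        index=index,
    )
    out.attrs["dispersion"] = disp
    return out


# ---------------------------------------------------------------------------
# Time-course analyses
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelation:
    mrna_id: str
    asxut_id: str
    pearson_r: float
    group: str  # "responsive" or "insensitive"


def _timepoint_means(table: pd.DataFrame, timepoints: list[str]) -> pd.DataFrame:
    """Collapse {timepoint}_{replicate} columns to per-timepoint means."""
    cols = {}
    for tp in timepoints:
        reps = [c for c in table.columns if c == tp or c.startswith(f"{tp}_")]
        if not reps:
            raise ValueError(f"no columns found for time point {tp!r}")
        cols[tp] = table[reps].mean(axis=1)
    return pd.DataFrame(cols)


def pair_timecourse_correlation(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    timepoints: list[str],
    response_labels: dict[str, bool] | None = None,
) -> tuple[list[PairCorrelation], dict[str, float]]:
    """Pearson r per (mRNA, asXUT) pair over the time points.

    ``pairs`` needs columns mrna_id / xut_id and, unless
    ``response_labels`` maps xut_id -> responsive, a ``responsive`` column.
    Pairs where either series has zero variance are skipped (r undefined).
    Returns the per-pair records and the median r per group.
    """
    if len(timepoints) < 3:
        raise ValueError("need at least 3 time points")
    means = _timepoint_means(table, timepoints)
    out: list[PairCorrelation] = []
    for _, row in pairs.iterrows():
        if response_labels is not None:
            responsive = bool(response_labels[row["xut_id"]])
        else:
            responsive = bool(row["responsive"])
        x = means.loc[row["xut_id"]].to_numpy(dtype=float)
        y = means.loc[row["mrna_id"]].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out.append(
            PairCorrelation(
                mrna_id=row["mrna_id"], asxut_id=row["xut_id"], pearson_r=r,
                group="responsive" if responsive else "insensitive",
            )
        )
    medians = {}
    for group in ("responsive", "insensitive"):
        rs = [p.pearson_r for p in out if p.group == group]
        if rs:
            medians[group] = float(np.median(rs))
    return out, medians


def response_classifier(
    table: pd.DataFrame,
    timepoints: list[str],
    n_replicates: int = 2,
    fold_threshold: float = 2.0,
    alpha_level: float = 0.05,
    rpkm_scale: float = 10.0,
) -> pd.DataFrame:
    """Flag features up-regulated in at least one time point vs baseline.

    Each later time point is contrasted against the first (T0) with the NB
    test; BH adjustment is applied within each contrast.  A feature is
    responsive iff any contrast shows fold > fold_threshold and adjusted
    p < alpha_level; the first such time point is reported.  RPKM input is
    converted to pseudo-counts by scaling and rounding before testing.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per time point")
    baseline = timepoints[0]

    def counts_for(tp: str) -> np.ndarray:
        cols = [f"{tp}_{r}" for r in range(1, n_replicates + 1)]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"missing replicate columns {missing}")
        return np.rint(table[cols].to_numpy(dtype=float) * rpkm_scale)

    base = counts_for(baseline)
    unit = np.ones(n_replicates)
    fold_by_tp = {}
    padj_by_tp = {}
    for tp in timepoints[1:]:
        cur = counts_for(tp)
        res = nb_differential(
            base, cur, unit, unit, fold_threshold=fold_threshold,
            alpha_level=alpha_level, index=table.index,
        )
        fold_by_tp[tp] = res["fold_change"]
        padj_by_tp[tp] = res["p_adj"]

    responsive = pd.Series(False, index=table.index)
    first_tp = pd.Series(None, index=table.index, dtype=object)
    best_fold = pd.Series(0.0, index=table.index)
    best_padj = pd.Series(1.0, index=table.index)
    for tp in timepoints[1:]:
        passes = (fold_by_tp[tp] > fold_threshold) & (padj_by_tp[tp] < alpha_level)
        newly = passes & ~responsive
        first_tp[newly] = tp
        responsive |= passes
        better = fold_by_tp[tp] > best_fold
        best_fold[better] = fold_by_tp[tp][better]
        best_padj[better] = padj_by_tp[tp][better]
    return pd.DataFrame(
        dict(
            fold=best_fold,
            p_adj=best_padj,
            responsive=responsive,
            first_responsive_timepoint=first_tp,
        )
    )
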