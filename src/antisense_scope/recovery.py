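"""Planted-truth recovery scoring on synthetic data.

These functions run the full analysis on generated data and score the
result against the generator's truth labels: antisense-call sensitivity
and specificity, XUT recall/precision with a boundary tolerance, the sign
of the sense/antisense anti-correlation, and the recovered time-course
pair correlation.  The analysis only ever sees the unlabeled data; labels
enter at scoring time.
"""

from __future__ import annotations

import numpy as np

from . import segmentation, stats
from .antisense_caller import AnalysisParameters, call_genes
from .synthetic_data import (
    Annotation,
    SimulationConfig,
    generate_annotation,
    simulate_decay_tracks,
    simulate_netseq,
    simulate_netseq_input,
    simulate_timecourse,
)

BOUNDARY_TOLERANCE = 50  # nt per end when matching called to planted XUTs


def score_antisense_calls(
    annotation: Annotation, calls
) -> dict[str, float]:
    """Sensitivity/specificity of the antisense call against planted flags."""
    truth = annotation.gene_truth["antisense"]
    called = calls["antisense_transcribed"].reindex(truth.index)
    tp = int((called & truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    fp = int((called & ~truth).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_positive": tp + fn,
        "n_negative": tn + fp,
    }


def match_xuts(
    annotation: Annotation,
    xuts: list[segmentation.XutAnnotation],
    tolerance: int = BOUNDARY_TOLERANCE,
) -> dict[str, float]:
    """Recall/precision of retained XUTs vs planted templates.

    A call matches a planted XUT when chromosome and strand agree and both
    boundaries are within ``tolerance`` nt.
    """
    truth = annotation.xut_truth
    matched_truth = set()
    matched_calls = 0
    for x in xuts:
        seg = x.segment
        hit = None
        for xid, row in truth.iterrows():
            if (
                row["chrom"] == seg.chrom
                and row["strand"] == seg.strand
                and abs(int(row["start"]) - seg.start) <= tolerance
                and abs(int(row["end"]) - seg.end) <= tolerance
            ):
                hit = xid
                break
        if hit is not None:
            matched_calls += 1
            matched_truth.add(hit)
    n_truth = len(truth)
    n_calls = len(xuts)
    return {
        "recall": len(matched_truth) / n_truth if n_truth else float("nan"),
        "precision": matched_calls / n_calls if n_calls else float("nan"),
        "n_planted": n_truth,
        "n_called": n_calls,
    }


def planted_recovery(config: SimulationConfig | None = None) -> dict:
    """Run the whole analysis on one synthetic dataset and score it.

    Returns a flat dict of recovery metrics used by the acceptance checks:
    antisense sensitivity/specificity, XUT recall/precision (boundary
    tolerance 50 nt/end), the Spearman correlation between realized sense
    RPKM and antisense coverage over antisense-called genes, and the
    median per-pair time-course Pearson r of responsive pairs.
    """
    config = config or SimulationConfig(seed=0)
    params = AnalysisParameters()
    ann = generate_annotation(config)

    # --- antisense calling on NET-seq ------------------------------------
    netseq = simulate_netseq(ann, config)
    control = simulate_netseq_input(ann, config)
    calls, thresholds = call_genes(ann.genes, netseq, control, params)
    call_scores = score_antisense_calls(ann, calls)

    as_idx = calls.index[calls["antisense_transcribed"]]
    if len(as_idx) >= 3:
        rho = stats.spearman(
            calls.loc[as_idx, "sense_rpkm"], calls.loc[as_idx, "antisense_coverage"]
        )
    else:
        rho = float("nan")

    # --- XUT segmentation on decay-mutant RNA-seq ------------------------
    decay = simulate_decay_tracks(ann, config)
    seg = segmentation.segment_xuts(
        decay["exo2"], decay["wt"], mrnas=ann.mrnas, orfs=ann.orfs,
        snornas=ann.of_kind("snoRNA"), prior_lncrnas=ann.of_kind("lncRNA"),
        params=params,
    )
    xut_scores = match_xuts(ann, seg.xuts)

    # --- time-course pair correlation ------------------------------------
    table, pairs = simulate_timecourse(ann, config)
    _corr, medians = stats.pair_timecourse_correlation(
        table, pairs, list(config.timecourse_points)
    )

    return {
        "antisense_sensitivity": call_scores["sensitivity"],
        "antisense_specificity": call_scores["specificity"],
        "n_genes": len(ann.genes),
        "rpkm_threshold": thresholds[0],
        "coverage_threshold": thresholds[1],
        "sense_antisense_spearman": rho,
        "n_antisense_called": int(len(as_idx)),
        "xut_recall": xut_scores["recall"],
        "xut_precision": xut_scores["precision"],
        "n_planted_xuts": xut_scores["n_planted"],
        "n_called_xuts": xut_scores["n_called"],
        "selected_window": seg.window_w,
        "selected_theta": seg.threshold_theta,
        "timecourse_median_pearson_responsive": medians.get("responsive", float("nan")),
        "timecourse_median_pearson_insensitive": medians.get("insensitive", float("nan")),
        "n_responsive_pairs": int(pairs["responsive"].sum()) if len(pairs) else 0,
    }
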