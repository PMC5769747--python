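"""End-to-end orchestration: simulate -> quantify -> call -> metagene ->
segment -> stats, with deterministic seeding and a machine-readable report.

The run report carries per-stage record counts and derived percentages;
percentages are always recomputed from the counts with half-up rounding at
the stated precision, never stored independently, and the partition
identities (antisense + solo = total XUTs; convergent + nonconvergent =
antisense-called genes) are asserted on every run.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, metagene, segmentation, stats
from .antisense_caller import AnalysisParameters, call_genes
from .synthetic_data import (
    SimulationConfig,
    generate_annotation,
    simulate_decay_rnaseq,
    simulate_decay_tracks,
    simulate_netseq,
    simulate_netseq_input,
    simulate_smallrna,
    simulate_timecourse,
)

REPORT_SCHEMA_VERSION = 1


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero at the given number of decimals,
    matching the usual printed-percentage convention."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up; 0/anything is 0."""
    if numerator == 0:
        return 0.0
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def summarize_percentages(counts: dict[str, float]) -> dict[str, float]:
    """Derived ratio table from a report's raw counts.

    XUT-class ratios are printed at 1 decimal, the condition-sensitive
    (Spt6-style) antisense share as an integer percentage.
    """
    out: dict[str, float] = {}
    total_xut = counts.get("xuts_total", 0)
    if total_xut:
        out["pct_xut_antisense"] = percentage(counts.get("xuts_antisense", 0), total_xut)
        out["pct_xut_solo"] = percentage(counts.get("xuts_solo", 0), total_xut)
        out["pct_xut_novel"] = percentage(counts.get("xuts_novel", 0), total_xut)
    n_genes = counts.get("genes_total", 0)
    if n_genes:
        out["pct_genes_antisense"] = percentage(
            counts.get("genes_antisense", 0), n_genes
        )
    sens_total = counts.get("condition_sensitive_total", 0)
    if sens_total:
        out["pct_condition_sensitive_antisense"] = percentage(
            counts.get("condition_sensitive_antisense", 0), sens_total, decimals=0
        )
    return out


def verify_count_identities(counts: dict[str, float]) -> None:
    """Partition identities that must hold on every report."""
    if "xuts_total" in counts:
        assert counts["xuts_antisense"] + counts["xuts_solo"] == counts["xuts_total"], (
            "antisense + solo XUTs must equal the XUT total"
        )
    if "genes_antisense" in counts:
        assert (
            counts["genes_convergent"] + counts["genes_nonconvergent_antisense"]
            == counts["genes_antisense"]
        ), "convergent + nonconvergent must equal antisense-called genes"


def _log(msg: str) -> None:
    sys.stderr.write(f"[antisense-scope {time.strftime('%H:%M:%S')}] {msg}\n")


DEFAULT_PIPELINE_CONFIG = {
    "simulation": {},
    "parameters": {},
    "grid": {"windows": None, "thetas": None},
    "write_tracks": True,
    "flank": 500,
}


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_PIPELINE_CONFIG, **raw}
    return cfg


def run_pipeline(config: dict | None = None, seed: int = 0, outdir=None) -> dict:
    """Execute all stages on synthetic data and return the run report.

    ``config`` follows :data:`DEFAULT_PIPELINE_CONFIG`; ``seed`` overrides
    the simulation seed so one global seed fans out to every stage.  When
    ``outdir`` is given, all stage outputs (GFF3, bedGraph, TSV, report
    JSON) are written there; reruns with the same config and seed are
    byte-identical.
    """
    cfg = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    sim = SimulationConfig(**{**cfg["simulation"], "seed": seed})
    params = AnalysisParameters(**cfg["parameters"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        if outdir is not None:
            writer(outdir / name)
            outputs[name] = name  # relative to the run directory

    _log("stage simulate")
    ann = generate_annotation(sim)
    netseq = simulate_netseq(ann, sim)
    control = simulate_netseq_input(ann, sim)
    decay_tracks = simulate_decay_tracks(ann, sim)
    decay_counts = simulate_decay_rnaseq(ann, sim)
    tc_table, tc_pairs = simulate_timecourse(ann, sim)
    smallrna = simulate_smallrna(ann, sim)

    emit("annotation.gff3", lambda p: io_formats.write_gff3(
        ann.features, p, ann.chrom_lengths))
    emit("chrom_lengths.yaml", lambda p: io_formats.write_chrom_lengths(
        ann.chrom_lengths, p))
    emit("decay_counts.tsv", lambda p: io_formats.write_count_matrix(decay_counts, p))
    emit("timecourse_rpkm.tsv", lambda p: tc_table.to_csv(p, sep="\t"))
    emit("smallrna_reads.tsv", lambda p: smallrna.to_csv(p, sep="\t", index=False))
    if cfg["write_tracks"]:
        for t in netseq:
            emit_name = f"netseq_rep{t.replicate}"
            if outdir is not None:
                io_formats.write_stranded_bedgraph(
                    t, outdir / f"{emit_name}.plus.bedgraph",
                    outdir / f"{emit_name}.minus.bedgraph")
                outputs[emit_name] = f"{emit_name}.plus.bedgraph"

    _log("stage quantify + call")
    genes = ann.genes
    if genes:
        calls, thresholds = call_genes(genes, netseq, control, params)
    else:
        calls = pd.DataFrame(
            columns=["transcribed", "antisense_transcribed", "convergence_class",
                     "coverage_bin", "tss_overlapped", "sense_rpkm", "sense_coverage",
                     "antisense_rpkm", "antisense_coverage"]
        )
        thresholds = (params.rpkm_threshold, params.coverage_threshold)
    emit("antisense_calls.tsv", lambda p: calls.to_csv(p, sep="\t"))

    _log("stage metagene")
    with_as = [g for g in genes if calls.loc[g.id, "antisense_transcribed"]]
    without_as = [g for g in genes if not calls.loc[g.id, "antisense_transcribed"]]
    flank = cfg["flank"]
    for label, group in (("with_antisense", with_as), ("without_antisense", without_as)):
        if not group:
            continue
        prof = metagene.metagene_profile(netseq, group, which="sense", flank=flank)
        if outdir is not None:
            df = pd.DataFrame(
                dict(position=np.arange(len(prof.mean)), mean=prof.mean,
                     ci_low=prof.ci_low, ci_high=prof.ci_high)
            )
            df["class"] = label
            df.to_csv(outdir / f"metagene_{label}.tsv", sep="\t", index=False)
            outputs[f"metagene_{label}.tsv"] = f"metagene_{label}.tsv"

    _log("stage segment")
    grid_cfg = cfg.get("grid") or {}
    windows = tuple(grid_cfg.get("windows") or segmentation.DEFAULT_WINDOWS)
    thetas = tuple(grid_cfg.get("thetas") or segmentation.DEFAULT_THETAS)
    seg = segmentation.segment_xuts(
        decay_tracks["exo2"], decay_tracks["wt"],
        mrnas=ann.mrnas, orfs=ann.orfs, snornas=ann.of_kind("snoRNA"),
        prior_lncrnas=ann.of_kind("lncRNA"), params=params,
        windows=windows, thetas=thetas,
    )
    xut_features = [
        io_formats.Feature(
            id=f"XUTcalled{i + 1:04d}", kind="XUT", chrom=x.segment.chrom,
            start=x.segment.start, end=x.segment.end, strand=x.segment.strand,
            attributes={"fold_change": f"{x.fold_change:.3f}",
                        "p_adj": f"{x.p_adj:.3g}", "klass": x.klass,
                        "novel": str(x.novel)},
        )
        for i, x in enumerate(seg.xuts)
    ]
    emit("xuts.bed", lambda p: io_formats.write_bed(xut_features, p))
    emit("xuts.gff3", lambda p: io_formats.write_gff3(xut_features, p, ann.chrom_lengths))

    _log("stage stats")
    as_genes = calls.index[calls["antisense_transcribed"]] if len(calls) else []
    if len(as_genes) >= 3:
        sense_rpkm = calls.loc[as_genes, "sense_rpkm"]
        anti_cov = calls.loc[as_genes, "antisense_coverage"]
        rho = stats.spearman(sense_rpkm, anti_cov)
    else:
        rho = float("nan")
    timepoints = list(sim.timecourse_points)
    if len(tc_table):
        resp = stats.response_classifier(
            tc_table, timepoints, n_replicates=sim.timecourse_replicates,
            fold_threshold=params.fold_threshold, alpha_level=params.alpha,
        )
        xut_rows = resp.loc[[i for i in resp.index if i in set(tc_pairs["xut_id"])]]
        labels = {x: bool(xut_rows.loc[x, "responsive"]) for x in xut_rows.index}
        corr, medians = stats.pair_timecourse_correlation(
            tc_table, tc_pairs, timepoints, response_labels=labels
        )
        n_responsive = int(xut_rows["responsive"].sum())
    else:
        medians = {}
        n_responsive = 0

    counts = {
        "genes_total": len(genes),
        "genes_transcribed": int(calls["transcribed"].sum()) if len(calls) else 0,
        "genes_antisense": int(calls["antisense_transcribed"].sum()) if len(calls) else 0,
        "genes_convergent": int((calls["convergence_class"] == "convergent_overlap").sum())
        if len(calls) else 0,
        "genes_nonconvergent_antisense": int(
            (calls["convergence_class"] == "nonconvergent_antisense").sum()
        ) if len(calls) else 0,
        "genes_tss_overlapped": int(calls["tss_overlapped"].sum()) if len(calls) else 0,
        "segments_candidate": len(seg.candidates),
        "xuts_total": len(seg.xuts),
        "xuts_antisense": sum(1 for x in seg.xuts if x.klass == "antisense"),
        "xuts_solo": sum(1 for x in seg.xuts if x.klass == "solo"),
        "xuts_novel": sum(1 for x in seg.xuts if x.novel),
        "responsive_xuts": n_responsive,
    }
    verify_count_identities(counts)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "config": {
            "simulation": {k: v for k, v in dataclasses.asdict(sim).items()},
            "parameters": dataclasses.asdict(params),
            "grid": {"windows": list(windows), "thetas": [float(t) for t in thetas]},
        },
        "thresholds": {"rpkm": thresholds[0], "coverage": thresholds[1]},
        "selected_segmentation": {
            "window": seg.window_w, "theta": seg.threshold_theta,
        },
        "counts": counts,
        "percentages": summarize_percentages(counts),
        "sense_antisense_spearman": None if np.isnan(rho) else rho,
        "timecourse_median_pearson": medians,
        "outputs": outputs,
    }
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
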