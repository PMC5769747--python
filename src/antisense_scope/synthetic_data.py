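"""Synthetic annotations, stranded tracks and count tables with planted truth.

This module generates toy genomes carrying the statistical structure the
downstream analysis assumes: strand-specific nascent-transcription (NET-seq)
tag tracks with read-through beyond the mRNA 3' end, RNA-seq coverage for a
wild-type / decay-mutant (exo2-like) contrast harbouring planted unstable
transcripts (XUTs), sn(o)RNA normalization anchors, a five-point meiosis-like
time course with coupled sense/antisense pairs, ChIP-style histone-mark
tracks and a small-RNA read table.  Every dataset is emitted alongside truth
labels so recovery can be scored without circularity: downstream code only
ever sees the unlabeled data, the labels are used for scoring.

Sense-antisense coupling is generative, not correlational: the sense
transcription rate of a gene is multiplied by ``exp(-coupling_beta * a)``
where ``a`` is the planted antisense coverage fraction, so the recovered
anti-correlation is a planted ground truth.

Determinism: each ``simulate_*`` stage derives its own
:class:`numpy.random.Generator` from ``(config.seed, stage id)`` via
:class:`numpy.random.SeedSequence`, so identical configs give byte-identical
outputs and stages are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Feature, StrandedTrack, opposite

__all__ = [
    "SimulationConfig",
    "Annotation",
    "generate_annotation",
    "simulate_netseq",
    "simulate_netseq_input",
    "simulate_decay_rnaseq",
    "simulate_decay_tracks",
    "simulate_timecourse",
    "simulate_chip",
    "simulate_smallrna",
]

_STAGE = {
    "annotation": 0,
    "netseq": 1,
    "netseq_input": 2,
    "decay_counts": 3,
    "decay_tracks": 4,
    "timecourse": 5,
    "chip": 6,
    "smallrna": 7,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Scale defaults (2 chromosomes x 500 kb, 500 genes, 200 XUTs) keep an
    end-to-end run within minutes on one CPU while leaving every planted
    class populous enough for recovery scoring.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 500
    convergent_fraction: float = 0.4
    antisense_fraction: float = 0.6
    coupling_beta: float = 2.0
    n_xuts: int = 200
    xut_antisense_fraction: float = 0.75
    xut_fold_law: tuple[float, float] = (2.5, 0.6)  # mean/sd of log2 fold, clipped >= 1.2
    nb_dispersion: float = 0.05
    readthrough_tail: float = 150.0  # mean nt of geometric-like 3' read-through
    readthrough_cap: int = 300
    n_snorna: int = 30
    n_repeats: int = 6
    n_untranscribed: int = 60
    n_unmappable: int = 8
    prior_lncrna_fraction: float = 0.5
    timecourse_points: tuple[str, ...] = ("T0", "T2", "T4", "T6", "T8")
    timecourse_replicates: int = 2
    n_timecourse_pairs: int = 600
    responsive_fraction: float = 0.5
    responsive_pair_rho: float = -0.5
    timecourse_rep_noise: float = 0.05
    # signal scales (rates are tags or coverage per nucleotide)
    sense_rate_median: float = 3.0
    sense_rate_sigma: float = 0.8
    antisense_rate_median: float = 2.0
    antisense_rate_sigma: float = 0.4
    netseq_background: float = 0.002
    input_background: float = 0.05
    rnaseq_mrna_rate_median: float = 15.0
    rnaseq_mrna_rate_sigma: float = 0.8
    rnaseq_xut_wt_rate_median: float = 1.2
    rnaseq_xut_wt_rate_sigma: float = 0.25
    rnaseq_snorna_rate: float = 20.0
    rnaseq_background: float = 0.01
    mutant_mrna_factor: float = 1.2
    chip_h3_rate: float = 20.0
    chip_promoter_ratio: float = 0.5
    chip_body_ratio: float = 1.3
    chip_promoter_width: int = 300

    def __post_init__(self) -> None:
        for name in (
            "convergent_fraction",
            "antisense_fraction",
            "xut_antisense_fraction",
            "prior_lncrna_fraction",
            "responsive_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.responsive_pair_rho <= 0.0:
            raise ValueError("responsive_pair_rho must be in [-1, 0]")
        if self.coupling_beta < 0:
            raise ValueError("coupling_beta must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.xut_fold_law[0] < 1.0:
            raise ValueError("mean planted log2 fold must be >= 1")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGE[stage],))
    )


@dataclass
class Annotation:
    """Generated features plus the truth labels of every planted signal."""

    features: list[Feature]
    gene_truth: pd.DataFrame  # indexed by gene id
    xut_truth: pd.DataFrame  # indexed by xut id
    chrom_lengths: dict[str, int]

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def genes(self) -> list[Feature]:
        return self.of_kind("gene")

    @property
    def mrnas(self) -> list[Feature]:
        return self.of_kind("mRNA")

    @property
    def orfs(self) -> list[Feature]:
        return self.of_kind("ORF")


def _empty_gene_truth() -> pd.DataFrame:
    cols = [
        "chrom", "strand", "start", "end", "length", "lambda_base", "lambda_sense",
        "antisense", "convergent_partner", "a", "as_start", "as_end",
        "lambda_antisense", "untranscribed", "unmappable", "xut_id",
    ]
    return pd.DataFrame(columns=cols)


def _empty_xut_truth() -> pd.DataFrame:
    cols = ["chrom", "strand", "start", "end", "host_gene", "klass", "log2_fold", "novel"]
    return pd.DataFrame(columns=cols)


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Lay out genes, convergent pairs, snoRNAs, repeats and XUT templates.

    Genes never overlap in coordinates (so antisense XUTs never touch a
    same-strand ORF); a ``convergent_fraction`` of genes is paired
    tail-to-tail with a 3'-3' gap drawn from [50, 800] nt.  Returns the
    feature list together with per-gene and per-XUT truth tables.
    """
    rng = _rng(config, "annotation")
    n_conv = 2 * int(round(config.n_genes * config.convergent_fraction / 2.0))
    n_pairs = n_conv // 2
    n_single = config.n_genes - n_conv
    n_as_target = int(round(config.n_genes * config.antisense_fraction))
    if n_as_target < n_conv:
        raise ValueError(
            "antisense_fraction * n_genes must cover all convergent-pair genes"
        )
    n_as_xut = int(round(config.n_xuts * config.xut_antisense_fraction))
    n_solo_xut = config.n_xuts - n_as_xut
    if config.n_genes > 0 and n_as_xut > n_as_target:
        raise ValueError("more antisense XUTs requested than antisense genes")

    units = (
        [("pair",)] * n_pairs
        + [("single",)] * n_single
        + [("solo_xut",)] * n_solo_xut
        + [("snorna",)] * config.n_snorna
        + [("repeat",)] * config.n_repeats
    )
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    chroms = sorted(config.chrom_lengths)
    chrom_idx, cursor = 0, 1000
    gene_rows: list[dict] = []
    solo_slots: list[tuple[str, int, int, str]] = []
    features: list[Feature] = []
    n_sno = 0
    n_rep = 0

    def advance(length: int) -> tuple[str, int]:
        nonlocal chrom_idx, cursor
        margin = int(rng.integers(400, 1001))
        while True:
            if chrom_idx >= len(chroms):
                raise ValueError(
                    "infeasible packing: genome too short for requested features; "
                    "increase chrom_length or n_chroms"
                )
            start = cursor + margin
            if start + length + 1000 <= config.chrom_lengths[chroms[chrom_idx]]:
                cursor = start + length
                return chroms[chrom_idx], start
            chrom_idx += 1
            cursor = 1000

    for unit in units:
        kind = unit[0]
        if kind == "pair":
            la = int(rng.integers(700, 1501))
            lb = int(rng.integers(700, 1501))
            gap = int(rng.integers(50, 801))
            chrom, start = advance(la + gap + lb)
            gid_a = f"gene{len(gene_rows) + 1:04d}"
            gene_rows.append(
                dict(gene_id=gid_a, chrom=chrom, strand="+", start=start, end=start + la,
                     pair_role="left")
            )
            gid_b = f"gene{len(gene_rows) + 1:04d}"
            gene_rows.append(
                dict(gene_id=gid_b, chrom=chrom, strand="-", start=start + la + gap,
                     end=start + la + gap + lb, pair_role="right")
            )
            gene_rows[-2]["convergent_partner"] = gid_b
            gene_rows[-1]["convergent_partner"] = gid_a
        elif kind == "single":
            length = int(rng.integers(700, 1501))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = advance(length)
            gid = f"gene{len(gene_rows) + 1:04d}"
            gene_rows.append(
                dict(gene_id=gid, chrom=chrom, strand=strand, start=start,
                     end=start + length, pair_role=None, convergent_partner=None)
            )
        elif kind == "solo_xut":
            length = int(rng.integers(300, 901))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = advance(length)
            solo_slots.append((chrom, start, start + length, strand))
        elif kind == "snorna":
            length = int(rng.integers(80, 201))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = advance(length)
            n_sno += 1
            features.append(
                Feature(id=f"sno{n_sno:03d}", kind="snoRNA", chrom=chrom,
                        start=start, end=start + length, strand=strand)
            )
        else:  # repeat
            length = int(rng.integers(1500, 2501))
            chrom, start = advance(length)
            n_rep += 1
            features.append(
                Feature(id=f"rep{n_rep:02d}", kind="repeat", chrom=chrom,
                        start=start, end=start + length, strand="+")
            )

    truth = pd.DataFrame(gene_rows).set_index("gene_id") if gene_rows else _empty_gene_truth()
    if gene_rows:
        truth["length"] = truth["end"] - truth["start"]
        # --- flags -------------------------------------------------------
        pair_ids = truth.index[truth["pair_role"].notna()]
        singles = truth.index[truth["pair_role"].isna()].to_numpy()
        extra_as = rng.choice(singles, size=n_as_target - len(pair_ids), replace=False)
        truth["antisense"] = False
        truth.loc[pair_ids, "antisense"] = True
        truth.loc[extra_as, "antisense"] = True
        non_as = truth.index[~truth["antisense"]].to_numpy()
        if len(non_as) < config.n_untranscribed:
            raise ValueError("not enough non-antisense genes for the untranscribed set")
        untr = rng.choice(non_as, size=config.n_untranscribed, replace=False)
        truth["untranscribed"] = False
        truth.loc[untr, "untranscribed"] = True
        unmap = rng.choice(untr, size=min(config.n_unmappable, len(untr)), replace=False)
        truth["unmappable"] = False
        truth.loc[unmap, "unmappable"] = True
        # --- expression rates -------------------------------------------
        lam = rng.lognormal(math.log(config.sense_rate_median), config.sense_rate_sigma,
                            size=len(truth))
        lam[truth["untranscribed"].to_numpy()] = 0.0
        truth["lambda_base"] = lam
        # --- planted antisense regions -----------------------------------
        truth["a"] = 0.0
        truth["as_start"] = -1
        truth["as_end"] = -1
        truth["lambda_antisense"] = 0.0
        for gid in truth.index[truth["antisense"]]:
            row = truth.loc[gid]
            length = int(row["length"])
            if row["pair_role"] is not None:
                a = float(rng.uniform(0.2, 0.5))
            else:
                a = float(rng.uniform(0.3, 0.95))
            reg_len = min(length, max(260, int(round(a * length))))
            if row["pair_role"] == "left":  # plus-strand gene, 3'-anchored region
                as_start = int(row["end"]) - reg_len
            elif row["pair_role"] == "right":  # minus-strand gene, 3' at start
                as_start = int(row["start"])
            else:
                as_start = int(row["start"]) + int(rng.integers(0, length - reg_len + 1))
            truth.loc[gid, ["a", "as_start", "as_end"]] = (
                reg_len / length, as_start, as_start + reg_len,
            )
            truth.loc[gid, "lambda_antisense"] = rng.lognormal(
                math.log(config.antisense_rate_median), config.antisense_rate_sigma
            )
        truth["lambda_sense"] = truth["lambda_base"] * np.exp(
            -config.coupling_beta * truth["a"]
        )
    else:
        truth = _empty_gene_truth()

    # --- XUT templates ----------------------------------------------------
    xut_rows: list[dict] = []
    if gene_rows and n_as_xut:
        as_hosts = rng.choice(
            truth.index[truth["antisense"]].to_numpy(), size=n_as_xut, replace=False
        )
    else:
        as_hosts = np.array([], dtype=object)
    truth["xut_id"] = None
    for host in as_hosts:
        row = truth.loc[host]
        xid = f"XUT{len(xut_rows) + 1:04d}"
        xut_rows.append(
            dict(xut_id=xid, chrom=row["chrom"], strand=opposite(row["strand"]),
                 start=int(row["as_start"]), end=int(row["as_end"]),
                 host_gene=host, klass="antisense")
        )
        truth.loc[host, "xut_id"] = xid
    for chrom, start, end, strand in solo_slots:
        xid = f"XUT{len(xut_rows) + 1:04d}"
        xut_rows.append(
            dict(xut_id=xid, chrom=chrom, strand=strand, start=start, end=end,
                 host_gene=None, klass="solo")
        )
    xut_truth = (
        pd.DataFrame(xut_rows).set_index("xut_id") if xut_rows else _empty_xut_truth()
    )
    if xut_rows:
        mean_l2, sd_l2 = config.xut_fold_law
        folds = rng.normal(mean_l2, sd_l2, size=len(xut_truth))
        xut_truth["log2_fold"] = np.clip(folds, 1.2, None)
        xut_truth["novel"] = rng.random(len(xut_truth)) >= config.prior_lncrna_fraction
    # prior lncRNA annotation for the non-novel XUTs
    n_prior = 0
    for xid, row in xut_truth.iterrows():
        if row.get("novel", True):
            continue
        n_prior += 1
        jitter = rng.integers(-30, 31, size=2)
        s = max(0, int(row["start"]) + int(jitter[0]))
        e = min(config.chrom_lengths[row["chrom"]], int(row["end"]) + int(jitter[1]))
        if e - s < 50:
            s, e = int(row["start"]), int(row["end"])
        features.append(
            Feature(id=f"prior_lnc{n_prior:03d}", kind="lncRNA", chrom=row["chrom"],
                    start=s, end=e, strand=row["strand"],
                    attributes={"matches_xut": xid})
        )

    # --- gene/mRNA/ORF features ------------------------------------------
    for gid, row in truth.iterrows():
        start, end, strand = int(row["start"]), int(row["end"]), row["strand"]
        length = end - start
        utr5 = int(rng.integers(50, 151))
        utr3 = int(rng.integers(80, 251))
        if length - utr5 - utr3 < 150:
            utr5, utr3 = 50, 80
        if strand == "+":
            orf = (start + utr5, end - utr3)
        else:
            orf = (start + utr3, end - utr5)
        attrs = {
            "antisense": str(bool(row["antisense"])),
            "untranscribed": str(bool(row["untranscribed"])),
            "unmappable": str(bool(row["unmappable"])),
        }
        if row["convergent_partner"]:
            attrs["convergent_partner"] = row["convergent_partner"]
        if row["xut_id"]:
            attrs["xut_id"] = row["xut_id"]
        features.append(
            Feature(id=gid, kind="gene", chrom=row["chrom"], start=start, end=end,
                    strand=strand, attributes=attrs)
        )
        features.append(
            Feature(id=f"{gid}.1", kind="mRNA", chrom=row["chrom"], start=start,
                    end=end, strand=strand, parent=gid)
        )
        features.append(
            Feature(id=f"{gid}.1.orf", kind="ORF", chrom=row["chrom"], start=orf[0],
                    end=orf[1], strand=strand, parent=f"{gid}.1")
        )

    if gene_rows:
        truth = truth.drop(columns=["pair_role"])
    return Annotation(
        features=features,
        gene_truth=truth,
        xut_truth=xut_truth,
        chrom_lengths=dict(config.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# NET-seq
# ---------------------------------------------------------------------------

def _blank_values(chrom_lengths, rng, background) -> dict:
    return {
        c: {
            "+": rng.poisson(background, n).astype(float),
            "-": rng.poisson(background, n).astype(float),
        }
        for c, n in sorted(chrom_lengths.items())
    }


def simulate_netseq(
    annotation: Annotation, config: SimulationConfig, n_replicates: int = 2
) -> list[StrandedTrack]:
    """Simulate NET-seq IP tracks: per-nt Poisson 3'-end tags.

    Sense tags cover the gene body at the coupled rate ``lambda_sense`` and
    decay geometrically past the TTS (read-through); planted antisense
    regions receive tags on the opposite strand, 3'-peaked for convergent
    pairs and broadly placed otherwise.
    """
    rng = _rng(config, "netseq")
    truth = annotation.gene_truth
    tracks = []
    cap = config.readthrough_cap
    decay = np.exp(-np.arange(cap) / config.readthrough_tail)
    for rep in range(1, n_replicates + 1):
        values = _blank_values(annotation.chrom_lengths, rng, config.netseq_background)
        for gid, row in truth.iterrows():
            chrom, strand = row["chrom"], row["strand"]
            start, end = int(row["start"]), int(row["end"])
            lam = float(row["lambda_sense"])
            arr = values[chrom][strand]
            if lam > 0:
                arr[start:end] += rng.poisson(lam, end - start)
                rates = lam * decay
                if strand == "+":
                    avail = min(cap, len(arr) - end)
                    arr[end:end + avail] += rng.poisson(rates[:avail])
                else:
                    avail = min(cap, start)
                    arr[start - avail:start] += rng.poisson(rates[:avail][::-1])
            if row["antisense"]:
                opp = values[chrom][opposite(strand)]
                s, e = int(row["as_start"]), int(row["as_end"])
                opp[s:e] += rng.poisson(float(row["lambda_antisense"]), e - s)
        for gid, row in truth[truth["unmappable"]].iterrows():
            for strand in ("+", "-"):
                values[row["chrom"]][strand][int(row["start"]):int(row["end"])] = 0.0
        total = float(sum(v[s].sum() for v in values.values() for s in v))
        tracks.append(
            StrandedTrack(sample_id=f"netseq_rep{rep}", replicate=rep,
                          assay="netseq_ip", values=values, total_tags=total)
        )
    return tracks


def simulate_netseq_input(annotation: Annotation, config: SimulationConfig) -> StrandedTrack:
    """Total-RNA control track used as the mappability reference.

    Uniform low background everywhere except genes flagged unmappable,
    which get no signal at all (emulating repeat-rich loci where reads
    cannot be uniquely assigned).
    """
    rng = _rng(config, "netseq_input")
    values = _blank_values(annotation.chrom_lengths, rng, config.input_background)
    for gid, row in annotation.gene_truth.iterrows():
        lam = 0.2 * float(row["lambda_sense"])
        if lam > 0:
            arr = values[row["chrom"]][row["strand"]]
            s, e = int(row["start"]), int(row["end"])
            arr[s:e] += rng.poisson(lam, e - s)
    for gid, row in annotation.gene_truth[annotation.gene_truth["unmappable"]].iterrows():
        for strand in ("+", "-"):
            values[row["chrom"]][strand][int(row["start"]):int(row["end"])] = 0.0
    total = float(sum(v[s].sum() for v in values.values() for s in v))
    return StrandedTrack(sample_id="netseq_input", replicate=1, assay="netseq_input",
                         values=values, total_tags=total)


# ---------------------------------------------------------------------------
# Decay-mutant RNA-seq
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2.

    In the dispersion -> 0 limit this degenerates to Poisson draws.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_decay_rnaseq(annotation: Annotation, config: SimulationConfig) -> pd.DataFrame:
    """Per-feature count matrix for WT x2 vs decay mutant x2.

    Planted XUTs have low WT means and mutant means multiplied by
    ``2**log2_fold`` (all planted folds >= 2 in linear scale at defaults);
    snoRNAs are condition-invariant normalization anchors; mRNAs are mildly
    elevated in the mutant.
    """
    rng = _rng(config, "decay_counts")
    ids, wt_mean, mut_mean = [], [], []
    for f in annotation.mrnas:
        ids.append(f.id)
        m = rng.lognormal(math.log(300.0), 1.0)
        wt_mean.append(m)
        mut_mean.append(m * config.mutant_mrna_factor)
    for f in annotation.of_kind("snoRNA"):
        ids.append(f.id)
        wt_mean.append(1000.0)
        mut_mean.append(1000.0)
    for xid, row in annotation.xut_truth.iterrows():
        ids.append(xid)
        w = rng.lognormal(math.log(50.0), 0.5)
        wt_mean.append(w)
        mut_mean.append(w * 2.0 ** float(row["log2_fold"]))
    wt_mean = np.asarray(wt_mean)
    mut_mean = np.asarray(mut_mean)
    cols = {}
    for rep in (1, 2):
        cols[f"WT_{rep}"] = _nb_draw(rng, wt_mean, config.nb_dispersion)
    for rep in (1, 2):
        cols[f"exo2_{rep}"] = _nb_draw(rng, mut_mean, config.nb_dispersion)
    return pd.DataFrame(cols, index=pd.Index(ids, name="feature_id")).astype(np.int64)


def simulate_decay_tracks(
    annotation: Annotation, config: SimulationConfig, n_replicates: int = 2
) -> dict[str, list[StrandedTrack]]:
    """Full-coverage RNA-seq tracks for WT and the decay mutant.

    Coverage rates per feature are drawn once and shared across replicates
    and conditions (the planted fold applies only to XUTs), so replicates
    differ by sampling noise alone.
    """
    rng = _rng(config, "decay_tracks")
    mrna_rate = {
        f.id: rng.lognormal(
            math.log(config.rnaseq_mrna_rate_median), config.rnaseq_mrna_rate_sigma
        )
        for f in annotation.mrnas
    }
    xut_wt_rate = {
        xid: rng.lognormal(
            math.log(config.rnaseq_xut_wt_rate_median), config.rnaseq_xut_wt_rate_sigma
        )
        for xid in annotation.xut_truth.index
    }
    out: dict[str, list[StrandedTrack]] = {"wt": [], "exo2": []}
    for condition in ("wt", "exo2"):
        for rep in range(1, n_replicates + 1):
            values = _blank_values(annotation.chrom_lengths, rng, config.rnaseq_background)
            for f in annotation.mrnas:
                lam = mrna_rate[f.id]
                if condition == "exo2":
                    lam *= config.mutant_mrna_factor
                values[f.chrom][f.strand][f.start:f.end] += rng.poisson(lam, f.length)
            for f in annotation.of_kind("snoRNA"):
                values[f.chrom][f.strand][f.start:f.end] += rng.poisson(
                    config.rnaseq_snorna_rate, f.length
                )
            for xid, row in annotation.xut_truth.iterrows():
                lam = xut_wt_rate[xid]
                if condition == "exo2":
                    lam *= 2.0 ** float(row["log2_fold"])
                s, e = int(row["start"]), int(row["end"])
                values[row["chrom"]][row["strand"]][s:e] += rng.poisson(lam, e - s)
            total = float(sum(v[s].sum() for v in values.values() for s in v))
            out[condition].append(
                StrandedTrack(sample_id=f"rnaseq_{condition}_rep{rep}", replicate=rep,
                              assay="rnaseq", values=values, total_tags=total)
            )
    return out


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------

_NOISE_SHAPE_X = 0.4  # noise sd per unit |slope| on the rising antisense series
_NOISE_SHAPE_Y = 2.0  # same for the declining mRNA series (flatter slope)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _calibrate_timecourse_noise(
    rho: float, n_t: int, n_reps: int, rep_noise: float, n_mc: int = 4000
) -> float:
    """Noise scale c such that the median sample Pearson r equals rho.

    The per-pair correlation over a handful of fixed time points is not
    the population correlation of an iid bivariate draw, so the scale is
    solved by Monte Carlo: simulate pairs under the same trend and clip
    conventions as the generator (with a fixed internal seed, so the
    result is deterministic) and bisect on c.  c = 0 gives r = -1 exactly.
    """
    if rho >= -1e-9:
        return 50.0
    if rho <= -0.999:
        return 0.0
    rng = np.random.default_rng(20180201)  # calibration stream, data-independent
    t = np.arange(n_t, dtype=float)
    x0 = rng.uniform(8.0, 16.0, n_mc)
    fold = rng.uniform(3.0, 6.0, n_mc)
    y0 = rng.uniform(10.0, 30.0, n_mc)
    sx = x0 * (fold - 1.0) / (n_t - 1)
    sy = -(y0 * 0.4) / (n_t - 1)
    eps_x = rng.standard_normal((n_mc, n_t))
    eps_y = rng.standard_normal((n_mc, n_t))
    rep_x = rng.standard_normal((n_mc, n_t)) * rep_noise / math.sqrt(max(n_reps, 1))
    rep_y = rng.standard_normal((n_mc, n_t)) * rep_noise / math.sqrt(max(n_reps, 1))

    def median_r(c: float) -> float:
        x = x0[:, None] + sx[:, None] * t + c * _NOISE_SHAPE_X * sx[:, None] * eps_x
        y = y0[:, None] + sy[:, None] * t + c * _NOISE_SHAPE_Y * np.abs(sy)[:, None] * eps_y
        x = np.clip(x, 0.05, None) * (1.0 + rep_x)
        y = np.clip(y, 0.05, None) * (1.0 + rep_y)
        return float(np.nanmedian(_rowwise_pearson(x, y)))

    lo, hi = 0.0, 50.0
    if median_r(hi) < rho:  # even huge noise keeps |r| above target
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if median_r(mid) > rho:  # too noisy, |r| too small
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_timecourse(
    annotation: Annotation, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM table over the time course for antisense-XUT / mRNA pairs.

    Responsive pairs get a monotone antisense increase with a coupled sense
    decrease; the additive noise on each series is calibrated so the
    per-pair Pearson correlation over time points centres on
    ``responsive_pair_rho`` (with a small-sample bias correction).
    Insensitive pairs are uncorrelated noise around flat means.

    Returns ``(table, pairs)`` where ``table`` has one row per feature and
    one column per ``{timepoint}_{replicate}`` and ``pairs`` lists
    (mrna_id, xut_id, responsive truth).
    """
    rng = _rng(config, "timecourse")
    points = list(config.timecourse_points)
    n_t = len(points)
    if n_t < 3:
        raise ValueError("need at least 3 time points")
    t = np.arange(n_t, dtype=float)

    as_xuts = annotation.xut_truth[annotation.xut_truth["klass"] == "antisense"]
    # The time course emulates a separately deposited dataset with hundreds
    # of asXUT/mRNA pairs; annotated antisense XUTs supply the first pairs
    # and standalone pairs pad up to the configured total.
    pair_ids = [(f"{row['host_gene']}.1", xid) for xid, row in as_xuts.iterrows()]
    for i in range(len(pair_ids), config.n_timecourse_pairs):
        pair_ids.append((f"tc_mrna{i + 1:04d}", f"tc_xut{i + 1:04d}"))
    pair_ids = pair_ids[: config.n_timecourse_pairs] if config.n_timecourse_pairs else pair_ids

    pair_rows = []
    n_resp = int(round(len(pair_ids) * config.responsive_fraction))
    resp_idx = set(rng.choice(len(pair_ids), size=n_resp, replace=False))

    c = _calibrate_timecourse_noise(
        config.responsive_pair_rho, n_t, config.timecourse_replicates,
        config.timecourse_rep_noise,
    )

    series: dict[str, np.ndarray] = {}
    for k, (mrna_id, xid) in enumerate(pair_ids):
        responsive = k in resp_idx
        pair_rows.append(dict(mrna_id=mrna_id, xut_id=xid, responsive=responsive))
        if responsive:
            x0 = rng.uniform(8.0, 16.0)
            fold = rng.uniform(3.0, 6.0)
            sx = x0 * (fold - 1.0) / (n_t - 1)
            y0 = rng.uniform(10.0, 30.0)
            sy = -(y0 * 0.4) / (n_t - 1)  # declines to ~0.6x by the last point
            sig_x = c * _NOISE_SHAPE_X * abs(sx)
            sig_y = c * _NOISE_SHAPE_Y * abs(sy)
            eps_x = rng.standard_normal(n_t)
            eps_y = rng.standard_normal(n_t)
            x = x0 + sx * t + sig_x * eps_x
            y = y0 + sy * t + sig_y * eps_y
        else:
            x0 = rng.uniform(2.0, 10.0)
            y0 = rng.uniform(10.0, 30.0)
            x = x0 * (1.0 + 0.2 * rng.standard_normal(n_t))
            y = y0 * (1.0 + 0.2 * rng.standard_normal(n_t))
        series[xid] = np.clip(x, 0.05, None)
        series[mrna_id] = np.clip(y, 0.05, None)

    ids = list(series)
    data = {}
    for j, point in enumerate(points):
        for rep in range(1, config.timecourse_replicates + 1):
            col = np.array([series[i][j] for i in ids])
            noise = 1.0 + config.timecourse_rep_noise * rng.standard_normal(len(col))
            data[f"{point}_{rep}"] = np.clip(col * noise, 0.0, None)
    table = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"))
    pairs = pd.DataFrame(pair_rows)
    return table, pairs


# ---------------------------------------------------------------------------
# ChIP and small RNA
# ---------------------------------------------------------------------------

def simulate_chip(
    annotation: Annotation, config: SimulationConfig, n_replicates: int = 2
) -> dict[str, list[StrandedTrack]]:
    """Histone H3 and one acetylation-mark track pair.

    Genes flagged antisense get a planted mark/H3 ratio of
    ``chip_promoter_ratio`` upstream of the TSS and ``chip_body_ratio``
    over the gene body; all other positions have ratio 1.
    """
    rng = _rng(config, "chip")
    ratio = {c: np.ones(n) for c, n in sorted(annotation.chrom_lengths.items())}
    for gid, row in annotation.gene_truth.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if not row["antisense"]:
            continue
        if row["strand"] == "+":
            p0, p1 = max(0, start - config.chip_promoter_width), start
        else:
            p0, p1 = end, min(len(ratio[row["chrom"]]), end + config.chip_promoter_width)
        ratio[row["chrom"]][p0:p1] = config.chip_promoter_ratio
        ratio[row["chrom"]][start:end] = config.chip_body_ratio
    half = config.chip_h3_rate / 2.0
    out: dict[str, list[StrandedTrack]] = {"h3": [], "mark": []}
    for name in ("h3", "mark"):
        for rep in range(1, n_replicates + 1):
            values = {}
            for chrom, r in ratio.items():
                rate = half * (r if name == "mark" else np.ones_like(r))
                values[chrom] = {
                    "+": rng.poisson(rate).astype(float),
                    "-": rng.poisson(rate).astype(float),
                }
            total = float(sum(v[s].sum() for v in values.values() for s in v))
            out[name].append(
                StrandedTrack(sample_id=f"chip_{name}_rep{rep}", replicate=rep,
                              assay="chip", values=values, total_tags=total)
            )
    return out


def simulate_smallrna(annotation: Annotation, config: SimulationConfig) -> pd.DataFrame:
    """Small-RNA read table (chrom, start, length, strand).

    Repeat-derived reads dominate with the 22-23 nt modal length typical of
    Dicer products from centromeric repeats; a sparse genome-wide background
    spans lengths 15-35 nt so the 18-30 nt filter is exercised.  No reads
    are planted inside XUT regions.
    """
    rng = _rng(config, "smallrna")
    lengths = np.arange(18, 31)
    probs = np.array([0.02, 0.02, 0.02, 0.03, 0.38, 0.38, 0.03, 0.03, 0.03,
                      0.02, 0.02, 0.01, 0.01])
    probs = probs / probs.sum()
    rows = []
    for f in annotation.of_kind("repeat"):
        n = int(rng.poisson(1.0 * f.length))
        starts = rng.integers(f.start, max(f.start + 1, f.end - 23), size=n)
        ls = rng.choice(lengths, size=n, p=probs)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        for s, l, st in zip(starts, ls, strands):
            rows.append((f.chrom, int(s), int(l), st))
    for chrom, clen in sorted(annotation.chrom_lengths.items()):
        n = int(rng.poisson(0.0005 * clen * 2))
        starts = rng.integers(0, clen - 40, size=n)
        ls = rng.integers(15, 36, size=n)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        for s, l, st in zip(starts, ls, strands):
            rows.append((chrom, int(s), int(l), st))
    return pd.DataFrame(rows, columns=["chrom", "start", "length", "strand"])
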