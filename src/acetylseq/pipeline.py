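"""End-to-end orchestration: config in, result bundle + summary out.

``run_pipeline`` executes whichever stages its inputs allow — peak
calling + replicate consensus (skipped when peaks are supplied),
annotation, metagene/TSS/chromosome profiles, methylation levels and
DMRs, DARs/uDAGs against a mutant genotype, and the integrative mark x
expression statistics — writing per-stage TSV/BED outputs and one
machine-readable ``summary.json``.  Identical config + inputs give a
byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import differential as diff
from . import feature_annotation as fa
from . import integration_stats as istats
from . import methylation as meth
from . import peak_calling as pc
from . import profiles as prof
from .formats_io import (GenomicInterval, expression_dict, read_bed,
                         read_bedgraph, read_cx_report, read_expression_table,
                         read_gene_models, write_bed)
from .genome_intervals import GenomeLayout, merge_intervals

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every input path and printed threshold in one place."""

    outdir: str
    chrom_sizes: str
    gene_models: str
    seed: int = 0
    # wild-type inputs
    peaks_bed: str | None = None
    ip_tracks: list[str] = field(default_factory=list)
    input_tracks: list[str] = field(default_factory=list)
    expression: str | None = None
    cx_report: str | None = None
    # mutant genotype (optional)
    mutant_name: str | None = None
    mutant_ip_tracks: list[str] = field(default_factory=list)
    mutant_input_tracks: list[str] = field(default_factory=list)
    mutant_cx_report: str | None = None
    # companion interval sets
    histone_beds: dict[str, str] = field(default_factory=dict)
    dhs_bed: str | None = None
    tf_beds: dict[str, str] = field(default_factory=dict)
    # thresholds
    promoter_bp: int = 1000
    tss_window: int = 250
    body_bins: int = 20
    flank: int = 1000
    flank_bin: int = 50
    chrom_bin: int = 100_000
    lfc_cut: float = 1.0
    fdr: float = 0.05
    fpkm_cut: float = 0.0
    min_overlap_bp: int = 1
    peak_params: pc.PeakCallParams = field(default_factory=pc.PeakCallParams)
    dmr_params: meth.DMRParams = field(default_factory=meth.DMRParams)

    def __post_init__(self) -> None:
        for name in ("promoter_bp", "tss_window", "body_bins", "flank",
                     "flank_bin", "chrom_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.peak_params, dict):
            self.peak_params = pc.PeakCallParams(**self.peak_params)
        if isinstance(self.dmr_params, dict):
            self.dmr_params = meth.DMRParams(**self.dmr_params)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _require(config: PipelineConfig, stage: str, **paths):
    missing = [f"{k}={v!r}" for k, v in paths.items() if not v]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r} requires inputs: {', '.join(missing)}")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the supplied inputs permit; return the summary."""
    layout = GenomeLayout.from_chrom_sizes(config.chrom_sizes)
    genes = read_gene_models(config.gene_models)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "seed": config.seed, "n_genes": len(genes)}

    # ---- stage 1: peaks -------------------------------------------------
    if config.peaks_bed:
        peaks = read_bed(config.peaks_bed)
        summary["peak_calling"] = {"source": "supplied", "n_peaks": len(peaks)}
    elif config.ip_tracks and config.input_tracks:
        reps = []
        for i, ip_path in enumerate(config.ip_tracks):
            in_path = config.input_tracks[min(i, len(config.input_tracks) - 1)]
            reps.append(pc.call_enriched_windows(
                read_bedgraph(ip_path), read_bedgraph(in_path),
                config.peak_params, layout))
        peaks = pc.consensus_peaks(reps[0], reps[1]) if len(reps) > 1 else reps[0]
        summary["peak_calling"] = {
            "source": "called",
            "n_peaks_per_replicate": [len(r) for r in reps],
            "n_peaks": len(peaks)}
    else:
        raise FileNotFoundError(
            "stage 'peaks' requires either peaks_bed or ip_tracks+input_tracks")
    write_bed(peaks, out / "peaks.bed")

    # ---- stage 2: annotation -------------------------------------------
    dist = fa.annotation_distribution(peaks, genes, layout, config.promoter_bp)
    dist.to_csv(out / "annotation_distribution.tsv", sep="\t", index=False)
    assign = fa.assign_peaks_to_genes(peaks, genes, layout, config.promoter_bp)
    marked_frac = assign.marked_fraction_by_biotype()
    summary["annotation"] = {
        "category_percent": dict(zip(dist["category"], dist["percent"])),
        "marked_fraction_by_biotype": {k: float(v) for k, v in marked_frac.items()},
        "body_peak_histogram": assign.body_peak_histogram(),
    }

    # ---- stage 3: profiles ---------------------------------------------
    tss_labels = prof.tss_marked_classification(
        peaks, genes, config.tss_window, config.promoter_bp, layout)
    chrom_prof = prof.chromosome_bin_profile(peaks, layout, config.chrom_bin)
    with open(out / "chromosome_profile.tsv", "w") as fh:
        fh.write("chrom\tbin\tpeak_fraction\n")
        for chrom, vals in chrom_prof.items():
            for i, v in enumerate(vals):
                fh.write(f"{chrom}\t{i}\t{v:.6f}\n")
    profile_summary: dict = {
        "n_tss_marked": sum(1 for v in tss_labels.values() if v == "tss_marked"),
        "n_nontss_marked": sum(1 for v in tss_labels.values() if v == "nontss_marked"),
        "n_unmarked": sum(1 for v in tss_labels.values() if v == "unmarked"),
    }
    if config.ip_tracks:
        track = read_bedgraph(config.ip_tracks[0])
        mg = prof.metagene_matrix(track, genes, config.body_bins, config.flank,
                                  config.flank_bin, layout)
        profile = mg.profile()
        np.savetxt(out / "metagene_profile.tsv",
                   np.column_stack([np.arange(len(profile)), profile]),
                   fmt=("%d", "%.6f"), delimiter="\t", header="bin\tmean",
                   comments="")
        argmax = int(np.nanargmax(profile))
        profile_summary["metagene_argmax_bin"] = argmax
        profile_summary["metagene_tss_bin"] = mg.tss_column()
    else:
        profile_summary["metagene"] = "skipped"
    summary["profiles"] = profile_summary

    # ---- stage 4: methylation ------------------------------------------
    mcg_class: dict[str, str] = {}
    dmrs_all: list[meth.DMRRecord] = []
    if config.cx_report:
        wt_meth = read_cx_report(config.cx_report)
        levels = meth.gene_body_levels(wt_meth, genes, "CG",
                                       config.dmr_params.min_cov)
        mcg_class = {g: meth.classify_gene_mcg(l) for g, l in levels.items()
                     if l is not None}
        meth_summary: dict = {
            "n_classified": len(mcg_class),
            "class_counts": {c: sum(1 for v in mcg_class.values() if v == c)
                             for c in ("heavy", "moderate", "light")},
        }
        if config.mutant_cx_report:
            mut_meth = read_cx_report(config.mutant_cx_report)
            for context in ("CG", "CHG", "CHH"):
                d = meth.call_dmrs(wt_meth, mut_meth, context, config.dmr_params)
                dmrs_all.extend(d)
                meth_summary[f"n_dmrs_{context}"] = len(d)
            meth.write_dmrs(dmrs_all, out / "dmrs.bed")
        else:
            meth_summary["dmrs"] = "skipped"
        summary["methylation"] = meth_summary
    else:
        summary["methylation"] = "skipped"

    # ---- stage 5: differential -----------------------------------------
    if config.mutant_ip_tracks and config.mutant_input_tracks:
        mut_reps = []
        for i, ip_path in enumerate(config.mutant_ip_tracks):
            in_path = config.mutant_input_tracks[min(i, len(config.mutant_input_tracks) - 1)]
            mut_reps.append(pc.call_enriched_windows(
                read_bedgraph(ip_path), read_bedgraph(in_path),
                config.peak_params, layout))
        mut_peaks = (pc.consensus_peaks(mut_reps[0], mut_reps[1])
                     if len(mut_reps) > 1 else mut_reps[0])
        regions = merge_intervals(list(peaks) + list(mut_peaks))
        tracks = {}
        for i, p in enumerate(config.ip_tracks):
            tracks[f"wt_{i + 1}"] = read_bedgraph(p)
        for i, p in enumerate(config.mutant_ip_tracks):
            tracks[f"mut_{i + 1}"] = read_bedgraph(p)
        matrix, libs = diff.build_count_matrix(regions, tracks)
        groups = {s: ("wt" if s.startswith("wt") else "mut") for s in tracks}
        dars = diff.call_dars(matrix, libs, groups, regions,
                              config.lfc_cut, config.fdr)
        diff.write_dar_table(dars, out / "dars.tsv")
        dar_ivs = [r.interval for r in dars]
        diff_summary = {"n_mutant_peaks": len(mut_peaks),
                        "n_regions": len(regions), "n_dars": len(dars)}
        dags = diff.dar_genes(dars, genes, layout, config.promoter_bp)
        diff_summary["n_dags"] = len(dags)
        if dmrs_all:
            udags = diff.identify_udags(dags, genes, dmrs_all,
                                        config.promoter_bp, layout)
            with open(out / "udags.tsv", "w") as fh:
                fh.writelines(f"{g}\n" for g in udags)
            diff_summary["n_udags"] = len(udags)
            if dar_ivs:
                cmp_ = diff.dar_dmr_overlap_comparison(
                    dar_ivs, [d.interval for d in dmrs_all], layout,
                    seed=config.seed)
                diff_summary["dar_dmr_overlap"] = {
                    k: cmp_[k] for k in ("observed_percent", "null_percent",
                                         "fisher_p")}
        summary["differential"] = diff_summary
    else:
        summary["differential"] = "skipped"

    # ---- stage 6: integration ------------------------------------------
    if config.expression:
        expr = expression_dict(read_expression_table(config.expression))
        histone = {m: read_bed(p) for m, p in config.histone_beds.items()}
        dhs = read_bed(config.dhs_bed) if config.dhs_bed else None
        tfs = {t: read_bed(p) for t, p in config.tf_beds.items()}
        table = istats.build_marked_gene_table(
            genes, expr, tss_labels, mcg_class or None, histone or None,
            dhs, tfs or None, layout=layout)
        table.to_csv(out / "marked_gene_table.tsv", sep="\t")
        overlap = istats.expressed_gene_overlap(table, config.fpkm_cut)
        marked = table["acetylation"] != "unmarked"
        comp = istats.compare_marked_expression(
            table, table["acetylation"].where(marked, "unmarked"))
        integration = {
            "expressed_overlap": {k: overlap[k] for k in
                                  ("fisher_p", "pct_expressed_marked",
                                   "pct_marked_expressed", "n_expressed",
                                   "n_marked")},
            "expression_by_acetylation": {
                "medians": {k: v["median"] for k, v in comp["groups"].items()},
                "pairwise_p": {f"{a}|{b}": p
                               for (a, b), p in comp["pairwise_p"].items()},
            },
        }
        refsets = dict(histone)
        if dhs is not None:
            refsets["DHS"] = dhs
        refsets.update({f"tf_{t}": v for t, v in tfs.items()})
        if refsets:
            coloc = istats.colocalization_table(peaks, refsets, layout,
                                                seed=config.seed,
                                                min_overlap_bp=config.min_overlap_bp)
            coloc.to_csv(out / "colocalization.tsv", sep="\t", index=False)
            integration["colocalization_percent"] = dict(
                zip(coloc["set"], coloc["observed_percent"]))
        summary["integration"] = integration
    else:
        summary["integration"] = "skipped"

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
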