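"""Coupled synthetic genome / epigenome / expression generator.

The simulator emulates the structure the analysis is built to detect in
a small flowering-plant genome: non-overlapping genes on both strands
confined to chromosome arms, a pericentromeric heterochromatin block
per chromosome, log-normal expression, TSS-proximal acetylation peaks
whose presence probability rises with expression rank (logistic link),
IP coverage as Poisson noise over a fragment-smoothed enrichment
profile with a matched input, three-context cytosine methylation
(hyper-mCHG/mCHH heterochromatin, gene-body mCG), histone marks and
DHS/TF intervals sampled conditional on the acetylation truth, and two
methylation-mutant modes (CG erasure; regional hypermethylation with
optional peak attenuation planting true DARs).

Every planted element is recorded in a ground-truth manifest, and the
whole bundle is deterministic given the seed: identical configs produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import (CoverageTrack, GeneModel, GenomicInterval,
                         MethylationTable, write_bed, write_bedgraph,
                         write_cx_report, write_expression_table,
                         write_gene_models, ExpressionRecord)
from .genome_intervals import GenomeLayout

_BIOTYPE_WEIGHTS = {
    "protein_coding": 0.82, "te_gene": 0.06, "pseudogene": 0.04,
    "mirna": 0.02, "trna": 0.02, "snrna": 0.01, "snorna": 0.01,
    "other_ncrna": 0.02,
}


@dataclass(slots=True)
class SimulationConfig:
    """Study conditions of the synthetic epigenome.

    Defaults mirror the assayed system: a ~5 Mb toy genome with 500
    genes, 200-400 bp IP fragments at ~30x background depth, planted
    peaks at 8-fold enrichment centred near the TSS, ~30x bisulfite
    depth, and a pericentromeric heterochromatin block per chromosome.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_500_000
    n_genes: int = 500
    gene_length_mu: float = math.log(2000.0)   # log-normal body length
    gene_length_sigma: float = 0.45
    min_gene_length: int = 600
    max_gene_length: int = 15_000
    min_gene_gap: int = 400
    heterochromatin_fraction: float = 0.2      # central block per chromosome
    # expression (FPKM)
    expression_zero_fraction: float = 0.2
    expression_mu: float = 1.0                 # log-normal, natural log
    expression_sigma: float = 1.5
    # acetylation peaks: logistic link on centred expression rank
    peak_logit_intercept: float = 0.0
    peak_logit_slope: float = 6.0
    # given a peak, P(TSS-proximal placement) is also a logistic in the
    # expression rank, so body-marked genes skew to lower expression
    tss_placement_intercept: float = 1.0
    tss_placement_slope: float = 3.0
    peak_offset_mean: float = 150.0            # bp downstream of the TSS
    peak_offset_sigma: float = 100.0           # bp, spread of the peak centre
    peak_width_min: int = 300
    peak_width_max: int = 500
    enrichment_fold: float = 8.0
    # coverage
    background_depth: float = 30.0             # per-base expected IP/input depth
    coverage_bin: int = 10                     # bedGraph resolution, bp
    fragment_length: int = 300                 # smoothing kernel (200-400 bp library)
    # methylation
    site_spacing: int = 20                     # mean bp between cytosine sites
    meth_depth: float = 30.0                   # mean bisulfite coverage per site
    beta_het: dict = field(default_factory=lambda: {
        "CG": (8.0, 2.0), "CHG": (6.0, 4.0), "CHH": (2.0, 4.0)})
    beta_eu: dict = field(default_factory=lambda: {
        "CG": (0.5, 20.0), "CHG": (0.5, 30.0), "CHH": (0.5, 30.0)})
    beta_gene_body_cg: tuple = (0.5, 3.5)      # per-gene body-mCG mean (~0.125)
    gene_body_cg_conc: float = 2.0             # site-level spread around the gene mean
    # histone marks / DHS / TFs: P(mark | 4acC gene), P(mark | other gene)
    histone_cond: dict = field(default_factory=lambda: {
        "H3K4me2": (0.75, 0.30), "H3K4me3": (0.75, 0.25),
        "H3K36me3": (0.70, 0.30), "H3K9ac": (0.70, 0.25),
        "H3K14ac": (0.65, 0.25), "H3K9me2": (0.05, 0.25),
        "H3K9me3": (0.05, 0.20), "H3K27me3": (0.10, 0.30)})
    dhs_cond: tuple = (0.75, 0.25)
    dhs_width: int = 400
    n_tfs: int = 3
    tf_peak_fraction: float = 0.3              # truth peaks bound per TF
    tf_background_sites: int = 200
    tf_width: int = 200
    # mutants
    met1_beta: tuple = (0.5, 50.0)             # CG levels after CG erasure
    rdd_n_hyper: int = 20
    rdd_hyper_delta: float = 0.4
    rdd_hyper_length: int = 2000
    dar_attenuated_fraction: float = 0.3       # peaks attenuated in mutants
    attenuated_fold: float = 1.0               # residual fold at attenuated peaks

    def __post_init__(self) -> None:
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if self.meth_depth < 1:
            raise ValueError("meth_depth must be >= 1")
        for p in (self.expression_zero_fraction, self.heterochromatin_fraction,
                  self.tf_peak_fraction, self.dar_attenuated_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TruthManifest:
    """Ground truth of every planted element, keyed to emitted files."""

    genes: list[dict]                 # gene_id, chrom, tss, strand, fpkm, peak
    peaks: list[dict]                 # chrom, start, end, fold, gene_id
    het_blocks: list[dict]            # chrom, start, end
    mutants: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def peak_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(p["chrom"], p["start"], p["end"], score=p["fold"])
                for p in self.peaks]


def _het_blocks(config: SimulationConfig) -> list[tuple[str, int, int]]:
    out = []
    L = config.chrom_length
    half = int(L * config.heterochromatin_fraction / 2)
    for c in range(config.n_chroms):
        mid = L // 2
        out.append((f"chr{c + 1}", mid - half, mid + half))
    return out


def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None):
    """Genome layout plus non-overlapping gene models (euchromatic arms).

    Genes get 1-5 exons, UTRs at the transcript ends, random strands and
    biotypes.  Deterministic given the config seed.  Raises when the
    requested gene density cannot be placed.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    layout = GenomeLayout({f"chr{c + 1}": config.chrom_length
                           for c in range(config.n_chroms)})
    het = {c: (s, e) for c, s, e in _het_blocks(config)}
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return layout, genes
    lengths = np.clip(np.exp(rng.normal(config.gene_length_mu, config.gene_length_sigma,
                                        config.n_genes)).astype(np.int64),
                      config.min_gene_length, config.max_gene_length)
    demand = int(lengths.sum() + config.n_genes * config.min_gene_gap)
    arms_bp = int(config.n_chroms * config.chrom_length * (1 - config.heterochromatin_fraction))
    if demand > arms_bp:
        raise ValueError("requested gene density exceeds the euchromatic space; "
                         "lower n_genes or gene lengths")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    biotypes = list(_BIOTYPE_WEIGHTS)
    bt_p = np.array(list(_BIOTYPE_WEIGHTS.values()))
    bt_p = bt_p / bt_p.sum()
    for i, glen in enumerate(lengths):
        ok = False
        for _ in range(300):
            chrom = layout.names[int(rng.integers(config.n_chroms))]
            start = int(rng.integers(0, config.chrom_length - glen))
            end = start + int(glen)
            hs, he = het[chrom]
            if not (end + config.min_gene_gap <= hs or start >= he + config.min_gene_gap):
                continue
            if any(start < e + config.min_gene_gap and end + config.min_gene_gap > s
                   for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            ok = True
            break
        if not ok:
            raise ValueError("gene placement failed after bounded retries; "
                             "lower the gene density")
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotypes[int(rng.choice(len(biotypes), p=bt_p))]
        n_exons = int(rng.integers(1, 6))
        exons = _split_exons(rng, start, end, n_exons)
        utr5, utr3 = _make_utrs(rng, exons, strand)
        genes.append(GeneModel(f"gene{i + 1:04d}", chrom, strand, start, end,
                               exons=exons, utr5=utr5, utr3=utr3, biotype=biotype))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return layout, genes


def _split_exons(rng: np.random.Generator, start: int, end: int, n_exons: int):
    length = end - start
    n_seg = 2 * n_exons - 1
    if length < n_seg * 60:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, length // 60), size=n_seg - 1,
                              replace=False)) * 60
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for k in range(n_exons):
        s = start + int(bounds[2 * k])
        e = start + int(bounds[2 * k + 1])
        exons.append((s, e))
    return exons


def _make_utrs(rng: np.random.Generator, exons, strand):
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    u_left = min(int(rng.integers(40, 200)), (first_e - first_s) // 2)
    u_right = min(int(rng.integers(40, 200)), (last_e - last_s) // 2)
    left = [(first_s, first_s + u_left)] if u_left > 0 else []
    right = [(last_e - u_right, last_e)] if u_right > 0 else []
    if strand == "+":
        return left, right
    return right, left


@dataclass
class SyntheticEpigenome:
    """Complete synthetic bundle with its ground truth.

    ``sites`` holds per-chromosome cytosine arrays (pos, strand code,
    context code, base level) so mutants can resample counts from
    modified levels at the same positions.
    """

    config: SimulationConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    expression: dict[str, float]
    manifest: TruthManifest
    ip_tracks: list[CoverageTrack]
    input_tracks: list[CoverageTrack]
    methylation: MethylationTable
    site_levels: dict[str, np.ndarray]
    histone_peaks: dict[str, list[GenomicInterval]]
    dhs: list[GenomicInterval]
    tf_peaks: dict[str, list[GenomicInterval]]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.layout.write_chrom_sizes(out / "chrom.sizes")
        write_gene_models(self.genes, out / "genes.gff3")
        write_expression_table(
            [ExpressionRecord(g, f) for g, f in sorted(self.expression.items())],
            out / "expression.tsv")
        for i, tr in enumerate(self.ip_tracks, 1):
            write_bedgraph(tr, out / f"ip_rep{i}.bedgraph")
        for i, tr in enumerate(self.input_tracks, 1):
            write_bedgraph(tr, out / f"input_rep{i}.bedgraph")
        write_cx_report(self.methylation, out / "cx_report.txt")
        marks = out / "marks"
        marks.mkdir(exist_ok=True)
        for mark, ivs in self.histone_peaks.items():
            write_bed(ivs, marks / f"{mark}.bed")
        write_bed(self.dhs, out / "dhs.bed")
        for tf, ivs in self.tf_peaks.items():
            write_bed(ivs, out / f"tf_{tf}.bed")
        self.manifest.to_json(out / "manifest.json")


def _peak_rate_profile(layout: GenomeLayout, peaks: list[dict], fold_by_index,
                       config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-bin enrichment multiplier: 1 + (fold-1) * smoothed footprint."""
    bin_size = config.coverage_bin
    kernel_bins = max(1, config.fragment_length // bin_size)
    kernel = np.ones(kernel_bins) / kernel_bins
    out = {}
    for chrom in layout.names:
        n = (layout.length(chrom) + bin_size - 1) // bin_size
        boost = np.zeros(n)
        for i, p in enumerate(peaks):
            if p["chrom"] != chrom:
                continue
            fold = fold_by_index(i)
            b0, b1 = p["start"] // bin_size, (p["end"] - 1) // bin_size + 1
            boost[b0:b1] = np.maximum(boost[b0:b1], fold - 1.0)
        smooth = np.convolve(boost, kernel, mode="same")
        out[chrom] = 1.0 + smooth
    return out


def _sample_tracks(rng: np.random.Generator, layout: GenomeLayout,
                   rate_profile: dict[str, np.ndarray] | None,
                   config: SimulationConfig) -> CoverageTrack:
    bin_size = config.coverage_bin
    values = {}
    for chrom in layout.names:
        n = (layout.length(chrom) + bin_size - 1) // bin_size
        rate = np.full(n, config.background_depth)
        if rate_profile is not None:
            rate = rate * rate_profile[chrom]
        counts = rng.poisson(rate * bin_size)
        values[chrom] = counts / bin_size
    return CoverageTrack.from_binned(values, bin_size, layout.lengths)


_CTX_CODE = {"CG": 0, "CHG": 1, "CHH": 2}
_CTX_NAME = {v: k for k, v in _CTX_CODE.items()}


def _base_methylation_levels(rng, layout, genes, het, config):
    """Sample cytosine positions and their latent methylation levels."""
    sites = {}
    levels = {}
    gene_spans = {}
    a_g, b_g = config.beta_gene_body_cg
    for g in genes:
        # one latent body-mCG mean per gene, so genes spread across the
        # heavy/moderate/light classes instead of clustering at one mean
        gene_spans.setdefault(g.chrom, []).append(
            (g.start, g.end, float(rng.beta(a_g, b_g))))
    for chrom in layout.names:
        L = layout.length(chrom)
        n = L // config.site_spacing
        pos = np.sort(rng.choice(L, size=n, replace=False)).astype(np.int64)
        ctx = rng.choice(3, size=n, p=[0.35, 0.30, 0.35]).astype(np.int8)
        strand = rng.choice(2, size=n).astype(np.int8)
        hs, he = het[chrom]
        in_het = (pos >= hs) & (pos < he)
        gene_mean = np.full(n, np.nan)
        for s, e, gm in gene_spans.get(chrom, []):
            lo, hi = np.searchsorted(pos, (s, e))
            gene_mean[lo:hi] = gm
        in_gene = ~np.isnan(gene_mean)
        lvl = np.empty(n)
        for code, name in _CTX_NAME.items():
            m = ctx == code
            a, b = config.beta_eu[name]
            lvl[m] = rng.beta(a, b, size=int(m.sum()))
            mh = m & in_het
            a, b = config.beta_het[name]
            lvl[mh] = rng.beta(a, b, size=int(mh.sum()))
            if name == "CG":
                mg = m & in_gene & ~in_het
                k = config.gene_body_cg_conc
                gm = np.clip(gene_mean[mg], 1e-3, 1 - 1e-3)
                lvl[mg] = rng.beta(k * gm, k * (1.0 - gm))
        sites[chrom] = np.rec.fromarrays([pos, strand, ctx],
                                         names=["pos", "strand", "ctx"])
        levels[chrom] = lvl
    return sites, levels


def _sample_methylation(rng, sites, levels, config) -> MethylationTable:
    frames = []
    for chrom in sorted(sites):
        rec = sites[chrom]
        lvl = levels[chrom]
        total = rng.poisson(config.meth_depth, size=len(rec))
        meth = rng.binomial(total, np.clip(lvl, 0, 1))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": rec.pos,
            "strand": np.where(rec.strand == 0, "+", "-"),
            "context": [ _CTX_NAME[c] for c in rec.ctx ],
            "n_meth": meth, "n_total": total}))
    return MethylationTable(pd.concat(frames, ignore_index=True))


def generate_epigenome(config: SimulationConfig | None = None) -> SyntheticEpigenome:
    """Generate the full coupled wild-type bundle from one config."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence([config.seed, 2])
    (r_genome, r_expr, r_peaks, r_cov1, r_cov2, r_in1, r_in2,
     r_meth, r_marks) = [np.random.default_rng(s) for s in ss.spawn(9)]

    layout, genes = generate_genome(config, r_genome)
    het = {c: (s, e) for c, s, e in _het_blocks(config)}

    # expression
    n = len(genes)
    fpkm = np.exp(r_expr.normal(config.expression_mu, config.expression_sigma, n))
    zero = r_expr.random(n) < config.expression_zero_fraction
    fpkm[zero] = 0.0
    expression = {g.gene_id: float(f) for g, f in zip(genes, fpkm)}

    # acetylation truth: logistic link on centred expression rank
    order = np.argsort(np.argsort(fpkm, kind="stable"), kind="stable")
    u = order / max(n - 1, 1) - 0.5
    logit = config.peak_logit_intercept + config.peak_logit_slope * u
    p_peak = 1.0 / (1.0 + np.exp(-logit))
    has_peak = r_peaks.random(n) < p_peak
    p_tss = 1.0 / (1.0 + np.exp(-(config.tss_placement_intercept
                                  + config.tss_placement_slope * u)))
    peaks: list[dict] = []
    gene_entries = []
    for g, hp, f, pt in zip(genes, has_peak, fpkm, p_tss):
        entry = {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
                 "strand": g.strand, "fpkm": float(f), "has_peak": bool(hp),
                 "peak": None, "placement": None}
        if hp:
            width = int(r_peaks.integers(config.peak_width_min, config.peak_width_max + 1))
            at_tss = (r_peaks.random() < pt) or (g.length < 3 * width)
            if at_tss:
                # centred slightly downstream of the TSS (into the 5' end
                # of the body); truncated at 4 sigma to stay TSS-proximal
                offset = config.peak_offset_mean + float(
                    np.clip(r_peaks.normal(0.0, config.peak_offset_sigma),
                            -4 * config.peak_offset_sigma,
                            4 * config.peak_offset_sigma))
                center = g.tss + int(round(offset if g.strand == "+" else -offset))
            else:
                # gene-body peak well clear of the TSS window
                lo = g.start + width if g.strand == "+" else g.start
                hi = g.end if g.strand == "+" else g.end - width
                center = int(r_peaks.integers(lo + width, hi - width))
            s = max(0, center - width // 2)
            e = min(layout.length(g.chrom), s + width)
            if e - s >= 50:
                peaks.append({"chrom": g.chrom, "start": s, "end": e,
                              "fold": config.enrichment_fold, "gene_id": g.gene_id})
                entry["peak"] = [s, e]
                entry["placement"] = "tss" if at_tss else "body"
            else:
                entry["has_peak"] = False
        gene_entries.append(entry)

    profile = _peak_rate_profile(layout, peaks, lambda i: peaks[i]["fold"], config)
    ip1 = _sample_tracks(r_cov1, layout, profile, config)
    ip2 = _sample_tracks(r_cov2, layout, profile, config)
    in1 = _sample_tracks(r_in1, layout, None, config)
    in2 = _sample_tracks(r_in2, layout, None, config)

    sites, site_levels = _base_methylation_levels(r_meth, layout, genes, het, config)
    meth = _sample_methylation(r_meth, sites, site_levels, config)

    # histone marks / DHS / TFs conditional on the acetylation truth
    histone: dict[str, list[GenomicInterval]] = {m: [] for m in config.histone_cond}
    dhs: list[GenomicInterval] = []
    for g, hp in zip(genes, has_peak):
        for mark, (p_ac, p_no) in config.histone_cond.items():
            if r_marks.random() < (p_ac if hp else p_no):
                histone[mark].append(GenomicInterval(g.chrom, g.start, g.end,
                                                     name=f"{mark}_{g.gene_id}"))
        if r_marks.random() < (config.dhs_cond[0] if hp else config.dhs_cond[1]):
            s = max(0, g.tss - config.dhs_width // 2)
            e = min(layout.length(g.chrom), s + config.dhs_width)
            dhs.append(GenomicInterval(g.chrom, s, e, name=f"dhs_{g.gene_id}"))
    tf_peaks: dict[str, list[GenomicInterval]] = {}
    for t in range(config.n_tfs):
        name = f"TF{t + 1}"
        ivs = []
        for p in peaks:
            if r_marks.random() < config.tf_peak_fraction:
                c = (p["start"] + p["end"]) // 2
                s = max(0, c - config.tf_width // 2)
                ivs.append(GenomicInterval(p["chrom"], s, s + config.tf_width))
        for _ in range(config.tf_background_sites):
            chrom = layout.names[int(r_marks.integers(config.n_chroms))]
            s = int(r_marks.integers(0, layout.length(chrom) - config.tf_width))
            ivs.append(GenomicInterval(chrom, s, s + config.tf_width))
        tf_peaks[name] = ivs

    manifest = TruthManifest(
        genes=gene_entries, peaks=peaks,
        het_blocks=[{"chrom": c, "start": s, "end": e} for c, s, e in _het_blocks(config)])
    return SyntheticEpigenome(config, layout, genes, expression, manifest,
                              [ip1, ip2], [in1, in2], meth, site_levels,
                              histone, dhs, tf_peaks,
                              )


# stash sites for mutant resampling
def _regen_sites(wt: SyntheticEpigenome):
    """Reconstruct the site arrays (pos/strand/ctx) from the WT table."""
    sites = {}
    for chrom in sorted(wt.methylation.df["chrom"].unique()):
        sub = wt.methylation.df[wt.methylation.df["chrom"] == chrom]
        sites[chrom] = np.rec.fromarrays(
            [sub["pos"].to_numpy(np.int64),
             np.where(sub["strand"].to_numpy() == "+", 0, 1).astype(np.int8),
             sub["context"].map(_CTX_CODE).to_numpy(np.int8)],
            names=["pos", "strand", "ctx"])
    return sites


@dataclass
class MutantEpigenome:
    """One mutant genotype derived from a WT bundle."""

    mode: str
    ip_tracks: list[CoverageTrack]
    input_tracks: list[CoverageTrack]
    methylation: MethylationTable
    planted_hyper_regions: list[GenomicInterval]
    attenuated_peaks: list[GenomicInterval]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, tr in enumerate(self.ip_tracks, 1):
            write_bedgraph(tr, out / f"{self.mode}_ip_rep{i}.bedgraph")
        for i, tr in enumerate(self.input_tracks, 1):
            write_bedgraph(tr, out / f"{self.mode}_input_rep{i}.bedgraph")
        write_cx_report(self.methylation, out / f"{self.mode}_cx_report.txt")
        write_bed(self.planted_hyper_regions, out / f"{self.mode}_hyper_regions.bed")
        write_bed(self.attenuated_peaks, out / f"{self.mode}_attenuated_peaks.bed")


def generate_mutant_epigenome(wt: SyntheticEpigenome, mode: str,
                              config: SimulationConfig | None = None,
                              plant_dars: bool = True) -> MutantEpigenome:
    """Derive a mutant bundle from the WT truth.

    ``met1``: CG site levels resampled near zero (CG erasure), CHG/CHH
    untouched.  ``rdd``: planted hyper-regions gain +delta in all three
    contexts.  In both modes a configured fraction of planted peaks is
    attenuated (``plant_dars``) to create true DARs; the manifest gains
    every planted DMR/DAR.
    """
    config = config or wt.config
    if mode not in ("met1", "rdd"):
        raise ValueError(f"unknown mutant mode {mode!r}")
    ss = np.random.SeedSequence([config.seed, 3, {"met1": 0, "rdd": 1}[mode]])
    r_lvl, r_cnt, r_cov1, r_cov2, r_in1, r_in2, r_sel = [
        np.random.default_rng(s) for s in ss.spawn(7)]

    sites = _regen_sites(wt)
    levels = {c: wt.site_levels[c].copy() for c in wt.site_levels}
    hyper_regions: list[GenomicInterval] = []
    if mode == "met1":
        a, b = config.met1_beta
        for chrom, rec in sites.items():
            cg = rec.ctx == _CTX_CODE["CG"]
            levels[chrom][cg] = r_lvl.beta(a, b, size=int(cg.sum()))
    else:
        arms = []
        for blk in wt.manifest.het_blocks:
            L = wt.layout.length(blk["chrom"])
            arms.append((blk["chrom"], 0, blk["start"]))
            arms.append((blk["chrom"], blk["end"], L))
        for _ in range(config.rdd_n_hyper):
            chrom, lo, hi = arms[int(r_lvl.integers(len(arms)))]
            if hi - lo <= config.rdd_hyper_length:
                continue
            s = int(r_lvl.integers(lo, hi - config.rdd_hyper_length))
            e = s + config.rdd_hyper_length
            hyper_regions.append(GenomicInterval(chrom, s, e))
            rec = sites[chrom]
            i0, i1 = np.searchsorted(rec.pos, (s, e))
            levels[chrom][i0:i1] = np.clip(
                levels[chrom][i0:i1] + config.rdd_hyper_delta, 0.0, 0.97)

    meth = _sample_methylation(r_cnt, sites, levels, config)

    attenuated: list[GenomicInterval] = []
    if plant_dars and wt.manifest.peaks:
        sel = r_sel.random(len(wt.manifest.peaks)) < config.dar_attenuated_fraction
        folds = np.array([p["fold"] for p in wt.manifest.peaks])
        folds[sel] = config.attenuated_fold
        attenuated = [GenomicInterval(p["chrom"], p["start"], p["end"])
                      for p, s in zip(wt.manifest.peaks, sel) if s]
        profile = _peak_rate_profile(wt.layout, wt.manifest.peaks,
                                     lambda i: float(folds[i]), config)
    else:
        profile = _peak_rate_profile(wt.layout, wt.manifest.peaks,
                                     lambda i: wt.manifest.peaks[i]["fold"], config)
    ip1 = _sample_tracks(r_cov1, wt.layout, profile, config)
    ip2 = _sample_tracks(r_cov2, wt.layout, profile, config)
    in1 = _sample_tracks(r_in1, wt.layout, None, config)
    in2 = _sample_tracks(r_in2, wt.layout, None, config)

    wt.manifest.mutants[mode] = {
        "hyper_regions": [[iv.chrom, iv.start, iv.end] for iv in hyper_regions],
        "attenuated_peaks": [[iv.chrom, iv.start, iv.end] for iv in attenuated],
    }
    return MutantEpigenome(mode, [ip1, ip2], [in1, in2], meth,
                           hyper_regions, attenuated)
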