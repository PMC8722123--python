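"""Differential acetylation (DAR) calling, uDAG derivation, DAR-DMR overlap.

DARs are called over a merged peak universe: per region, IP signal is
summed per sample, scaled to the mean library size, and the pooled
mutant-vs-wild-type counts are tested with a two-sided binomial test
against the library-size-ratio null; log2 fold changes use a 0.5
pseudocount.  A region is a DAR iff |log2FC| > 1 and BH-adjusted
q < 0.05 (the contractual thresholds); the pooled binomial test is a
fully specified stand-in for negative-binomial shrinkage machinery.

uDAGs are differentially acetylated genes whose gene body and 1-kb
upstream region overlap no DMR in any context — the 4acC changes that
cannot be explained by local 5mC changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._stats import bh_adjust, fisher_exact, mannwhitney_p
from .formats_io import CoverageTrack, GeneModel, GenomicInterval
from .genome_intervals import GenomeLayout, sample_matched_random_regions
from .methylation import DMRRecord, MethylationTable, region_level_profile
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class DARRecord:
    interval: GenomicInterval
    mean_norm_wt: float
    mean_norm_mut: float
    log2fc: float
    p: float
    q: float

    def is_dar(self, lfc_cut: float = 1.0, fdr: float = 0.05) -> bool:
        return abs(self.log2fc) > lfc_cut and self.q < fdr


def build_count_matrix(regions: list[GenomicInterval],
                       tracks: dict[str, CoverageTrack]):
    """Regions x samples signal matrix plus per-sample library sizes.

    Regions must be disjoint (pre-merged); a region on a chromosome a
    track lacks contributes 0 with a warning.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    "count regions overlap; merge them first (merge_intervals)")
    data = {}
    lib = {}
    warned: set[tuple[str, str]] = set()
    for name, track in tracks.items():
        col = np.zeros(len(regions))
        chroms = set(track.chroms())
        for i, iv in enumerate(regions):
            if iv.chrom not in chroms:
                if (name, iv.chrom) not in warned:
                    logger.warning("track %s lacks chromosome %s: counting 0", name, iv.chrom)
                    warned.add((name, iv.chrom))
                continue
            col[i] = track.sum_range(iv.chrom, iv.start, iv.end)
        data[name] = col
        lib[name] = track.library_size
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    return pd.DataFrame(data, index=index), lib


def call_dars(matrix: pd.DataFrame, lib_sizes: dict[str, float],
              groups: dict[str, str], regions: list[GenomicInterval],
              lfc_cut: float = 1.0, fdr: float = 0.05,
              return_all: bool = False) -> list[DARRecord]:
    """Call DARs from a region x sample signal matrix.

    ``groups`` maps sample name to ``wt``/``mut``.  Swapping the group
    labels negates every log2 fold change and preserves q-values.
    Returns significant DARs, or every scored region when
    ``return_all`` is set.
    """
    wt = [s for s, g in groups.items() if g == "wt"]
    mut = [s for s, g in groups.items() if g == "mut"]
    if not wt or not mut:
        raise ValueError("need at least one sample per group")
    mean_lib = np.mean([lib_sizes[s] for s in groups])
    scaled = matrix.copy()
    for s in groups:
        scaled[s] = matrix[s] * (mean_lib / lib_sizes[s])
    raw_wt = matrix[wt].sum(axis=1).to_numpy()
    raw_mut = matrix[mut].sum(axis=1).to_numpy()
    lib_wt = sum(lib_sizes[s] for s in wt)
    lib_mut = sum(lib_sizes[s] for s in mut)
    p_null = lib_mut / (lib_mut + lib_wt)

    mean_wt = scaled[wt].mean(axis=1).to_numpy()
    mean_mut = scaled[mut].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_mut + 0.5) / (mean_wt + 0.5))

    keep = (raw_wt + raw_mut) > 0
    if (~keep).any():
        logger.warning("call_dars: %d all-zero regions excluded", int((~keep).sum()))
    p = np.ones(len(matrix))
    for i in np.flatnonzero(keep):
        k = int(round(raw_mut[i]))
        n = int(round(raw_mut[i] + raw_wt[i]))
        k = min(k, n)
        p[i] = stats.binomtest(k, n, p_null, alternative="two-sided").pvalue
    q = np.ones(len(matrix))
    q[keep] = bh_adjust(p[keep])

    records = [DARRecord(regions[i], float(mean_wt[i]), float(mean_mut[i]),
                         float(log2fc[i]), float(p[i]), float(q[i]))
               for i in np.flatnonzero(keep)]
    if return_all:
        return records
    return [r for r in records if r.is_dar(lfc_cut, fdr)]


def dar_genes(dars: list[DARRecord] | list[GenomicInterval], genes: list[GeneModel],
              layout: GenomeLayout | None = None, promoter_bp: int = 1000) -> list[str]:
    """Genes whose body or 1-kb promoter overlaps a DAR (the DAGs)."""
    tree: dict[str, IntervalTree] = {}
    for d in dars:
        iv = d.interval if isinstance(d, DARRecord) else d
        tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for g in genes:
        t = tree.get(g.chrom)
        if t is None:
            continue
        clen = layout.length(g.chrom) if layout is not None and g.chrom in layout else None
        prom = g.promoter(promoter_bp, clen)
        if t.overlap(g.start, g.end) or (prom and t.overlap(*prom)):
            out.append(g.gene_id)
    return out


def identify_udags(dags: list[str], genes: list[GeneModel],
                   dmrs: list[DMRRecord] | list[GenomicInterval],
                   upstream_bp: int = 1000,
                   layout: GenomeLayout | None = None) -> list[str]:
    """DAGs whose body and 1-kb upstream region overlap no DMR."""
    by_id = {g.gene_id: g for g in genes}
    tree: dict[str, IntervalTree] = {}
    for d in dmrs:
        iv = d.interval if isinstance(d, DMRRecord) else d
        tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for gid in dags:
        if gid not in by_id:
            raise ValueError(f"unknown gene_id {gid!r}")
        g = by_id[gid]
        t = tree.get(g.chrom)
        if t is None:
            out.append(gid)
            continue
        clen = layout.length(g.chrom) if layout is not None and g.chrom in layout else None
        up = g.upstream_interval(upstream_bp, clen)
        if t.overlap(g.start, g.end) or (up and t.overlap(*up)):
            continue
        out.append(gid)
    return out


def dar_dmr_overlap_comparison(dars: list[GenomicInterval], dmrs: list[GenomicInterval],
                               layout: GenomeLayout, n_null: int = 1,
                               seed: int = 0) -> dict:
    """Observed vs random-region DMR overlap of the DAR set.

    Returns observed %, null % (length-matched random regions,
    ``n_null`` seeded draws pooled), and the two-sided Fisher p on the
    overlapping / non-overlapping x DAR / random 2x2 table.
    """
    if not dars:
        raise ValueError("dar_dmr_overlap_comparison requires at least one DAR")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    tree: dict[str, IntervalTree] = {}
    for iv in dmrs:
        tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def frac_hit(regions):
        hits = 0
        for iv in regions:
            t = tree.get(iv.chrom)
            if t is not None and t.overlap(iv.start, iv.end):
                hits += 1
        return hits

    obs_hit = frac_hit(dars)
    rng = np.random.default_rng(seed)
    null_regions: list[GenomicInterval] = []
    for _ in range(n_null):
        null_regions.extend(sample_matched_random_regions(dars, layout, rng))
    null_hit = frac_hit(null_regions)
    n_obs, n_nul = len(dars), len(null_regions)
    p = fisher_exact([[obs_hit, n_obs - obs_hit], [null_hit, n_nul - null_hit]])
    return {"observed_percent": 100.0 * obs_hit / n_obs,
            "null_percent": 100.0 * null_hit / n_nul,
            "fisher_p": p, "n_dars": n_obs}


def methylation_fold_change_comparison(regions: list[GenomicInterval],
                                       calls_wt: MethylationTable,
                                       calls_mut: MethylationTable,
                                       context: str, layout: GenomeLayout,
                                       seed: int = 0, min_cov: int = 5,
                                       pseudocount: float = 0.01) -> dict:
    """Compare 5mC fold changes (mut/wt) in regions vs random regions.

    Per region the log2 ratio of (weighted level + pseudocount) between
    the two genotypes; unmeasured regions are dropped.  Returns the two
    fold-change arrays and the two-sided Mann-Whitney p.
    """
    random_regions = sample_matched_random_regions(regions, layout, seed)

    def fcs(rs):
        a = region_level_profile(calls_wt, rs, context, min_cov)
        b = region_level_profile(calls_mut, rs, context, min_cov)
        ok = ~(np.isnan(a) | np.isnan(b))
        return np.log2((b[ok] + pseudocount) / (a[ok] + pseudocount))

    fc_obs, fc_null = fcs(regions), fcs(random_regions)
    p = (mannwhitney_p(fc_obs, fc_null)
         if len(fc_obs) and len(fc_null) else float("nan"))
    return {"fc_regions": fc_obs, "fc_random": fc_null, "mannwhitney_p": p}


def write_dar_table(records: list[DARRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmean_norm_wt\tmean_norm_mut\tlog2fc\tp\tq\n")
        for r in records:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                     f"{r.mean_norm_wt:.6f}\t{r.mean_norm_mut:.6f}\t"
                     f"{r.log2fc:.6f}\t{r.p:.6g}\t{r.q:.6g}\n")
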