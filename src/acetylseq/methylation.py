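"""Context-resolved 5mC statistics and a simplified DMR caller.

Methylation over an interval is summarised as the weighted level
sum(methylated reads) / sum(total reads) over qualifying cytosines of
one context (CG/CHG/CHH), the estimator that is robust to uneven
per-site depth.  Gene-body mCG levels feed the heavy / moderate /
light classification (>= 0.1, [0.01, 0.1), < 0.01).

The DMR caller tests every shared cytosine with a two-sided Fisher
exact test on the (methylated, unmethylated) counts of the two samples,
keeps sites with p below threshold and a same-sign level difference of
at least ``delta``, joins candidate runs within ``max_gap`` bp, and
retains regions meeting the site-count, span, and region-level
difference thresholds (delta = 0.1, p = 0.05, >= 4 sites, >= 100 bp,
>= 5x coverage by default).  It is a fully specified exact-test
stand-in for smoothed beta-binomial DMR callers: the thresholds, not
the dispersion model, are the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fisher_exact_vec
from .formats_io import CoverageTrack, GeneModel, GenomicInterval, MethylationTable
from .genome_intervals import GenomeLayout

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class DMRParams:
    delta: float = 0.1
    p_threshold: float = 0.05
    min_cg: int = 4
    min_len: int = 100
    min_cov: int = 5
    max_gap: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.delta <= 1):
            raise ValueError("need 0 < delta <= 1")
        if self.min_cg < 1 or self.min_len < 1:
            raise ValueError("min_cg and min_len must be >= 1")


@dataclass(slots=True)
class DMRRecord:
    interval: GenomicInterval
    context: str
    mean_level_a: float
    mean_level_b: float
    direction: str  # hyper means b > a
    n_sites: int


def _context_arrays(table: MethylationTable, chrom: str, context: str):
    return table.context_sites(chrom, context)


def weighted_methylation_level(table: MethylationTable, interval: GenomicInterval,
                               context: str, min_cov: int = 0) -> float | None:
    """Weighted methylation of one interval, or None when unmeasured.

    Only sites with ``n_total >= min_cov`` (and at least one read)
    qualify; "no qualifying site" is distinct from a measured level of
    zero.
    """
    pos, meth, total = _context_arrays(table, interval.chrom, context)
    lo = np.searchsorted(pos, interval.start, side="left")
    hi = np.searchsorted(pos, interval.end, side="left")
    m, t = meth[lo:hi], total[lo:hi]
    keep = (t >= max(min_cov, 1))
    if not keep.any() or t[keep].sum() == 0:
        return None
    return float(m[keep].sum() / t[keep].sum())


def gene_body_levels(table: MethylationTable, genes: list[GeneModel], context: str = "CG",
                     min_cov: int = 5) -> dict[str, float | None]:
    """Weighted gene-body methylation per gene (None when unmeasured)."""
    out: dict[str, float | None] = {}
    for g in genes:
        out[g.gene_id] = weighted_methylation_level(
            table, GenomicInterval(g.chrom, g.start, g.end), context, min_cov)
    return out


def classify_gene_mcg(level: float) -> str:
    """heavy (>= 0.1) / moderate ([0.01, 0.1)) / light (< 0.01)."""
    if level is None or not (0 <= level <= 1):
        raise ValueError("level must be a defined ratio in [0, 1]")
    if level >= 0.1:
        return "heavy"
    if level >= 0.01:
        return "moderate"
    return "light"


def level_track(table: MethylationTable, context: str, min_cov: int = 1,
                chroms: list[str] | None = None) -> CoverageTrack:
    """Per-cytosine methylation-level track (1-bp steps at covered sites).

    Pairs with ``metagene_matrix(..., gap_policy='ignore')`` so bin
    means average over measured cytosines only.
    """
    steps = {}
    for chrom in (chroms or table.chroms()):
        pos, meth, total = _context_arrays(table, chrom, context)
        keep = total >= max(min_cov, 1)
        p, m, t = pos[keep], meth[keep], total[keep]
        if len(p) == 0:
            continue
        steps[chrom] = (p, p + 1, m / t)
    return CoverageTrack(steps)


def call_dmrs(calls_a: MethylationTable, calls_b: MethylationTable, context: str,
              params: DMRParams | None = None) -> list[DMRRecord]:
    """Differentially methylated regions between two samples.

    Direction ``hyper`` means sample b more methylated than sample a.
    Swapping the arguments returns identical intervals with flipped
    direction.
    """
    params = params or DMRParams()
    records: list[DMRRecord] = []
    chroms = sorted(set(calls_a.chroms()) & set(calls_b.chroms()))
    any_shared = False
    for chrom in chroms:
        pos_a, m_a, t_a = _context_arrays(calls_a, chrom, context)
        pos_b, m_b, t_b = _context_arrays(calls_b, chrom, context)
        shared, ia, ib = np.intersect1d(pos_a, pos_b, return_indices=True)
        if len(shared) == 0:
            continue
        ma, ta = m_a[ia], t_a[ia]
        mb, tb = m_b[ib], t_b[ib]
        cov = (ta >= params.min_cov) & (tb >= params.min_cov)
        shared, ma, ta, mb, tb = shared[cov], ma[cov], ta[cov], mb[cov], tb[cov]
        if len(shared) == 0:
            continue
        any_shared = True
        p = fisher_exact_vec(ma, ta - ma, mb, tb - mb)
        la, lb = ma / ta, mb / tb
        diff = lb - la
        cand = (p < params.p_threshold) & (np.abs(diff) >= params.delta)
        idx = np.flatnonzero(cand)
        if len(idx) == 0:
            continue
        sign = np.sign(diff[idx])
        # break runs on sign change or inter-site gap > max_gap
        brk = np.flatnonzero(
            (np.diff(shared[idx]) > params.max_gap) | (np.diff(sign) != 0)) + 1
        for run in np.split(idx, brk):
            if len(run) < params.min_cg:
                continue
            start, end = int(shared[run[0]]), int(shared[run[-1]]) + 1
            if end - start < params.min_len:
                continue
            lvl_a = ma[run].sum() / ta[run].sum()
            lvl_b = mb[run].sum() / tb[run].sum()
            if abs(lvl_b - lvl_a) < params.delta:
                continue
            records.append(DMRRecord(
                GenomicInterval(chrom, start, end), context,
                float(lvl_a), float(lvl_b),
                "hyper" if lvl_b > lvl_a else "hypo", int(len(run))))
    if not any_shared:
        logger.warning("call_dmrs: no shared %s sites passed the coverage filter", context)
    return records


def write_dmrs(dmrs: list[DMRRecord], path) -> None:
    """BED6+ writer: chrom, start, end, context, levels, direction, sites."""
    with open(path, "w") as fh:
        for d in dmrs:
            fh.write("\t".join([
                d.interval.chrom, str(d.interval.start), str(d.interval.end),
                d.context, f"{d.mean_level_a:.6f}", f"{d.mean_level_b:.6f}",
                d.direction, str(d.n_sites)]) + "\n")


def genome_weighted_level(table: MethylationTable, context: str,
                          min_cov: int = 1) -> float | None:
    """Genome-wide weighted methylation level for one context."""
    tm = ts = 0
    for chrom in table.chroms():
        pos, meth, total = _context_arrays(table, chrom, context)
        keep = total >= max(min_cov, 1)
        tm += int(meth[keep].sum())
        ts += int(total[keep].sum())
    return None if ts == 0 else tm / ts


def region_level_profile(table: MethylationTable, regions: list[GenomicInterval],
                         context: str, min_cov: int = 5) -> np.ndarray:
    """Weighted level per region (NaN when unmeasured)."""
    out = np.full(len(regions), np.nan)
    for i, iv in enumerate(regions):
        lvl = weighted_methylation_level(table, iv, context, min_cov)
        if lvl is not None:
            out[i] = lvl
    return out
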