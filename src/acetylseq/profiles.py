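"""Metagene matrices, TSS-window gene labels, chromosome-scale profiles.

A metagene profile rescales every gene body to a fixed number of bins
(default 20) between TSS and TES, adds fixed-width flank bins over the
1-kb upstream/downstream regions, and averages the per-base signal per
bin; minus-strand genes are reversed so columns always run
upstream -> TSS -> body -> TES -> downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats_io import CoverageTrack, GeneModel, GenomicInterval
from .genome_intervals import GenomeLayout, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class MetageneMatrix:
    """Genes x bins matrix of mean signal per bin.

    Columns: ``flank_bins`` upstream bins, ``body_bins`` body bins,
    ``flank_bins`` downstream bins, in transcription orientation.
    NaN marks bins with no measurable bases (outside the chromosome, or
    no covered site under the ``ignore``-gaps policy).
    """

    gene_ids: list[str]
    values: np.ndarray
    body_bins: int
    flank: int
    flank_bin: int

    @property
    def flank_bins(self) -> int:
        return self.flank // self.flank_bin

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def profile(self) -> np.ndarray:
        """Column means over genes (NaN bins excluded)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def tss_column(self) -> int:
        """Index of the first body bin (the TSS-proximal column)."""
        return self.flank_bins

    def to_frame(self) -> pd.DataFrame:
        cols = ([f"up_{i}" for i in range(self.flank_bins)]
                + [f"body_{i}" for i in range(self.body_bins)]
                + [f"down_{i}" for i in range(self.flank_bins)])
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


def _gene_bins(gene: GeneModel, body_bins: int, flank: int, flank_bin: int):
    """(start, end) per bin in transcription order; flanks may leave the
    chromosome and are clipped by the caller."""
    nf = flank // flank_bin
    bins: list[tuple[int, int]] = []
    L = gene.length
    w = L // body_bins
    if gene.strand == "+":
        for j in range(nf):  # upstream, farthest first
            s = gene.start - flank + j * flank_bin
            bins.append((s, s + flank_bin))
        for i in range(body_bins):
            s = gene.start + i * w
            e = gene.start + (i + 1) * w if i < body_bins - 1 else gene.end
            bins.append((s, e))
        for j in range(nf):
            s = gene.end + j * flank_bin
            bins.append((s, s + flank_bin))
    else:
        for j in range(nf):
            e = gene.end + flank - j * flank_bin
            bins.append((e - flank_bin, e))
        for i in range(body_bins):
            e = gene.end - i * w
            s = gene.end - (i + 1) * w if i < body_bins - 1 else gene.start
            bins.append((s, e))
        for j in range(nf):
            e = gene.start - j * flank_bin
            bins.append((e - flank_bin, e))
    return bins


def metagene_matrix(track: CoverageTrack, genes: list[GeneModel],
                    body_bins: int = 20, flank: int = 1000, flank_bin: int = 50,
                    layout: GenomeLayout | None = None,
                    gap_policy: str = "zero") -> MetageneMatrix:
    """Build the genes x bins metagene matrix from a coverage track.

    Each gene body is split into ``body_bins`` equal-length bins (the
    remainder bp go to the bin nearest the TES); flanks are fixed
    ``flank_bin``-bp windows.  ``gap_policy='zero'`` treats uncovered
    bases as signal 0 (IP coverage); ``'ignore'`` averages only covered
    bases (methylation-level tracks, where gaps are missing cytosines).
    Genes shorter than ``body_bins`` bp are skipped with a warning.
    """
    if gap_policy not in ("zero", "ignore"):
        raise ValueError("gap_policy must be 'zero' or 'ignore'")
    nf = flank // flank_bin
    used_ids, rows = [], []
    for g in genes:
        if g.length < body_bins:
            logger.warning("gene %s shorter than %d bp: skipped from metagene",
                           g.gene_id, body_bins)
            continue
        clen = (layout.length(g.chrom) if layout is not None and g.chrom in layout
                else max(track.chrom_end(g.chrom), g.end + flank))
        bins = _gene_bins(g, body_bins, flank, flank_bin)
        starts = np.array([max(0, s) for s, _ in bins], dtype=np.int64)
        ends = np.array([min(clen, e) for _, e in bins], dtype=np.int64)
        width = np.maximum(ends - starts, 0)
        sums = np.zeros(len(bins))
        ok = width > 0
        sums[ok] = track.sums(g.chrom, starts[ok], ends[ok])
        if gap_policy == "zero":
            denom = width.astype(float)
        else:
            denom = np.zeros(len(bins))
            denom[ok] = track.covered_bp(g.chrom, starts[ok], ends[ok])
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, sums / np.maximum(denom, 1e-300), np.nan)
        rows.append(row)
        used_ids.append(g.gene_id)
    values = np.array(rows) if rows else np.empty((0, 2 * nf + body_bins))
    return MetageneMatrix(used_ids, values, body_bins, flank, flank_bin)


def tss_marked_classification(peaks: list[GenomicInterval], genes: list[GeneModel],
                              window: int = 250, promoter_bp: int = 1000,
                              layout: GenomeLayout | None = None) -> dict[str, str]:
    """Label each gene tss_marked / nontss_marked / unmarked.

    ``tss_marked``: a peak overlaps the ``window``-bp window centred on
    the TSS (``[tss - w//2, tss + (w+1)//2)``); else ``nontss_marked``
    if a peak overlaps the gene body or 1-kb promoter; else unmarked.
    """
    tree: dict[str, IntervalTree] = {}
    for p in peaks:
        tree.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    labels: dict[str, str] = {}
    for g in genes:
        t = tree.get(g.chrom)
        if t is None:
            labels[g.gene_id] = "unmarked"
            continue
        ws = max(0, g.tss - window // 2)
        we = g.tss + (window + 1) // 2
        if t.overlap(ws, we):
            labels[g.gene_id] = "tss_marked"
            continue
        clen = layout.length(g.chrom) if layout is not None and g.chrom in layout else None
        prom = g.promoter(promoter_bp, clen)
        if t.overlap(g.start, g.end) or (prom and t.overlap(*prom)):
            labels[g.gene_id] = "nontss_marked"
        else:
            labels[g.gene_id] = "unmarked"
    return labels


def chromosome_bin_profile(peaks: list[GenomicInterval], layout: GenomeLayout,
                           bin_size: int = 100_000) -> dict[str, np.ndarray]:
    """Fraction of each fixed-size bin covered by (merged) peaks.

    The final partial bin is normalised by its true length.  Peaks
    straddling a bin boundary contribute their bases to each side.
    """
    merged = merge_intervals(peaks)
    out: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        length = layout.length(chrom)
        n = (length + bin_size - 1) // bin_size
        cov = np.zeros(n)
        for iv in merged:
            if iv.chrom != chrom:
                continue
            b0, b1 = iv.start // bin_size, (iv.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = b * bin_size, min((b + 1) * bin_size, length)
                cov[b] += max(0, min(iv.end, hi) - max(iv.start, lo))
        widths = np.minimum((np.arange(n) + 1) * bin_size, length) - np.arange(n) * bin_size
        out[chrom] = cov / widths
    return out
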