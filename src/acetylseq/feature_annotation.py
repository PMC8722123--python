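"""Single-category peak annotation and observed-vs-expected enrichment.

Each peak is assigned exactly one genomic category — promoter (1 kb
upstream of the TSS, strand-aware), 5' UTR, exon (excluding UTRs),
intron, 3' UTR, or intergenic — by maximal base overlap, so category
percentages always sum to 100.  Bases are labelled with a fixed
priority when features collide: any gene-body subfeature beats a
promoter, and among subfeatures 5' UTR > exon > intron > 3' UTR; when
two genes claim a base at equal priority the gene listed first wins.
The expected genomic composition for the Fisher enrichment tests is
computed by labelling every base of the genome with the same rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._stats import fisher_exact
from .formats_io import BIOTYPES, GeneModel, GenomicInterval
from .genome_intervals import GenomeLayout

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic")

# per-base label codes; higher code wins when features collide
_CODE = {"intergenic": 0, "promoter": 1, "utr3": 2, "intron": 3, "exon": 4, "utr5": 5}
_NAME = {v: k for k, v in _CODE.items()}
# tie order among categories with equal peak overlap (best first)
_TIE_ORDER = ("utr5", "exon", "intron", "utr3", "promoter")

_NO_GENE = -1


@dataclass(slots=True)
class PeakAnnotation:
    peak: GenomicInterval
    category: str
    gene_id: str | None


class GenomeAnnotator:
    """Indexes gene models for per-base labelling and peak annotation."""

    def __init__(self, genes: list[GeneModel], layout: GenomeLayout | None = None,
                 promoter_bp: int = 1000):
        self.genes = list(genes)
        self.layout = layout
        self.promoter_bp = promoter_bp
        self._tree: dict[str, IntervalTree] = {}
        for gi, g in enumerate(self.genes):
            clen = layout.length(g.chrom) if layout is not None and g.chrom in layout else None
            prom = g.promoter(promoter_bp, clen)
            lo = min(g.start, prom[0]) if prom else g.start
            hi = max(g.end, prom[1]) if prom else g.end
            self._tree.setdefault(g.chrom, IntervalTree()).addi(lo, hi, gi)

    def _gene_segments(self, gi: int):
        """(code, start, end) pieces of one gene, ascending priority."""
        g = self.genes[gi]
        clen = (self.layout.length(g.chrom)
                if self.layout is not None and g.chrom in self.layout else None)
        prom = g.promoter(self.promoter_bp, clen)
        if prom:
            yield _CODE["promoter"], prom[0], prom[1]
        for s, e in g.utr3:
            yield _CODE["utr3"], s, e
        for s, e in g.introns:
            yield _CODE["intron"], s, e
        for s, e in g.exon_core():
            yield _CODE["exon"], s, e
        for s, e in g.utr5:
            yield _CODE["utr5"], s, e

    def label_span(self, chrom: str, start: int, end: int):
        """Per-base (category code, gene index) over ``[start, end)``.

        Bases are claimed in ascending priority order; a gene only
        overwrites a base when its category priority is strictly higher,
        so the first gene listed wins priority ties.
        """
        n = end - start
        labels = np.zeros(n, dtype=np.int8)
        owner = np.full(n, _NO_GENE, dtype=np.int64)
        tree = self._tree.get(chrom)
        if tree is None:
            return labels, owner
        hits = sorted((iv.data for iv in tree.overlap(start, end)))
        segs = []  # (code, gene order, start, end)
        for gi in hits:
            for code, s, e in self._gene_segments(gi):
                s, e = max(s, start), min(e, end)
                if s < e:
                    segs.append((code, gi, s, e))
        # ascending priority; within one priority the first-listed gene
        # is processed first and later genes cannot overwrite (strict <)
        segs.sort(key=lambda t: (t[0], t[1]))
        for code, gi, s, e in segs:
            sl = slice(s - start, e - start)
            mask = labels[sl] < code
            labels[sl][mask] = code
            owner[sl][mask] = gi
        return labels, owner

    def classify_peak(self, peak: GenomicInterval) -> PeakAnnotation:
        """Assign a peak the single category with maximal bp overlap.

        Ties go 5' UTR > exon > intron > 3' UTR > promoter; a peak
        touching nothing is intergenic with no gene.  The reported gene
        is the one contributing most bases of the winning category
        (ties to the first-listed gene).
        """
        labels, owner = self.label_span(peak.chrom, peak.start, peak.end)
        counts = np.bincount(labels, minlength=6)
        best, best_n = "intergenic", 0
        for cat in _TIE_ORDER:
            n = int(counts[_CODE[cat]])
            if n > best_n:
                best, best_n = cat, n
        if best == "intergenic":
            return PeakAnnotation(peak, "intergenic", None)
        sel = labels == _CODE[best]
        owners = owner[sel]
        uniq, cnt = np.unique(owners, return_counts=True)
        order = np.lexsort((uniq, -cnt))
        gene = self.genes[int(uniq[order[0]])]
        return PeakAnnotation(peak, best, gene.gene_id)

    def genome_composition(self, layout: GenomeLayout | None = None,
                           chunk: int = 2_000_000) -> dict[str, int]:
        """bp of the genome in each category, by per-base labelling."""
        layout = layout or self.layout
        if layout is None:
            raise ValueError("a GenomeLayout is required")
        bp = {cat: 0 for cat in CATEGORIES}
        for chrom in layout.names:
            length = layout.length(chrom)
            for s in range(0, length, chunk):
                e = min(s + chunk, length)
                labels, _ = self.label_span(chrom, s, e)
                counts = np.bincount(labels, minlength=6)
                for code, name in _NAME.items():
                    bp[name] += int(counts[code])
        return bp


def classify_peak(peak: GenomicInterval, genes: list[GeneModel],
                  layout: GenomeLayout | None = None, promoter_bp: int = 1000) -> PeakAnnotation:
    return GenomeAnnotator(genes, layout, promoter_bp).classify_peak(peak)


def annotate_peaks(peaks: list[GenomicInterval], genes: list[GeneModel],
                   layout: GenomeLayout | None = None,
                   promoter_bp: int = 1000) -> list[PeakAnnotation]:
    ann = GenomeAnnotator(genes, layout, promoter_bp)
    return [ann.classify_peak(p) for p in peaks]


def annotation_distribution(peaks: list[GenomicInterval], genes: list[GeneModel],
                            layout: GenomeLayout, promoter_bp: int = 1000) -> pd.DataFrame:
    """Category counts/percentages plus Fisher enrichment per category.

    The expected arm of each 2x2 table is the per-category bp fraction
    of the genome (same labelling rules) applied to the peak total, so
    the test asks whether peaks fall in a category more or less often
    than uniformly placed bases would.
    """
    if not peaks:
        raise ValueError("annotation_distribution requires at least one peak")
    ann = GenomeAnnotator(genes, layout, promoter_bp)
    cats = [ann.classify_peak(p).category for p in peaks]
    n = len(cats)
    comp = ann.genome_composition(layout)
    total_bp = sum(comp.values())
    rows = []
    for cat in CATEGORIES:
        count = sum(1 for c in cats if c == cat)
        frac = comp[cat] / total_bp
        expected = int(round(frac * n))
        p = fisher_exact([[count, n - count], [expected, n - expected]])
        rows.append({"category": cat, "count": count, "percent": 100.0 * count / n,
                     "expected_percent": 100.0 * frac, "fisher_p": p})
    return pd.DataFrame(rows)


@dataclass
class GenePeakAssignment:
    """Per-gene peak counts plus derived marked-gene summaries."""

    table: pd.DataFrame  # gene_id, biotype, n_body_peaks, n_promoter_peaks, marked

    def marked_gene_ids(self) -> set[str]:
        return set(self.table.loc[self.table["marked"], "gene_id"])

    def marked_fraction_by_biotype(self) -> pd.Series:
        frac = self.table.groupby("biotype")["marked"].mean()
        return frac.reindex([b for b in BIOTYPES if b in frac.index])

    def body_peak_histogram(self, biotype: str | None = "protein_coding") -> dict[str, int]:
        """{1, 2, >2} histogram over genes with gene-body peaks."""
        t = self.table
        if biotype is not None:
            t = t[t["biotype"] == biotype]
        n = t["n_body_peaks"]
        return {"1": int((n == 1).sum()), "2": int((n == 2).sum()),
                ">2": int((n > 2).sum())}


def assign_peaks_to_genes(peaks: list[GenomicInterval], genes: list[GeneModel],
                          layout: GenomeLayout | None = None, promoter_bp: int = 1000,
                          include_promoter: bool = True) -> GenePeakAssignment:
    """Count peaks per gene and flag marked genes.

    A gene is marked iff >= 1 peak overlaps its gene body, or (unless
    ``include_promoter`` is off, the body-only mode used for per-body
    peak histograms) its 1-kb promoter.  A peak spanning several genes
    counts for each of them.
    """
    tree: dict[str, IntervalTree] = {}
    for pi, p in enumerate(peaks):
        tree.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, pi)
    rows = []
    for g in genes:
        t = tree.get(g.chrom)
        n_body = len(t.overlap(g.start, g.end)) if t is not None else 0
        clen = layout.length(g.chrom) if layout is not None and g.chrom in layout else None
        prom = g.promoter(promoter_bp, clen)
        n_prom = len(t.overlap(*prom)) if (t is not None and prom) else 0
        marked = n_body > 0 or (include_promoter and n_prom > 0)
        rows.append({"gene_id": g.gene_id, "biotype": g.biotype,
                     "n_body_peaks": n_body, "n_promoter_peaks": n_prom,
                     "marked": marked})
    return GenePeakAssignment(pd.DataFrame(rows))
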