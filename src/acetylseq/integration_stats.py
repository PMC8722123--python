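"""Combinatorial mark x expression statistics.

Joins everything the pipeline knows about a gene — FPKM, acetylation
status (TSS-proximal / elsewhere / none), gene-body mCG class, histone
marks, DHS and TF-binding overlap — into one table, then answers the
integrative questions: are expressed genes preferentially acetylated
(Fisher), how does expression distribute across mark combinations
(Mann-Whitney on FPKM), and which reference interval sets colocalize
with the acetylation peaks beyond length-matched random chance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._stats import bh_adjust, fisher_exact, group_summary, mannwhitney_p
from .formats_io import ExpressionRecord, GeneModel, GenomicInterval
from .genome_intervals import GenomeLayout, sample_matched_random_regions

logger = logging.getLogger(__name__)

HISTONE_MARKS = ("H3K4me2", "H3K4me3", "H3K36me3", "H3K9ac", "H3K14ac",
                 "H3K9me2", "H3K9me3", "H3K27me3")

ACETYLATION_LABELS = ("tss_marked", "nontss_marked", "unmarked")
MCG_CLASSES = ("heavy", "moderate", "light", "undefined")


def _gene_overlaps(genes: list[GeneModel], intervals: list[GenomicInterval],
                   include_promoter: bool = False, promoter_bp: int = 1000,
                   layout: GenomeLayout | None = None) -> pd.Series:
    tree: dict[str, IntervalTree] = {}
    for iv in intervals:
        tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    flags = {}
    for g in genes:
        t = tree.get(g.chrom)
        hit = bool(t is not None and t.overlap(g.start, g.end))
        if not hit and include_promoter and t is not None:
            clen = layout.length(g.chrom) if layout is not None and g.chrom in layout else None
            prom = g.promoter(promoter_bp, clen)
            hit = bool(prom and t.overlap(*prom))
        flags[g.gene_id] = hit
    return pd.Series(flags)


def build_marked_gene_table(genes: list[GeneModel], expression: dict[str, float],
                            acetylation: dict[str, str],
                            mcg_class: dict[str, str] | None = None,
                            histone_peaks: dict[str, list[GenomicInterval]] | None = None,
                            dhs: list[GenomicInterval] | None = None,
                            tf_peaks: dict[str, list[GenomicInterval]] | None = None,
                            include_promoter: bool = False,
                            layout: GenomeLayout | None = None) -> pd.DataFrame:
    """One row per gene joining expression with every mark.

    Histone / DHS / TF flags mean >= 1 bp overlap with the gene body
    (promoter inclusion is opt-in via ``include_promoter``).
    """
    df = pd.DataFrame({"gene_id": [g.gene_id for g in genes]}).set_index("gene_id")
    df["fpkm"] = [expression.get(g.gene_id, 0.0) for g in genes]
    df["acetylation"] = [acetylation.get(g.gene_id, "unmarked") for g in genes]
    df["mcg_class"] = [(mcg_class or {}).get(g.gene_id, "undefined") for g in genes]
    for mark, peaks in (histone_peaks or {}).items():
        df[mark] = _gene_overlaps(genes, peaks, include_promoter, layout=layout)
    if dhs is not None:
        df["dhs"] = _gene_overlaps(genes, dhs, include_promoter, layout=layout)
    for tf, peaks in (tf_peaks or {}).items():
        df[f"tf_{tf}"] = _gene_overlaps(genes, peaks, include_promoter, layout=layout)
    bad = set(df["acetylation"]) - set(ACETYLATION_LABELS)
    if bad:
        raise ValueError(f"unknown acetylation labels: {sorted(bad)}")
    return df


def expressed_gene_overlap(table: pd.DataFrame, fpkm_cut: float = 0.0) -> dict:
    """2x2 expressed x acetylation-marked counts with Fisher p.

    Also reports the two headline percentages: expressed genes that are
    marked, and marked genes that are expressed.
    """
    if table.empty:
        raise ValueError("expressed_gene_overlap requires a non-empty table")
    expressed = table["fpkm"] > fpkm_cut
    marked = table["acetylation"] != "unmarked"
    a = int((expressed & marked).sum())
    b = int((expressed & ~marked).sum())
    c = int((~expressed & marked).sum())
    d = int((~expressed & ~marked).sum())
    return {
        "counts": [[a, b], [c, d]],
        "fisher_p": fisher_exact([[a, b], [c, d]]),
        "n_expressed": a + b,
        "n_marked": a + c,
        "pct_expressed_marked": 100.0 * a / (a + b) if a + b else 0.0,
        "pct_marked_expressed": 100.0 * a / (a + c) if a + c else 0.0,
    }


def expression_quartile_groups(expr: list[ExpressionRecord] | dict[str, float]) -> dict[str, str]:
    """Q1 (top 25%) .. Q4 by FPKM rank, deterministic under ties.

    Genes are ranked by FPKM descending with ties broken by gene id;
    group sizes differ by at most one, extra genes going to the
    higher-expression groups (n = 10 -> 3, 3, 2, 2).
    """
    if isinstance(expr, dict):
        items = list(expr.items())
    else:
        items = [(r.gene_id, r.fpkm) for r in expr]
    if len(items) < 4:
        raise ValueError("need at least 4 genes for quartile grouping")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    out: dict[str, str] = {}
    i = 0
    for qi, size in enumerate(sizes, 1):
        for gid, _ in items[i:i + size]:
            out[gid] = f"Q{qi}"
        i += size
    return out


def compare_marked_expression(table: pd.DataFrame, grouping,
                              pairs: list[tuple[str, str]] | None = None,
                              value_col: str = "fpkm") -> dict:
    """Per-group medians/IQR plus pairwise two-sided Mann-Whitney p.

    ``grouping`` is a column name or a mapping gene_id -> label; by
    default every pair of observed groups is compared.  Raises when a
    requested group is empty.
    """
    if isinstance(grouping, str):
        labels = table[grouping]
    else:
        labels = table.index.to_series().map(grouping)
    values = table[value_col]
    groups = {}
    for lab in labels.dropna().unique():
        groups[lab] = values[labels == lab].to_numpy()
    if pairs is None:
        names = sorted(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    summaries = {lab: group_summary(v) for lab, v in groups.items()}
    pvals = {}
    for a, b in pairs:
        for g in (a, b):
            if g not in groups or len(groups[g]) == 0:
                raise ValueError(f"empty or missing group {g!r}")
        pvals[(a, b)] = mannwhitney_p(groups[a], groups[b])
    return {"groups": summaries, "pairwise_p": pvals}


def colocalization_table(peaks: list[GenomicInterval],
                         reference_sets: dict[str, list[GenomicInterval]],
                         layout: GenomeLayout, seed: int = 0,
                         min_overlap_bp: int = 1) -> pd.DataFrame:
    """Percent of peaks overlapping each reference set vs random chance.

    The expected percentage comes from one length-matched random draw of
    the query peaks (seeded, shared across rows); each row gets a Fisher
    p on the overlap 2x2 table, plus a BH-adjusted column across rows.
    An empty reference set yields 0% with p = 1 and a warning.
    """
    if not peaks:
        raise ValueError("colocalization_table requires at least one peak")
    random_peaks = sample_matched_random_regions(peaks, layout, seed)

    def hits(query, refs) -> int:
        tree: dict[str, IntervalTree] = {}
        for iv in refs:
            tree.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        n = 0
        for iv in query:
            t = tree.get(iv.chrom)
            if t is None:
                continue
            shared = sum(min(h.end, iv.end) - max(h.begin, iv.start)
                         for h in t.overlap(iv.start, iv.end))
            if shared >= min_overlap_bp:
                n += 1
        return n

    n = len(peaks)
    rows = []
    for name, refs in reference_sets.items():
        if not refs:
            logger.warning("reference set %s is empty", name)
            rows.append({"set": name, "observed_percent": 0.0,
                         "expected_percent": 0.0, "fisher_p": 1.0})
            continue
        obs = hits(peaks, refs)
        exp = hits(random_peaks, refs)
        p = fisher_exact([[obs, n - obs], [exp, n - exp]])
        rows.append({"set": name, "observed_percent": 100.0 * obs / n,
                     "expected_percent": 100.0 * exp / n, "fisher_p": p})
    df = pd.DataFrame(rows)
    df["fisher_q"] = bh_adjust(df["fisher_p"].to_numpy())
    return df
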