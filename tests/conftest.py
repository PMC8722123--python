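"""Shared fixtures: toy genomes, a small synthetic bundle, oracles."""

import numpy as np
import pytest

from acetylseq import (GeneModel, GenomeLayout, GenomicInterval,
                       SimulationConfig, generate_epigenome)


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete synthetic bundle shared across tests."""
    config = SimulationConfig(seed=1, n_genes=60, chrom_length=400_000)
    return generate_epigenome(config)


def make_gene(gene_id="g1", chrom="chr1", strand="+", start=1000, end=3000,
              exons=None, utr5=None, utr3=None, biotype="protein_coding"):
    return GeneModel(gene_id, chrom, strand, start, end,
                     exons=exons or [(start, end)],
                     utr5=utr5 or [], utr3=utr3 or [], biotype=biotype)


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


def random_toy_genome(rng, max_len=100_000, max_genes=50):
    """Random gene models on a toy layout, for oracle comparisons."""
    length = int(rng.integers(20_000, max_len))
    layout = GenomeLayout({"chr1": length})
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    pos = 0
    for i in range(n_genes):
        gap = int(rng.integers(0, 2000))
        start = pos + gap
        glen = int(rng.integers(300, 4000))
        end = start + glen
        if end >= length:
            break
        n_ex = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2,
                                    replace=False)) if n_ex > 1 else np.array([], dtype=int)
        edges = np.concatenate([[0], bounds, [glen]])
        exons = [(start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                 for k in range(n_ex)]
        exons = [(s, e) for s, e in exons if e > s]
        utr5, utr3 = [], []
        fs, fe = exons[0]
        ls, le = exons[-1]
        if fe - fs > 20:
            left = (fs, fs + int(rng.integers(5, (fe - fs) // 2 + 1)))
        else:
            left = None
        if le - ls > 20:
            right = (le - int(rng.integers(5, (le - ls) // 2 + 1)), le)
        else:
            right = None
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            utr5 = [left] if left else []
            utr3 = [right] if right else []
        else:
            utr5 = [right] if right else []
            utr3 = [left] if left else []
        genes.append(GeneModel(f"g{i}", "chr1", strand, start, end,
                               exons=exons, utr5=utr5, utr3=utr3))
        pos = end
    return layout, genes


# independent per-base labelling oracle (naive loops, no interval code)
_ORACLE_PRIORITY = {"intergenic": 0, "promoter": 1, "utr3": 2, "intron": 3,
                    "exon": 4, "utr5": 5}


def oracle_label_genome(layout, genes, promoter_bp=1000):
    """Label every base of chr-by-chr arrays with (category, gene index)."""
    labels = {c: ["intergenic"] * layout.length(c) for c in layout.names}
    owners = {c: [-1] * layout.length(c) for c in layout.names}

    def paint(chrom, s, e, cat, gi):
        lab, own = labels[chrom], owners[chrom]
        for b in range(max(0, s), min(layout.length(chrom), e)):
            if _ORACLE_PRIORITY[lab[b]] < _ORACLE_PRIORITY[cat]:
                lab[b] = cat
                own[b] = gi
    for code in ("promoter", "utr3", "intron", "exon", "utr5"):
        for gi, g in enumerate(genes):
            if code == "promoter":
                prom = g.promoter(promoter_bp, layout.length(g.chrom))
                if prom:
                    paint(g.chrom, prom[0], prom[1], "promoter", gi)
            elif code == "utr3":
                for s, e in g.utr3:
                    paint(g.chrom, s, e, "utr3", gi)
            elif code == "intron":
                for s, e in g.introns:
                    paint(g.chrom, s, e, "intron", gi)
            elif code == "exon":
                for s, e in g.exon_core():
                    paint(g.chrom, s, e, "exon", gi)
            else:
                for s, e in g.utr5:
                    paint(g.chrom, s, e, "utr5", gi)
    return labels, owners


def oracle_classify(labels, owners, genes, peak):
    """Peak category/gene from the oracle labelling by max base count."""
    lab = labels[peak.chrom][peak.start:peak.end]
    own = owners[peak.chrom][peak.start:peak.end]
    counts = {}
    for cat in lab:
        counts[cat] = counts.get(cat, 0) + 1
    best, best_n = "intergenic", 0
    for cat in ("utr5", "exon", "intron", "utr3", "promoter"):
        if counts.get(cat, 0) > best_n:
            best, best_n = cat, counts[cat]
    if best == "intergenic":
        return "intergenic", None
    per_gene = {}
    for c, o in zip(lab, own):
        if c == best:
            per_gene[o] = per_gene.get(o, 0) + 1
    gi = min(per_gene, key=lambda k: (-per_gene[k], k))
    return best, genes[gi].gene_id
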