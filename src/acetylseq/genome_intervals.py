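"""Core interval arithmetic and the length-matched random-region null.

Every enrichment comparison in the pipeline ("peaks vs random regions",
"DARs vs random regions") draws its null from
:func:`sample_matched_random_regions`: one random region per template
interval, identical length, chromosome chosen proportional to
chromosome length, start uniform in the valid range.  The sampler does
not exclude the template's own positions — the simplest null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenomicInterval


@dataclass
class GenomeLayout:
    """Ordered chromosome names with lengths (bp)."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"{name}: chromosome length must be positive")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.lengths and iv.end <= self.lengths[iv.chrom]

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeLayout":
        """Read a 2-column ``chrom<TAB>length`` TSV."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                f = line.split()
                if len(f) < 2:
                    raise ValueError(f"{path}: need 2 columns at line {ln}")
                lengths[f[0]] = int(f[1])
        return cls(lengths)

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases of two half-open intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(xs: list[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Merge intervals within ``gap`` bp into sorted disjoint intervals.

    The merged score is the max of the member scores (names dropped).
    """
    if not xs:
        return []
    xs = sorted(xs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = xs[0].chrom, xs[0].start, xs[0].end
    cur_score = xs[0].score
    for iv in xs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end + gap:
            cur_end = max(cur_end, iv.end)
            if iv.score is not None:
                cur_score = iv.score if cur_score is None else max(cur_score, iv.score)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end, score=cur_score))
            cur_chrom, cur_start, cur_end, cur_score = iv.chrom, iv.start, iv.end, iv.score
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end, score=cur_score))
    return out


def total_covered_bp(xs: list[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(xs))


def sample_matched_random_regions(template: list[GenomicInterval], layout: GenomeLayout,
                                  seed: int | np.random.Generator) -> list[GenomicInterval]:
    """One random region per template interval, with identical length.

    Chromosomes are drawn with probability proportional to their length
    among those that can hold the region; the start is uniform in the
    valid range.  Sampled regions may overlap each other and the
    template.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = layout.names
    lengths = np.array([layout.lengths[n] for n in names], dtype=np.int64)
    out: list[GenomicInterval] = []
    for iv in template:
        fits = lengths >= iv.length
        if not fits.any():
            raise ValueError(
                f"template length {iv.length} exceeds every chromosome")
        p = np.where(fits, lengths, 0).astype(np.float64)
        p /= p.sum()
        ci = int(rng.choice(len(names), p=p))
        start = int(rng.integers(0, lengths[ci] - iv.length + 1))
        out.append(GenomicInterval(names[ci], start, start + iv.length))
    return out
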