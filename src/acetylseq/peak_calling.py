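"""Windowed Poisson IP-vs-input peak caller and replicate consensus.

The caller scores sliding windows by the one-sided Poisson upper-tail
probability of the observed IP signal against a library-size-scaled
input expectation, corrects across all windows with Benjamini-Hochberg,
gates on fold enrichment, and merges surviving windows into peaks.  It
is a deliberately simple, fully specified enrichment caller for
antibody-IP coverage (fragments of a few hundred bp); the FDR < 0.05
retention threshold is the analysis contract, and window/step/fold
defaults suit 200-400 bp fragment libraries.

Replicate handling follows the standard confidence rule: only peaks
that overlap between the two biological replicates are retained,
reported as the union of the reciprocally overlapping coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import bh_adjust
from .formats_io import CoverageTrack, GenomicInterval
from .genome_intervals import GenomeLayout, merge_intervals

MAX_NEGLOG10P = 1000.0


@dataclass(slots=True)
class PeakCallParams:
    """Tuning knobs of the window caller.

    ``fdr`` is the BH threshold on window p-values; ``min_fold`` is the
    extra fold-enrichment gate (IP window signal over the scaled input
    expectation); ``pseudocount`` floors the Poisson rate so empty input
    windows cannot produce infinite enrichment.
    """

    window: int = 200
    step: int = 50
    fdr: float = 0.05
    merge_gap: int = 100
    min_fold: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("need 0 < step <= window")
        if not (0 < self.fdr < 1):
            raise ValueError("need 0 < fdr < 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if length <= window:
        return np.array([0], dtype=np.int64)
    return np.arange(0, length - window + 1, step, dtype=np.int64)


def call_enriched_windows(ip: CoverageTrack, input_track: CoverageTrack,
                          params: PeakCallParams | None = None,
                          layout: GenomeLayout | None = None) -> list[GenomicInterval]:
    """Call enrichment peaks from an IP track against its input.

    Window p-values come from the Poisson upper tail
    ``P(X >= k)`` with ``k`` the (rounded) IP window signal and the rate
    the input window signal scaled by the library-size ratio, floored at
    the pseudocount.  Windows with BH q < fdr and fold >= min_fold are
    merged within ``merge_gap`` bp; the peak score is the max
    -log10 p of its member windows (capped at 1000).
    """
    params = params or PeakCallParams()
    if ip.library_size <= 0 or input_track.library_size <= 0:
        raise ValueError("both tracks need a positive library size")
    scale = ip.library_size / input_track.library_size

    chrom_lengths: dict[str, int] = {}
    for chrom in set(ip.chroms()) | set(input_track.chroms()):
        if layout is not None and chrom in layout:
            chrom_lengths[chrom] = layout.length(chrom)
        else:
            chrom_lengths[chrom] = max(ip.chrom_end(chrom), input_track.chrom_end(chrom))

    all_p, all_fold, keys = [], [], []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            continue
        starts = _window_starts(length, params.window, params.step)
        ends = np.minimum(starts + params.window, length)
        ip_sig = ip.sums(chrom, starts, ends)
        in_sig = input_track.sums(chrom, starts, ends)
        lam = np.maximum(in_sig * scale, params.pseudocount)
        k = np.round(ip_sig)
        p = stats.poisson.sf(k - 1, lam)
        all_p.append(p)
        all_fold.append(ip_sig / lam)
        keys.append((chrom, starts, ends))

    if not all_p:
        return []
    p = np.concatenate(all_p)
    fold = np.concatenate(all_fold)
    q = bh_adjust(p)
    neglog = np.where(p > 0, -np.log10(np.clip(p, 1e-300, None)), MAX_NEGLOG10P)

    passing: list[GenomicInterval] = []
    offset = 0
    for chrom, starts, ends in keys:
        n = len(starts)
        sel = (q[offset:offset + n] < params.fdr) & (fold[offset:offset + n] >= params.min_fold)
        for i in np.flatnonzero(sel):
            passing.append(GenomicInterval(chrom, int(starts[i]), int(ends[i]),
                                           score=float(min(neglog[offset + i], MAX_NEGLOG10P))))
        offset += n
    peaks = merge_intervals(passing, gap=params.merge_gap)
    for i, pk in enumerate(peaks, 1):
        pk.name = f"peak_{i}"
    return peaks


def consensus_peaks(rep1: list[GenomicInterval], rep2: list[GenomicInterval]) -> list[GenomicInterval]:
    """Keep peaks reproducible across two replicates.

    A peak from either replicate is retained iff it shares >= 1 bp with
    some peak of the other replicate; the retained peaks are merged so
    the output is disjoint (union coordinates, score = max contributing
    score).
    """
    kept: list[GenomicInterval] = []
    for mine, other in ((rep1, rep2), (rep2, rep1)):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in other:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
        for iv in mine:
            cands = by_chrom.get(iv.chrom, [])
            starts = [c.start for c in cands]
            lo = np.searchsorted(starts, iv.end)
            if any(c.end > iv.start for c in cands[:lo]):
                kept.append(iv)
    merged = merge_intervals(kept, gap=0)
    for i, pk in enumerate(merged, 1):
        pk.name = f"peak_{i}"
    return merged
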