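"""Readers and writers for the genomics formats the pipeline touches.

Every coordinate inside the package is 0-based, half-open (the BED
convention).  GFF3 (1-based, inclusive) and Bismark-style CX reports
(1-based positions) are converted at this boundary and nowhere else, so
interval arithmetic downstream never has to think about off-by-ones.

The domain types defined here — :class:`GenomicInterval`,
:class:`GeneModel`, :class:`MethylationSiteCall` /
:class:`MethylationTable`, :class:`CoverageTrack`,
:class:`ExpressionRecord` — are the currency of the whole package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Gene-category vocabulary used for per-biotype tallies.  Unknown biotype
#: strings collapse into ``other_ncrna`` with a logged warning.
BIOTYPES = (
    "protein_coding",
    "te_gene",
    "pseudogene",
    "mirna",
    "trna",
    "snrna",
    "snorna",
    "other_ncrna",
)

METH_CONTEXTS = ("CG", "CHG", "CHH")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(slots=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on one chromosome.

    ``score`` typically carries a peak signal (e.g. capped -log10 p) and
    ``strand`` is one of ``+``, ``-`` or ``None`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class GeneModel:
    """Strand-aware gene with one representative transcript.

    ``exons`` / ``utr5`` / ``utr3`` are sorted lists of half-open
    ``(start, end)`` tuples in genomic orientation; UTRs are subsets of
    exon space.  The TSS is the first transcribed base (``start`` on the
    plus strand, ``end - 1`` on the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint and "
                    f"within the gene span"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        prev = self.start
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < self.end:
            out.append((prev, self.end))
        return out

    def exon_core(self) -> list[tuple[int, int]]:
        """Exonic bases excluding both UTRs (the "exon" annotation class)."""
        cut = sorted(self.utr5 + self.utr3)
        out = []
        for s, e in self.exons:
            pos = s
            for cs, ce in cut:
                if ce <= pos or cs >= e:
                    continue
                if cs > pos:
                    out.append((pos, min(cs, e)))
                pos = max(pos, ce)
            if pos < e:
                out.append((pos, e))
        return out

    def promoter(self, flank: int = 1000, chrom_length: int | None = None) -> tuple[int, int] | None:
        """Strand-aware region up to ``flank`` bp upstream of the TSS.

        Clipped at the chromosome start (and end when ``chrom_length``
        is given); returns ``None`` when fully clipped away.
        """
        if self.strand == "+":
            s, e = max(0, self.start - flank), self.start
        else:
            s, e = self.end, self.end + flank
            if chrom_length is not None:
                e = min(e, chrom_length)
        return (s, e) if s < e else None

    def upstream_interval(self, flank: int = 1000, chrom_length: int | None = None) -> tuple[int, int] | None:
        return self.promoter(flank, chrom_length)


@dataclass(slots=True)
class MethylationSiteCall:
    """One cytosine: context, strand and methylated/total read counts."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.context not in METH_CONTEXTS:
            raise ValueError(f"unknown methylation context {self.context!r}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError("need 0 <= n_meth <= n_total")

    @property
    def level(self) -> float | None:
        return None if self.n_total == 0 else self.n_meth / self.n_total


class MethylationTable(Sequence):
    """Columnar container of cytosine calls.

    Behaves as a sequence of :class:`MethylationSiteCall` while storing
    the calls as numpy columns, so whole-genome queries stay vectorised.
    """

    COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        bad = set(df["context"].unique()) - set(METH_CONTEXTS)
        if bad:
            raise ParseError(f"unknown methylation context token(s): {sorted(bad)}")
        if (df["n_meth"] < 0).any() or (df["n_meth"] > df["n_total"]).any():
            raise ParseError("negative or inconsistent methylation counts")
        self.df = df.reset_index(drop=True)
        self._groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_calls(cls, calls: Iterable[MethylationSiteCall]) -> "MethylationTable":
        rows = [(c.chrom, c.pos, c.strand, c.context, c.n_meth, c.n_total) for c in calls]
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                cls.COLUMNS, (str, np.int64, str, str, np.int64, np.int64))})
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        r = self.df.iloc[i]
        return MethylationSiteCall(r["chrom"], int(r["pos"]), r["strand"],
                                   r["context"], int(r["n_meth"]), int(r["n_total"]))

    def __iter__(self) -> Iterator[MethylationSiteCall]:
        for t in self.df.itertuples(index=False):
            yield MethylationSiteCall(t.chrom, int(t.pos), t.strand, t.context,
                                      int(t.n_meth), int(t.n_total))

    def context_sites(self, chrom: str, context: str):
        """Sorted (pos, n_meth, n_total) arrays for one chrom/context.

        Sites on opposite strands at the same position are aggregated.
        """
        key = (chrom, context)
        if key not in self._groups:
            sub = self.df[(self.df["chrom"] == chrom) & (self.df["context"] == context)]
            agg = sub.groupby("pos", sort=True)[["n_meth", "n_total"]].sum()
            self._groups[key] = (
                agg.index.to_numpy(dtype=np.int64),
                agg["n_meth"].to_numpy(dtype=np.int64),
                agg["n_total"].to_numpy(dtype=np.int64),
            )
        return self._groups[key]

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())


class CoverageTrack:
    """Stepped, non-overlapping per-base signal (IP/input coverage).

    Gaps between steps are implicit zeros.  ``library_size`` is the total
    signal (sum of value x length over steps) unless supplied.
    """

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 library_size: float | None = None):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: zero/negative-length coverage step")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage on {chrom}")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage value")
            self._steps[chrom] = (starts, ends, values)
            total += float(np.sum(values * (ends - starts)))
        self.library_size = float(total if library_size is None else library_size)
        self._prefix: dict[str, np.ndarray] = {}
        self._prefix_cov: dict[str, np.ndarray] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_binned(cls, values_by_chrom: dict[str, np.ndarray], bin_size: int,
                    chrom_lengths: dict[str, int] | None = None) -> "CoverageTrack":
        """Build from per-bin per-base values (bins of ``bin_size`` bp)."""
        steps = {}
        for chrom, vals in values_by_chrom.items():
            vals = np.asarray(vals, dtype=np.float64)
            n = len(vals)
            starts = np.arange(n, dtype=np.int64) * bin_size
            ends = starts + bin_size
            if chrom_lengths is not None:
                ends[-1] = min(ends[-1], chrom_lengths[chrom])
            steps[chrom] = (starts, ends, vals)
        return cls(steps)

    # -- queries ------------------------------------------------------
    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def chrom_end(self, chrom: str) -> int:
        if chrom not in self._steps:
            return 0
        return int(self._steps[chrom][1][-1])

    def steps(self, chrom: str):
        if chrom not in self._steps:
            return
        starts, ends, values = self._steps[chrom]
        for s, e, v in zip(starts, ends, values):
            yield GenomicInterval(chrom, int(s), int(e)), float(v)

    def _cumulative(self, chrom: str, x: np.ndarray, coverage: bool) -> np.ndarray:
        """Total signal (or covered bp) in [0, x) for each x, vectorised."""
        if chrom not in self._steps:
            return np.zeros(len(x), dtype=np.float64)
        starts, ends, values = self._steps[chrom]
        cache = self._prefix_cov if coverage else self._prefix
        if chrom not in cache:
            v = np.ones_like(values) if coverage else values
            cache[chrom] = np.concatenate([[0.0], np.cumsum(v * (ends - starts))])
        prefix = cache[chrom]
        v = np.ones_like(values) if coverage else values
        i = np.searchsorted(starts, x, side="right")
        out = prefix[i]
        inside = (i > 0)
        idx = np.clip(i - 1, 0, None)
        partial = inside & (x < ends[idx])
        j = idx[partial]
        out[partial] = prefix[j] + v[j] * (x[partial] - starts[j])
        return out

    def sums(self, chrom: str, starts, ends) -> np.ndarray:
        """Signal sum over each half-open query interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._cumulative(chrom, ends, False) - self._cumulative(chrom, starts, False)

    def covered_bp(self, chrom: str, starts, ends) -> np.ndarray:
        """Number of bases with an explicit step in each query interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._cumulative(chrom, ends, True) - self._cumulative(chrom, starts, True)

    def sum_range(self, chrom: str, start: int, end: int) -> float:
        return float(self.sums(chrom, [start], [end])[0])

    def mean_range(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.sum_range(chrom, start, end) / (end - start)


@dataclass(slots=True)
class ExpressionRecord:
    gene_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: FPKM must be non-negative")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ into intervals (input order preserved).

    Columns 4-6 map to name/score/strand when present; ``.`` means unset.
    BED is already 0-based half-open so coordinates are taken as-is.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = _split(line)
            if len(f) < 3:
                raise ParseError(f"{path}: fewer than 3 columns at line {ln}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinates at line {ln}") from exc
            if start >= end:
                raise ParseError(f"{path}: start >= end at line {ln}")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = None
            if len(f) > 4 and f[4] != ".":
                try:
                    score = float(f[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: bad score at line {ln}") from exc
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
            out.append(GenomicInterval(f[0], start, end, score=score, name=name, strand=strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """BED writer mirroring :func:`read_bed` field-for-field.

    Scores use 6-decimal fixed point; unset fields become ``.``.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
                cols.append(f"{iv.score:.6f}" if iv.score is not None else ".")
                cols.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(cols) + "\n")


def _mrna_file_order(path) -> dict[str, int]:
    order: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 9 and f[2] == "mRNA":
                for kv in f[8].split(";"):
                    if kv.startswith("ID="):
                        order.setdefault(kv[3:], len(order))
    return order


def read_gene_models(path, biotype_attr: str = "biotype",
                     default_biotype: str = "protein_coding") -> list[GeneModel]:
    """Read gene/mRNA/exon/UTR features from GFF3 into :class:`GeneModel`.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    One representative transcript per gene: the longest mRNA by span,
    ties broken by file order.  ``biotype`` is read from the configurable
    gene attribute ``biotype_attr`` (default vocabulary in BIOTYPES).
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", merge_strategy="create_unique",
                            keep_order=True)
    file_order = _mrna_file_order(path)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if g.strand not in ("+", "-"):
            raise ParseError(f"gene {g.id}: unknown strand {g.strand!r}")
        gstart, gend = g.start - 1, g.end
        mrnas = list(db.children(g.id, featuretype="mRNA"))
        exons: list[tuple[int, int]]
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        if mrnas:
            mrnas.sort(key=lambda m: (-(m.end - m.start + 1), file_order.get(m.id, 1 << 30)))
            rep = mrnas[0]
            exons = sorted((f.start - 1, f.end) for f in db.children(rep.id, featuretype="exon"))
            utr5 = sorted((f.start - 1, f.end)
                          for f in db.children(rep.id, featuretype="five_prime_UTR"))
            utr3 = sorted((f.start - 1, f.end)
                          for f in db.children(rep.id, featuretype="three_prime_UTR"))
            for s, e in exons + utr5 + utr3:
                if s < gstart or e > gend:
                    raise ParseError(f"gene {g.id}: child feature outside parent span")
        else:
            exons = [(gstart, gend)]
        raw = g.attributes.get(biotype_attr, [default_biotype])[0]
        biotype = raw if raw in BIOTYPES else "other_ncrna"
        if raw not in BIOTYPES:
            logger.warning("gene %s: unknown biotype %r mapped to other_ncrna", g.id, raw)
        genes.append(GeneModel(g.id, g.seqid, g.strand, gstart, gend,
                               exons=exons, utr5=utr5, utr3=utr3, biotype=biotype))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive), one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(f"{g.chrom}\tacetylseq\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\tacetylseq\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mid};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tacetylseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.exon{i};Parent={mid}\n")
            for i, (s, e) in enumerate(g.utr5, 1):
                fh.write(f"{g.chrom}\tacetylseq\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.utr5.{i};Parent={mid}\n")
            for i, (s, e) in enumerate(g.utr3, 1):
                fh.write(f"{g.chrom}\tacetylseq\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.utr3.{i};Parent={mid}\n")


_CX_NORMALIZE = {"CG": "CG", "CPG": "CG", "CHG": "CHG", "CHH": "CHH"}


def read_cx_report(path) -> MethylationTable:
    """Read a Bismark-style CX report.

    Columns: chrom, 1-based position, strand, count methylated,
    count unmethylated, context, trinucleotide.  Positions become
    0-based; ``n_total = methylated + unmethylated`` (zero-coverage
    sites are kept and filtered downstream).
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos1", "strand", "n_meth", "n_unmeth", "context", "tri"],
                     dtype={"chrom": str, "pos1": np.int64, "strand": str,
                            "n_meth": np.int64, "n_unmeth": np.int64,
                            "context": str, "tri": str})
    ctx = df["context"].str.upper().map(_CX_NORMALIZE)
    if ctx.isna().any():
        bad = df.loc[ctx.isna(), "context"].iloc[0]
        line = int(df.index[ctx.isna()][0]) + 1
        raise ParseError(f"{path}: unknown context token {bad!r} at line {line}")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        line = int(df.index[(df["n_meth"] < 0) | (df["n_unmeth"] < 0)][0]) + 1
        raise ParseError(f"{path}: negative count at line {line}")
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos1"] - 1,
        "strand": df["strand"],
        "context": ctx,
        "n_meth": df["n_meth"],
        "n_total": df["n_meth"] + df["n_unmeth"],
    })
    return MethylationTable(out)


def write_cx_report(table: MethylationTable, path) -> None:
    df = table.df
    out = pd.DataFrame({
        0: df["chrom"], 1: df["pos"] + 1, 2: df["strand"],
        3: df["n_meth"], 4: df["n_total"] - df["n_meth"],
        5: df["context"], 6: df["context"].map({"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, library_size: float | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Steps may arrive unsorted; they are sorted and validated
    non-overlapping per chromosome (abutting equal-valued steps are
    preserved as given, never merged).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "value": np.float64})
    steps = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        steps[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                        sub["value"].to_numpy())
    try:
        return CoverageTrack(steps, library_size=library_size)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for iv, v in track.steps(chrom):
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{v:.6f}\n")


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV with required header ``gene_id<TAB>fpkm``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "fpkm"]:
        raise ParseError(f"{path}: expected header 'gene_id\\tfpkm'")
    return [ExpressionRecord(str(r.gene_id), float(r.fpkm)) for r in df.itertuples(index=False)]


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fpkm:.6f}\n")


def expression_dict(records: Iterable[ExpressionRecord]) -> dict[str, float]:
    return {r.gene_id: r.fpkm for r in records}
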