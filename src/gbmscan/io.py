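"""Readers and writers for methylation reports, annotations, and matrices.

Interchange formats are plain text: Bismark-style CX reports for
per-cytosine counts, BED6 / minimal GFF3 for gene models, BED for called
regions, and TSV for expression matrices. All internal intervals are
0-based half-open; CX positions are 1-based on disk and converted on
ingest. Readers validate and reject — they never silently repair.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
GENOTYPES = ("wildtype", "met1_like", "ddcc_like", "ddm1_like", "other")
CONDITIONS = ("mock", "BAsub", "mockDC", "BAsubDC", "none")

CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]


class ParseError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


@dataclass
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene span with strand-aware derived features.

    The TSS sits at ``start`` for plus-strand genes and at ``end`` for
    minus-strand genes. Derived intervals (promoter, TSS window, body) are
    computed on demand from configurable widths; see
    :mod:`gbmscan.genecontext` for the conventions.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span for {self.gene_id}")

    @property
    def tss_point(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id)

    def promoter_interval(self, promoter_bp: int = 1000) -> GenomicInterval | None:
        if self.strand == "+":
            start, end = self.tss_point - promoter_bp, self.tss_point
        else:
            start, end = self.tss_point, self.tss_point + promoter_bp
        start = max(start, 0)
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end)

    def tss_interval(self, tss_flank: int = 200) -> GenomicInterval:
        start = max(self.tss_point - tss_flank, 0)
        return GenomicInterval(self.chrom, start, self.tss_point + tss_flank)

    def body_interval(self, tss_flank: int = 200) -> GenomicInterval | None:
        """Gene span minus the TSS window; None if the TSS window covers it."""
        tss = self.tss_interval(tss_flank)
        if self.strand == "+":
            start, end = max(self.start, tss.end), self.end
        else:
            start, end = self.start, min(self.end, tss.start)
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end)


@dataclass
class MethylomeSample:
    """Per-cytosine methylation counts for one sample.

    ``cytosines`` holds columns chrom, pos (0-based after ingest), strand,
    context, n_meth, n_total, sorted by (chrom, pos, strand) and unique on
    that key.
    """

    sample_id: str
    genotype: str = "other"
    condition: str = "none"
    cytosines: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.cytosines) == 0:
            self.cytosines = pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "pos": pd.Series(dtype=np.int64),
                    "strand": pd.Series(dtype=str),
                    "context": pd.Series(dtype=str),
                    "n_meth": pd.Series(dtype=np.int64),
                    "n_total": pd.Series(dtype=np.int64),
                }
            )
            return
        df = self.cytosines
        if (df["n_meth"] > df["n_total"]).any():
            raise ValueError(f"{self.sample_id}: n_meth exceeds n_total")
        if (df["n_meth"] < 0).any():
            raise ValueError(f"{self.sample_id}: negative counts")
        if not df["context"].isin(CONTEXTS).all():
            bad = sorted(set(df["context"]) - set(CONTEXTS))
            raise ValueError(f"{self.sample_id}: unknown contexts {bad}")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
            drop=True
        )
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError(f"{self.sample_id}: duplicate (chrom, pos, strand)")
        self.cytosines = df

    def __len__(self) -> int:
        return len(self.cytosines)

    def mean_level(self, context: str) -> float:
        sub = self.cytosines[self.cytosines["context"] == context]
        tot = int(sub["n_total"].sum())
        return float(sub["n_meth"].sum() / tot) if tot else 0.0


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_cx_report(
    path, sample_id: str | None = None, genotype: str = "other", condition: str = "none"
) -> MethylomeSample:
    """Parse a Bismark-dialect CX report (TSV, 1-based positions).

    Columns: chrom, pos, strand, n_meth, n_unmeth, context. Positions are
    converted to 0-based; n_total = n_meth + n_unmeth.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            chrom, pos, strand, n_meth, n_unmeth, context = parts
            try:
                pos_i, m_i, u_i = int(pos), int(n_meth), int(n_unmeth)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ParseError(f"{path}:{lineno}: bad context {context!r}")
            if m_i < 0 or u_i < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if pos_i < 1:
                raise ParseError(f"{path}:{lineno}: positions are 1-based, got {pos_i}")
            rows.append((chrom, pos_i - 1, strand, context, m_i, m_i + u_i))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"])
    return MethylomeSample(sample_id, genotype, condition, df)


def write_cx_report(sample: MethylomeSample, path) -> None:
    """Write a CX report (inverse of :func:`read_cx_report`)."""
    with _open_text(path, "wt") as fh:
        for row in sample.cytosines.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.n_meth}"
                f"\t{row.n_total - row.n_meth}\t{row.context}\n"
            )


def read_gene_annotation(path) -> list[GeneModel]:
    """Read gene models from BED6 or minimal GFF3 ``gene`` lines."""
    path = Path(path)
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 9:  # GFF3: 1-based inclusive coordinates
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype != "gene":
                    continue
                gene_id = None
                for kv in attrs.split(";"):
                    k, _, v = kv.strip().partition("=")
                    if k == "ID":
                        gene_id = v
                if gene_id is None:
                    raise ParseError(f"{path}:{lineno}: gene line without ID attribute")
                start_i, end_i = int(start) - 1, int(end)
            elif len(parts) >= 6:
                chrom, start, end, gene_id, _score, strand = parts[:6]
                start_i, end_i = int(start), int(end)
            else:
                raise ParseError(f"{path}:{lineno}: expected BED6 or GFF3 fields")
            if start_i >= end_i:
                raise ParseError(f"{path}:{lineno}: start >= end for {gene_id}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            genes.append(GeneModel(gene_id, chrom, strand, start_i, end_i))
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_regions_bed(regions, path, header: str | None = None) -> None:
    """Write classified regions as BED: name = class, extra cols = levels."""
    with _open_text(path, "wt") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.klass}\t"
                f"{r.mean_mcg:.4f}\t{r.mean_mchg:.4f}\t{r.mean_mchh:.4f}\n"
            )


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix (genes x samples) with parsed labels.

    Column headers on disk are ``genotype.condition.replicate``; ``samples``
    holds one row per column with those three fields.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def columns_for(self, genotype: str, condition: str) -> list[str]:
        mask = (self.samples["genotype"] == genotype) & (
            self.samples["condition"] == condition
        )
        return list(self.samples.index[mask])


def parse_sample_labels(columns: Iterable[str]) -> pd.DataFrame:
    recs = []
    for col in columns:
        parts = col.split(".")
        if len(parts) != 3:
            raise ParseError(
                f"column {col!r} is not genotype.condition.replicate"
            )
        recs.append((col, *parts))
    df = pd.DataFrame(recs, columns=["sample", "genotype", "condition", "replicate"])
    return df.set_index("sample")


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r}")
    samples = parse_sample_labels(df.columns)
    return ExpressionMatrix(df.astype(float), samples)


def write_expression_matrix(matrix: ExpressionMatrix, path, header: str | None = None) -> None:
    with _open_text(path, "wt") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")
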