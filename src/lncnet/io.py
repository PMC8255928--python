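"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive throughout (GTF convention);
writers emit UTF-8 with LF line endings so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BIOTYPES = frozenset({"mRNA", "lncRNA_known", "lncRNA_novel", "candidate"})
GROUPS = frozenset({"control", "case"})
UNITS = frozenset({"count", "FPKM", "log2FPKM"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: genomic span, biotype and (exonic) length.

    ``start``/``end`` are the transcript span; ``exons`` holds the
    individual exon intervals when known (single-exon span otherwise).
    ``length`` is the summed exonic length in nt.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "candidate"
    length: int = 0
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.transcript_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        if self.length == 0:
            object.__setattr__(
                self, "length", sum(e - s + 1 for s, e in self.exons)
            )
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: non-positive length")

    def span_interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class GeneSet:
    """One annotation term (GO/KEGG-style) and its member genes."""

    term_id: str
    term_name: str
    member_gene_ids: frozenset[str]

    def __post_init__(self):
        if not self.member_gene_ids:
            raise ValueError(f"{self.term_id}: empty member set")


class ExpressionMatrix:
    """Gene x sample abundance grid with per-sample group labels.

    Thin wrapper over a pandas DataFrame (rows = genes, columns = samples)
    that validates non-negativity for count/FPKM units and keeps the
    control/case assignment alongside the values.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        group_labels: Mapping[str, str],
        unit: str = "FPKM",
    ):
        if unit not in UNITS:
            raise ValueError(f"unknown unit {unit!r}")
        if values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        if unit in ("count", "FPKM") and (values.to_numpy() < 0).any():
            raise FormatError(f"negative values not allowed for unit {unit}")
        missing = [s for s in values.columns if s not in group_labels]
        if missing:
            raise FormatError(f"samples without group label: {missing}")
        bad = {s: g for s, g in group_labels.items() if g not in GROUPS}
        if bad:
            raise FormatError(f"group labels must be control/case, got {bad}")
        self.values = values.astype(float)
        self.group_labels = {s: group_labels[s] for s in values.columns}
        self.unit = unit

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == group]

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform used for QC, correlation and testing."""
        if self.unit == "log2FPKM":
            return self.values
        return np.log2(self.values + 1.0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.group_labels, self.unit
        )


# ---------------------------------------------------------------------------
# GTF

_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(text: str) -> dict[str, str]:
    # tolerate both `key "value";` and `key=value` dialects
    attrs = dict(_ATTR_QUOTED.findall(text))
    if not attrs:
        attrs = {k: v.strip().strip('"') for k, v in _ATTR_EQ.findall(text)}
    return attrs


def parse_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse a 9-column GTF into transcript records.

    Exon lines belonging to one transcript are aggregated into a single
    record whose span covers all exons and whose length is the summed
    exonic length. Transcript-level feature lines, when present, supply
    gene_id/biotype but exon lines alone suffice.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            attrs = _parse_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(f"line {lineno}: missing transcript_id attribute")
            start_i, end_i = int(start), int(end)
            rec = per_tx.get(tid)
            if rec is None:
                rec = per_tx[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("biotype", attrs.get("gene_biotype", "candidate")),
                    "exons": [],
                    "span": None,
                }
                order.append(tid)
            if feature == "exon":
                rec["exons"].append((start_i, end_i))
            elif feature == "transcript":
                rec["span"] = (start_i, end_i)
            if "biotype" in attrs:
                rec["biotype"] = attrs["biotype"]
    records = []
    for tid in order:
        rec = per_tx[tid]
        exons = sorted(rec["exons"]) or ([rec["span"]] if rec["span"] else [])
        if not exons:
            raise FormatError(f"transcript {tid}: no exon or transcript feature")
        span = rec["span"] or (exons[0][0], exons[-1][1])
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                start=min(span[0], exons[0][0]),
                end=max(span[1], exons[-1][1]),
                strand=rec["strand"],
                biotype=rec["biotype"] if rec["biotype"] in BIOTYPES else "candidate",
                exons=tuple(exons),
            )
        )
    return records


def write_gtf(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            attrs = (
                f'transcript_id "{r.transcript_id}"; gene_id "{r.gene_id}"; '
                f'biotype "{r.biotype}";'
            )
            fh.write(
                f"{r.chrom}\tlncnet\ttranscript\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
            for s, e in r.exons:
                fh.write(
                    f"{r.chrom}\tlncnet\texon\t{s}\t{e}\t.\t{r.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA to {id: sequence}; uppercases and normalizes U->T.

    The id is the first whitespace token of the header. Duplicate ids are
    an error.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Expression TSV

def read_expression(
    path: str | Path, group_map: Mapping[str, str], unit: str = "FPKM"
) -> ExpressionMatrix:
    """Read a rectangular TSV (rows = genes, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError("expression table contains NA cells (no imputation)")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression body: {exc}") from None
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise FormatError(f"samples missing from group map: {missing}")
    return ExpressionMatrix(df, group_map, unit=unit)


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    buf = _io.StringIO()
    mat.values.to_csv(buf, sep="\t", lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, group) -> {sample: group}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s, g in group_map.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# GMT / clinical

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"GMT line {lineno}: empty member list")
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.member_gene_ids))
            fh.write(f"{gs.term_id}\t{gs.term_name}\t{members}\n")


CLINICAL_COLUMNS = [
    "patient",
    "esr",
    "hscrp",
    "osteocalcin",
    "vas",
    "wbc",
    "neutrophil",
]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-patient clinical table (ESR, hsCRP, osteocalcin, VAS,
    white blood cell count, neutrophil count)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing columns: {missing}")
    return df[CLINICAL_COLUMNS]


__all__ = [
    "BIOTYPES",
    "CLINICAL_COLUMNS",
    "ExpressionMatrix",
    "FormatError",
    "GeneSet",
    "TranscriptRecord",
    "parse_fasta",
    "parse_gtf",
    "read_clinical",
    "read_expression",
    "read_gmt",
    "read_group_map",
    "replace",
    "write_expression",
    "write_fasta",
    "write_gmt",
    "write_group_map",
    "write_gtf",
]
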