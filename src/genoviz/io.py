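"""Readers and writers for the standard text formats.

Supported formats: BED (0-based half-open; converted to the internal
1-based closed dialect on read), GFF3 and GTF (1-based closed; the
``Parent`` / ``transcript_id`` attribute becomes the ``tx_id`` grouping
column), SAM text alignments (CIGAR projected to reference blocks),
FASTA via Biopython, and three TSV dialects (chromosome sizes, links,
per-position scores).

Readers reject malformed records rather than coercing them, and error
messages carry the offending line number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .ranges import GenomicRange, RangeTable, SeqInfo, make_range_table

__all__ = [
    "AlignmentTable",
    "ReadAlignment",
    "read_features",
    "write_features",
    "read_fasta",
    "read_sam",
    "cigar_reference_blocks",
    "read_table",
]


def _err(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# CIGAR projection


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_reference_blocks(pos: int, cigar: str) -> list[tuple[int, int, int]]:
    """Project a CIGAR string to reference blocks.

    Returns (ref_start, ref_end, query_offset) triples, one per M/=/X run.
    M/=/X consume query and reference; D and N consume reference only and
    split blocks; I and S consume query only (I also splits blocks); H and
    P consume neither.  Blocks are disjoint and ascending, and the sum of
    block widths equals the sum of M/=/X lengths.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if not cigar or cigar == "*":
        raise ValueError("empty CIGAR")
    consumed = 0
    blocks: list[tuple[int, int, int]] = []
    ref = pos
    q = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != consumed:
            raise ValueError(f"invalid CIGAR {cigar!r}")
        consumed = m.end()
        n, op = int(m.group(1)), m.group(2)
        if n == 0:
            raise ValueError(f"zero-length CIGAR op in {cigar!r}")
        if op in "M=X":
            blocks.append((ref, ref + n - 1, q))
            ref += n
            q += n
        elif op in "DN":
            ref += n
        elif op in "IS":
            q += n
        # H and P consume nothing
    if consumed != len(cigar):
        raise ValueError(f"invalid CIGAR {cigar!r}")
    return blocks


# ---------------------------------------------------------------------------
# SAM


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read with its CIGAR projected to reference blocks."""

    qname: str
    flag: int
    seqname: str
    pos: int
    cigar: str
    seq: str
    blocks: tuple[tuple[int, int, int], ...]  # (ref_start, ref_end, query_offset)

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def block_sequences(self) -> list[tuple[int, int, str]]:
        """(ref_start, ref_end, query substring) per aligned block."""
        out = []
        for s, e, qoff in self.blocks:
            sub = self.seq[qoff : qoff + (e - s + 1)]
            out.append((s, e, sub))
        return out


class AlignmentTable:
    """An ordered collection of :class:`ReadAlignment` rows."""

    def __init__(self, reads: Sequence[ReadAlignment]):
        self.reads = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[ReadAlignment]:
        return iter(self.reads)

    @property
    def seqnames(self) -> list[str]:
        seen: list[str] = []
        for r in self.reads:
            if r.seqname not in seen:
                seen.append(r.seqname)
        return seen

    def blocks_table(self, group_by_read: bool = True) -> RangeTable:
        """Reference blocks as a RangeTable (grouped by read name).

        The grouped form feeds the alignment geom (spliced reads drawn as
        connected blocks); the flat form feeds coverage.
        """
        records = []
        meta_qname = []
        for r in self.reads:
            for s, e, _ in r.blocks:
                records.append((r.seqname, s, e, "*"))
                meta_qname.append(r.qname)
        table = make_range_table(records, metadata={"qname": meta_qname})
        if group_by_read:
            table = table.with_group_key("qname")
        return table


def read_sam(path, region: GenomicRange | None = None) -> AlignmentTable:
    """Read SAM text alignments (header optional, no index needed).

    Unmapped reads (flag 0x4 or missing RNAME/POS) are skipped.  With a
    ``region``, only reads whose reference span overlaps it are kept.
    """
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise _err(path, lineno, f"expected 11 SAM columns, got {len(fields)}")
            qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
            seq = fields[9]
            try:
                flag = int(flag_s)
            except ValueError:
                raise _err(path, lineno, f"non-integer FLAG {flag_s!r}") from None
            if flag & 0x4 or rname == "*":
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise _err(path, lineno, f"non-integer POS {pos_s!r}") from None
            if pos < 1:
                raise _err(path, lineno, f"POS must be >= 1, got {pos}")
            try:
                blocks = cigar_reference_blocks(pos, cigar)
            except ValueError as e:
                raise _err(path, lineno, str(e)) from None
            read = ReadAlignment(
                qname=qname, flag=flag, seqname=rname, pos=pos,
                cigar=cigar, seq=seq, blocks=tuple(blocks),
            )
            if region is not None:
                lo, hi = read.ref_span
                if read.seqname != region.seqname or lo > region.end or hi < region.start:
                    continue
            reads.append(read)
    return AlignmentTable(reads)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: sequence}; sequences upper-cased.

    The name is the first whitespace-delimited token of the header.
    Duplicate names and empty files are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# BED / GFF3 / GTF


def _parse_bed(path) -> RangeTable:
    records = []
    names: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise _err(path, lineno, "BED line needs at least 3 fields")
            seq = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise _err(path, lineno, "non-integer BED coordinates") from None
            if start < 0 or start >= end:
                raise _err(path, lineno, f"invalid BED interval [{start},{end})")
            name = fields[3] if len(fields) > 3 else f"feat{len(records) + 1}"
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise _err(path, lineno, f"non-numeric BED score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            if strand == ".":
                strand = "*"
            if strand not in ("+", "-", "*"):
                raise _err(path, lineno, f"invalid strand {strand!r}")
            records.append((seq, start, end, strand))
            names.append(name)
            scores.append(score)
    return make_range_table(
        records, dialect="zero_half_open",
        metadata={"name": names, "score": scores},
    )


_GFF3_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")
_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_gff_like(path, fmt: str) -> RangeTable:
    records = []
    tx_ids: list[str | None] = []
    types: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise _err(path, lineno, f"expected 9 {fmt.upper()} columns, got {len(fields)}")
            seq, _src, ftype, start_s, end_s, score_s, strand, _phase, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise _err(path, lineno, "non-integer coordinates") from None
            if start < 1 or start > end:
                raise _err(path, lineno, f"invalid interval [{start},{end}]")
            if strand == ".":
                strand = "*"
            if strand not in ("+", "-", "*"):
                raise _err(path, lineno, f"invalid strand {strand!r}")
            try:
                score = float(score_s) if score_s != "." else 0.0
            except ValueError:
                raise _err(path, lineno, f"non-numeric score {score_s!r}") from None
            if fmt == "gff3":
                attr = dict(_GFF3_ATTR_RE.findall(attrs))
                tx = attr.get("Parent")
            else:
                attr = dict(_GTF_ATTR_RE.findall(attrs))
                tx = attr.get("transcript_id")
            records.append((seq, start, end, strand))
            tx_ids.append(tx)
            types.append(ftype)
            scores.append(score)
    table = make_range_table(
        records,
        metadata={"tx_id": tx_ids, "type": types, "score": scores},
    )
    if any(t is not None for t in tx_ids):
        table = table.with_group_key("tx_id")
    return table


def read_features(path, format: str) -> RangeTable:
    """Read genomic features from BED, GFF3 or GTF into a RangeTable.

    BED coordinates are converted from 0-based half-open to the internal
    1-based closed dialect.  GFF3 ``Parent`` and GTF ``transcript_id``
    attributes are both normalised to a ``tx_id`` grouping column.
    """
    if format == "bed":
        return _parse_bed(path)
    if format in ("gff3", "gtf"):
        return _parse_gff_like(path, format)
    raise ValueError(f"unknown format {format!r}; expected bed, gff3 or gtf")


def write_features(table: RangeTable, path, format: str = "bed") -> None:
    """Write a RangeTable to BED (6 columns, 0-based half-open)."""
    if format != "bed":
        raise ValueError(f"only BED output is supported, got {format!r}")
    df = table.df
    names = df["name"] if "name" in df.columns else [
        f"feat{i + 1}" for i in range(len(df))
    ]
    scores = df["score"] if "score" in df.columns else [0] * len(df)
    with open(path, "w") as fh:
        for (seq, s, e, st), name, score in zip(
            zip(df["seqname"], df["start"], df["end"], df["strand"]), names, scores
        ):
            strand = "." if st == "*" else st
            fh.write(f"{seq}\t{s - 1}\t{e}\t{name}\t{score:g}\t{strand}\n")


# ---------------------------------------------------------------------------
# TSV dialects


_TABLE_COLUMNS = {
    "links": ["chr1", "pos1", "chr2", "pos2", "score", "support"],
    "scores": ["chr", "pos", "value"],
}


def read_table(path, kind: str):
    """Read one of the TSV dialects: ``links``, ``scores``, ``chromsizes``.

    chromsizes is headerless (name, length) and yields a SeqInfo preserving
    file order.  links and scores carry a header row; links gain a boolean
    ``inter`` column flagging inter-chromosomal pairs.
    """
    if kind == "chromsizes":
        pairs: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise _err(path, lineno, "chromsizes needs 2 tab-separated fields")
                try:
                    length = int(fields[1])
                except ValueError:
                    raise _err(path, lineno, f"non-integer length {fields[1]!r}") from None
                if length < 1:
                    raise _err(path, lineno, f"length must be >= 1, got {length}")
                pairs.append((fields[0], length))
        if not pairs:
            raise ValueError(f"{path}: empty chromsizes file")
        return SeqInfo(tuple(pairs))
    if kind not in _TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t")
    required = _TABLE_COLUMNS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if kind == "links":
        for col in ("pos1", "pos2", "score", "support"):
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValueError(f"{path}: non-numeric column {col!r}")
        if (df["pos1"] < 1).any() or (df["pos2"] < 1).any():
            raise ValueError(f"{path}: positions must be >= 1")
        df = df.copy()
        df["inter"] = df["chr1"].astype(str) != df["chr2"].astype(str)
        return df
    # scores
    for col in ("pos", "value"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric column {col!r}")
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be >= 1")
    return df
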