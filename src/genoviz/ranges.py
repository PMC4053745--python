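"""Data model for genomic intervals.

The universal currency of the package is the :class:`RangeTable`: a table of
genomic intervals (seqname, start, end, strand) plus arbitrary metadata
columns and an optional grouping column (e.g. ``tx_id`` for the exons of a
transcript).  Internally all coordinates are **1-based, closed** intervals
(the Bioconductor convention); the 0-based half-open dialect used by BED is
converted at I/O boundaries via :func:`convert_dialect`.

Interval algebra provided here — :func:`reduce_ranges` (union),
:func:`gaps_within_groups` (per-group complement, i.e. introns between
exons) and :func:`range_hull` — underpins the stepping statistic, the
gap-truncation coordinate transform and the alignment geom.

Strand is one of ``+``, ``-``, ``*`` (unstranded) and never affects interval
algebra; it only feeds aesthetics (e.g. colour in gene-model plots).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", "*")
DIALECTS = ("one_closed", "zero_half_open")
CORE_COLUMNS = ("seqname", "start", "end", "strand")

__all__ = [
    "STRANDS",
    "DIALECTS",
    "SeqInfo",
    "GenomicRange",
    "RangeTable",
    "make_range_table",
    "convert_dialect",
    "gaps_within_groups",
    "reduce_ranges",
    "range_hull",
]


@dataclass(frozen=True)
class SeqInfo:
    """Ordered set of (seqname, length) pairs.

    The order is significant: it defines the concatenation order of the
    genome coordinate map and the panel order of every layout.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("SeqInfo seqnames must be unique")
        for name, length in self.entries:
            if not name:
                raise ValueError("SeqInfo seqname must be nonempty")
            if int(length) < 1:
                raise ValueError(f"SeqInfo length for {name!r} must be >= 1, got {length}")
        object.__setattr__(
            self, "entries", tuple((str(n), int(l)) for n, l in self.entries)
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "SeqInfo":
        return cls(tuple(pairs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def length(self, seqname: str) -> int:
        try:
            return self.lengths[seqname]
        except KeyError:
            raise KeyError(f"unknown seqname {seqname!r}") from None

    def index(self, seqname: str) -> int:
        return self.names.index(seqname)

    def __contains__(self, seqname: str) -> bool:
        return seqname in self.lengths

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GenomicRange:
    """A single 1-based closed genomic interval."""

    seqname: str
    start: int
    end: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if not self.seqname:
            raise ValueError("seqname must be nonempty")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"require 1 <= start <= end, got [{self.start}, {self.end}]"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicRange") -> bool:
        return (
            self.seqname == other.seqname
            and self.start <= other.end
            and self.end >= other.start
        )


class RangeTable:
    """A validated table of genomic intervals with metadata columns.

    Parameters
    ----------
    df:
        DataFrame with at least the core columns ``seqname``, ``start``,
        ``end``, ``strand``; any further columns are metadata.
    group_key:
        Optional name of a metadata column that groups rows into units
        (e.g. ``tx_id`` grouping exons into transcripts).
    seqinfo:
        Optional :class:`SeqInfo`; when given, every row must fit within
        its chromosome and ``end <= length(seqname)`` is enforced.
    dialect:
        Coordinate dialect of ``df``.  Everything in the package operates
        on ``one_closed`` tables; ``zero_half_open`` tables exist only as
        transient I/O values produced by :func:`convert_dialect`.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        group_key: str | None = None,
        seqinfo: SeqInfo | None = None,
        dialect: str = "one_closed",
        copy: bool = True,
        validate: bool = True,
    ) -> None:
        if dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"RangeTable missing core columns: {missing}")
        df = df.copy() if copy else df
        df = df.reset_index(drop=True)
        df["seqname"] = df["seqname"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["strand"] = df["strand"].astype(str)
        self._df = df
        self.group_key = group_key
        self.seqinfo = seqinfo
        self.dialect = dialect
        if validate:
            self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        df = self._df
        if (df["seqname"] == "").any():
            raise ValueError("seqname must be nonempty")
        bad_strand = set(df["strand"]) - set(STRANDS)
        if bad_strand:
            raise ValueError(f"invalid strand value(s): {sorted(bad_strand)}")
        if self.dialect == "one_closed":
            bad = df.index[(df["start"] < 1) | (df["start"] > df["end"])]
            if len(bad):
                i = int(bad[0])
                raise ValueError(
                    f"row {i}: require 1 <= start <= end, got "
                    f"[{df.at[i, 'start']}, {df.at[i, 'end']}]"
                )
        else:  # zero_half_open
            bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
            if len(bad):
                i = int(bad[0])
                raise ValueError(
                    f"row {i}: require 0 <= start < end in zero_half_open dialect"
                )
        if self.group_key is not None and self.group_key not in df.columns:
            raise ValueError(f"group_key {self.group_key!r} is not a column")
        if self.seqinfo is not None and self.dialect == "one_closed":
            lengths = self.seqinfo.lengths
            for i, (seq, end) in enumerate(zip(df["seqname"], df["end"])):
                if seq not in lengths:
                    raise ValueError(f"row {i}: seqname {seq!r} not in SeqInfo")
                if end > lengths[seq]:
                    raise ValueError(
                        f"row {i}: end {end} exceeds length of {seq!r} ({lengths[seq]})"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def seqnames(self) -> np.ndarray:
        return self._df["seqname"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self._df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self._df["end"].to_numpy()

    @property
    def strands(self) -> np.ndarray:
        return self._df["strand"].to_numpy()

    @property
    def widths(self) -> np.ndarray:
        if self.dialect == "zero_half_open":
            return self.ends - self.starts
        return self.ends - self.starts + 1

    @property
    def metadata_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self._df.columns if c not in CORE_COLUMNS)

    def column(self, name: str) -> np.ndarray:
        if name not in self._df.columns:
            raise KeyError(f"no column {name!r}")
        return self._df[name].to_numpy()

    def with_column(self, name: str, values: Sequence[Any]) -> "RangeTable":
        if len(values) != len(self):
            raise ValueError("column length must match row count")
        df = self._df.copy()
        df[name] = list(values)
        return RangeTable(
            df, group_key=self.group_key, seqinfo=self.seqinfo,
            dialect=self.dialect, copy=False, validate=False,
        )

    def with_group_key(self, key: str) -> "RangeTable":
        return RangeTable(
            self._df, group_key=key, seqinfo=self.seqinfo, dialect=self.dialect
        )

    def subset(self, mask) -> "RangeTable":
        return RangeTable(
            self._df[mask].reset_index(drop=True),
            group_key=self.group_key, seqinfo=self.seqinfo,
            dialect=self.dialect, copy=False, validate=False,
        )

    def groups(self) -> Iterator[tuple[Any, pd.DataFrame]]:
        """Iterate (group id, sub-frame) in order of first appearance."""
        if self.group_key is None:
            raise ValueError("RangeTable has no group_key")
        for gid, sub in self._df.groupby(self.group_key, sort=False):
            yield gid, sub

    def rows(self) -> Iterator[GenomicRange]:
        for seq, s, e, st in zip(self.seqnames, self.starts, self.ends, self.strands):
            yield GenomicRange(seq, int(s), int(e), st)

    def hull_interval(self) -> GenomicRange:
        """Overall hull; requires a single seqname."""
        return _hull_of(self._df, scope="table")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = f", group_key={self.group_key!r}" if self.group_key else ""
        return f"RangeTable({len(self)} rows{g}, dialect={self.dialect!r})"


# ---------------------------------------------------------------------------
# constructors and dialect conversion


def make_range_table(
    records: Iterable[Sequence | Mapping],
    dialect: str = "one_closed",
    metadata: Mapping[str, Sequence] | None = None,
    group_key: str | None = None,
    seqinfo: SeqInfo | None = None,
) -> RangeTable:
    """Build a validated RangeTable (internal 1-based closed dialect).

    ``records`` may be tuples ``(seqname, start, end[, strand])`` or mappings
    with those keys plus arbitrary metadata.  ``dialect`` names the dialect
    the raw coordinates are expressed in; the result is always converted to
    the internal ``one_closed`` dialect.  Input order is preserved.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    seqs: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    extra: dict[str, list] = {}
    for i, rec in enumerate(records):
        if isinstance(rec, Mapping):
            try:
                seqs.append(str(rec["seqname"]))
                starts.append(int(rec["start"]))
                ends.append(int(rec["end"]))
            except KeyError as e:
                raise ValueError(f"record {i} missing field {e}") from None
            strands.append(str(rec.get("strand", "*")))
            for k, v in rec.items():
                if k in CORE_COLUMNS:
                    continue
                extra.setdefault(k, [None] * i).append(v)
            for k in extra:
                if len(extra[k]) < i + 1:
                    extra[k].append(None)
        else:
            if len(rec) < 3:
                raise ValueError(f"record {i} must have at least (seqname, start, end)")
            seqs.append(str(rec[0]))
            starts.append(int(rec[1]))
            ends.append(int(rec[2]))
            strands.append(str(rec[3]) if len(rec) > 3 else "*")
    df = pd.DataFrame(
        {"seqname": seqs, "start": starts, "end": ends, "strand": strands}
    )
    for k, v in extra.items():
        df[k] = v
    if metadata is not None:
        for k, v in metadata.items():
            if len(v) != len(df):
                raise ValueError(f"metadata column {k!r} has wrong length")
            df[k] = list(v)
    if dialect == "zero_half_open":
        df["start"] = df["start"] + 1  # end stays: closed end == half-open end
    return RangeTable(df, group_key=group_key, seqinfo=seqinfo, copy=False)


def convert_dialect(table: RangeTable, from_dialect: str, to_dialect: str) -> RangeTable:
    """Convert between 1-based closed and 0-based half-open coordinates.

    Widths are preserved and the round trip from→to→from is the identity.
    """
    for d in (from_dialect, to_dialect):
        if d not in DIALECTS:
            raise ValueError(f"unknown dialect {d!r}; expected one of {DIALECTS}")
    if from_dialect != table.dialect:
        raise ValueError(
            f"table is in dialect {table.dialect!r}, not {from_dialect!r}"
        )
    if from_dialect == to_dialect:
        return RangeTable(
            table.df, group_key=table.group_key, seqinfo=table.seqinfo,
            dialect=table.dialect,
        )
    df = table.df.copy()
    if to_dialect == "zero_half_open":
        df["start"] = df["start"] - 1
    else:
        df["start"] = df["start"] + 1
    return RangeTable(
        df, group_key=table.group_key, seqinfo=table.seqinfo,
        dialect=to_dialect, copy=False,
    )


# ---------------------------------------------------------------------------
# interval algebra


def _require_internal(table: RangeTable, op: str) -> None:
    if table.dialect != "one_closed":
        raise ValueError(f"{op} requires the internal one_closed dialect")


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Union of closed integer intervals; abutting intervals merge."""
    order = np.argsort(starts, kind="stable")
    merged: list[list[int]] = []
    for i in order:
        s, e = int(starts[i]), int(ends[i])
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _hull_of(df: pd.DataFrame, scope: str) -> GenomicRange:
    seqs = df["seqname"].unique()
    if len(seqs) != 1:
        raise ValueError(f"hull over mixed seqnames in one {scope}: {sorted(seqs)}")
    strands = df["strand"].unique()
    strand = strands[0] if len(strands) == 1 else "*"
    return GenomicRange(
        str(seqs[0]), int(df["start"].min()), int(df["end"].max()), strand
    )


def gaps_within_groups(table: RangeTable) -> RangeTable:
    """Per-group complement of the interval union within the group hull.

    For exons grouped by transcript id this yields the introns.  Each output
    row carries its group id; gaps are sorted by start within each group and
    groups appear in order of first appearance.  Abutting members produce no
    zero-width gap.  A group whose members do not share one seqname is an
    error.
    """
    _require_internal(table, "gaps_within_groups")
    if table.group_key is None:
        raise ValueError("gaps_within_groups requires a grouped RangeTable")
    key = table.group_key
    out: dict[str, list] = {c: [] for c in ("seqname", "start", "end", "strand", key)}
    for gid, sub in table.groups():
        seqs = sub["seqname"].unique()
        if len(seqs) != 1:
            raise ValueError(
                f"group {gid!r} spans multiple seqnames: {sorted(seqs)}"
            )
        strands = sub["strand"].unique()
        strand = strands[0] if len(strands) == 1 else "*"
        merged = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        for (s1, e1), (s2, _) in zip(merged, merged[1:]):
            out["seqname"].append(str(seqs[0]))
            out["start"].append(e1 + 1)
            out["end"].append(s2 - 1)
            out["strand"].append(strand)
            out[key].append(gid)
    return RangeTable(pd.DataFrame(out, columns=list(out)), group_key=key,
                      seqinfo=table.seqinfo, copy=False)


def reduce_ranges(table: RangeTable) -> RangeTable:
    """Minimal disjoint set of intervals with the same union as the input.

    Abutting intervals merge ([1,5],[6,9] → [1,9]).  Output is sorted by
    (seqname, start) — in SeqInfo order when a SeqInfo is attached, else
    lexicographically.  Metadata and grouping are dropped.  Idempotent and
    invariant to input order.
    """
    _require_internal(table, "reduce_ranges")
    df = table.df
    if len(df) == 0:
        empty = pd.DataFrame({c: [] for c in CORE_COLUMNS})
        return RangeTable(empty, seqinfo=table.seqinfo, copy=False)
    seq_order = sorted(df["seqname"].unique())
    if table.seqinfo is not None:
        known = [s for s in table.seqinfo.names if s in set(seq_order)]
        seq_order = known + [s for s in seq_order if s not in set(known)]
    out: dict[str, list] = {c: [] for c in CORE_COLUMNS}
    for seq in seq_order:
        sub = df[df["seqname"] == seq]
        for s, e in _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy()):
            out["seqname"].append(seq)
            out["start"].append(s)
            out["end"].append(e)
            out["strand"].append("*")
    return RangeTable(pd.DataFrame(out), seqinfo=table.seqinfo, copy=False)


def range_hull(table: RangeTable, per_group: bool = False) -> RangeTable:
    """[min start, max end] per group (or for the whole table).

    All rows in the scope of one hull must share a seqname.
    """
    _require_internal(table, "range_hull")
    if per_group:
        if table.group_key is None:
            raise ValueError("per_group hull requires a grouped RangeTable")
        key = table.group_key
        out: dict[str, list] = {
            c: [] for c in ("seqname", "start", "end", "strand", key)
        }
        for gid, sub in table.groups():
            h = _hull_of(sub, scope="group")
            out["seqname"].append(h.seqname)
            out["start"].append(h.start)
            out["end"].append(h.end)
            out["strand"].append(h.strand)
            out[key].append(gid)
        return RangeTable(pd.DataFrame(out, columns=list(out)), group_key=key,
                          seqinfo=table.seqinfo, copy=False)
    if len(table) == 0:
        raise ValueError("hull of an empty table")
    h = _hull_of(table.df, scope="table")
    df = pd.DataFrame(
        {"seqname": [h.seqname], "start": [h.start], "end": [h.end],
         "strand": [h.strand]}
    )
    return RangeTable(df, seqinfo=table.seqinfo, copy=False)
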