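"""Shared coordinate model and typed readers/writers for PAF, BED/GFF3 and TSV reports.

All coordinates are 0-based half-open internally (the PAF convention).
GFF3 (1-based inclusive) is converted at the boundary on read.  Minus-strand
alignment records keep their query interval in forward-strand coordinates,
again following PAF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

STRANDS = ("+", "-", ".")


class PafParseError(ValueError):
    """Raised when a PAF line cannot be parsed; carries the 1-based line number."""


class FormatError(ValueError):
    """Raised for unrecognized or inconsistent feature-file dialects."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval.

    ``start < end`` is enforced; ``strand`` is one of ``+``, ``-`` or ``.``
    (unstranded).
    """

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(
                f"negative coordinate in {self.seq_name}:{self.start}-{self.end}"
            )
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.seq_name}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Interval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF alignment: query and target intervals plus match statistics.

    ``identity`` is defined as col 10 / col 11 (residue matches over alignment
    block length, gap-inclusive), which is dialect-independent because both
    columns are mandatory.
    """

    query: Interval
    target: Interval
    n_matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if self.block_len <= 0:
            raise ValueError("block_len must be positive")
        if self.n_matches > self.block_len:
            raise ValueError("n_matches exceeds block_len")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside 0-255")

    @property
    def identity(self) -> float:
        return self.n_matches / self.block_len

    @property
    def strand(self) -> str:
        return self.query.strand


@dataclass(frozen=True)
class AlignmentFilter:
    """Alignment retention thresholds (length in bp, identity as a fraction).

    ``min_mapq`` is optional; ``None`` disables the mapping-quality floor.
    """

    min_block_len: int = 0
    min_identity: float = 0.0
    min_mapq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_block_len < 0 or self.min_identity < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_identity > 1:
            raise ValueError("min_identity must be <= 1")
        if self.min_mapq is not None and self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def passes(self, rec: AlignmentRecord) -> bool:
        if rec.block_len <= self.min_block_len and self.min_block_len > 0:
            return False
        if rec.identity <= self.min_identity and self.min_identity > 0:
            return False
        if self.min_mapq is not None and rec.mapq <= self.min_mapq:
            return False
        return True


#: pass-everything filter, convenient for round-trip IO
PASS_ALL = AlignmentFilter()


def _parse_paf_line(line: str, lineno: int) -> AlignmentRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise PafParseError(f"line {lineno}: expected >=12 PAF columns, got {len(cols)}")
    try:
        qname, qlen, qstart, qend = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
        strand = cols[4]
        tname, tlen, tstart, tend = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
        n_matches, block_len, mapq = int(cols[9]), int(cols[10]), int(cols[11])
    except ValueError as exc:
        raise PafParseError(f"line {lineno}: {exc}") from None
    if min(qstart, qend, tstart, tend, qlen, tlen) < 0:
        raise PafParseError(f"line {lineno}: negative coordinate")
    if strand not in ("+", "-"):
        raise PafParseError(f"line {lineno}: bad strand {strand!r}")
    try:
        return AlignmentRecord(
            query=Interval(qname, qstart, qend, strand),
            target=Interval(tname, tstart, tend, "+"),
            n_matches=n_matches,
            block_len=block_len,
            mapq=mapq,
        )
    except ValueError as exc:
        raise PafParseError(f"line {lineno}: {exc}") from None


def read_paf(path: str, filter: AlignmentFilter = PASS_ALL) -> list[AlignmentRecord]:
    """Read a PAF file, retaining only records that pass ``filter``.

    Records preserve input order.  Malformed lines raise :class:`PafParseError`
    naming the offending line number.
    """
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = _parse_paf_line(line, lineno)
            if filter.passes(rec):
                out.append(rec)
    return out


def write_paf(
    records: Iterable[AlignmentRecord],
    path: str,
    seq_lens: Optional[dict[str, int]] = None,
) -> None:
    """Write records as minimal 12-column PAF.

    Sequence lengths (PAF cols 2 and 7) come from ``seq_lens`` when provided,
    otherwise from the interval end coordinate (a valid lower bound).
    """
    seq_lens = seq_lens or {}
    with open(path, "w") as fh:
        for r in records:
            qlen = seq_lens.get(r.query.seq_name, r.query.end)
            tlen = seq_lens.get(r.target.seq_name, r.target.end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query.seq_name, qlen, r.query.start, r.query.end,
                        r.query.strand,
                        r.target.seq_name, tlen, r.target.start, r.target.end,
                        r.n_matches, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


def read_features(path: str, gff_types: Sequence[str] = ("gene",)) -> list[Interval]:
    """Read gene features from BED (0-based half-open) or GFF3 (1-based inclusive).

    The dialect is chosen by extension (.bed vs .gff/.gff3); GFF3 coordinates
    are converted so every returned interval uses the internal 0-based
    half-open convention.  For GFF3 only rows whose type is in ``gff_types``
    are returned; BED returns every row.
    """
    ext = os.path.splitext(path)[1].lower()
    feats: list[Interval] = []
    if ext == ".bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise FormatError(f"{path} line {lineno}: BED needs >=3 columns")
                strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
                feats.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
    elif ext in (".gff", ".gff3"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise FormatError(f"{path} line {lineno}: GFF3 needs 9 columns")
                if cols[2] not in gff_types:
                    continue
                strand = cols[6] if cols[6] in ("+", "-") else "."
                # GFF3 is 1-based inclusive: [start, end] -> [start-1, end)
                feats.append(Interval(cols[0], int(cols[3]) - 1, int(cols[4]), strand))
    else:
        raise FormatError(f"unknown feature-file extension {ext!r} for {path}")
    return feats


def write_report(table: pd.DataFrame, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write a result table as TSV: header row, floats at 4 decimals, stable order.

    ``header_lines`` are emitted first as ``#``-prefixed comments (used by the
    CLI to embed version and parameters).
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.4f", lineterminator="\n")


def read_report(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of bases covered by a set of (start, end) half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_s: Optional[int] = None
    cur_e = 0
    for s, e in ivs:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total
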