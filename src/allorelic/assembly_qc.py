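"""Assembly QC directly from FASTA: contig gaps (N-runs) and telomere repeats.

Scaffolded assemblies mark contig joins with runs of N; the edges of those
runs are the "contig breakpoints" used downstream to flag inversion calls
that may be contig mis-orientations.  Telomeres are located by counting
exact non-overlapping copies of the plant telomeric motif (TTTAGGG)n in
each scaffold's terminal windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Union

import pandas as pd
from pyfaidx import Fasta

from .io_core import Interval

SequenceSet = Mapping[str, str]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_sequences(fasta: Union[str, SequenceSet]) -> dict[str, str]:
    if isinstance(fasta, (str, bytes)):
        fa = Fasta(str(fasta), rebuild=True, build_index=True)
        return {name: str(fa[name][:]) for name in fa.keys()}
    return dict(fasta)


@dataclass
class ContigMap:
    """Per-scaffold record of N-run gaps and the contig breakpoints they imply.

    Breakpoints are the start and end positions of each gap; scaffold termini
    are not breakpoints (the rule concerns joins between contigs).
    """

    scaffold: str
    scaffold_len: int
    gaps: list[Interval] = field(default_factory=list)

    @property
    def breakpoints(self) -> list[int]:
        pts: set[int] = set()
        for g in self.gaps:
            pts.add(g.start)
            pts.add(g.end)
        return sorted(pts)

    def segments(self) -> list[tuple[int, int]]:
        """Non-gap (contig) intervals; together with gaps they tile the scaffold."""
        segs = []
        pos = 0
        for g in sorted(self.gaps, key=lambda g: g.start):
            if g.start > pos:
                segs.append((pos, g.start))
            pos = g.end
        if pos < self.scaffold_len:
            segs.append((pos, self.scaffold_len))
        return segs


@dataclass(frozen=True)
class TelomereHit:
    scaffold: str
    side: str  # "start" or "end"
    span: Interval
    repeat_copies: int


def find_contig_gaps(
    fasta: Union[str, SequenceSet], min_n_run: int = 10
) -> list[ContigMap]:
    """Report every maximal N-run of length >= ``min_n_run`` per scaffold.

    Case-insensitive; empty sequences yield an empty map rather than an error.
    """
    seqs = _load_sequences(fasta)
    pattern = re.compile(r"[Nn]+")
    maps = []
    for name, seq in seqs.items():
        gaps = [
            Interval(name, m.start(), m.end())
            for m in pattern.finditer(seq)
            if m.end() - m.start() >= min_n_run
        ]
        maps.append(ContigMap(scaffold=name, scaffold_len=len(seq), gaps=gaps))
    return maps


def _count_nonoverlapping(haystack: str, needle: str) -> tuple[int, tuple[int, int]]:
    """Count non-overlapping occurrences; also return (first_start, last_end)."""
    count = 0
    first = last = -1
    i = haystack.find(needle)
    while i != -1:
        if first < 0:
            first = i
        last = i + len(needle)
        count += 1
        i = haystack.find(needle, i + len(needle))
    return count, (first, last)


def find_telomeres(
    fasta: Union[str, SequenceSet],
    repeat_unit: str = "TTTAGGG",
    terminal_window: int = 10000,
    min_copies: int = 25,
) -> list[TelomereHit]:
    """Locate telomeric repeat arrays in each scaffold's terminal windows.

    The forward motif is counted at the scaffold end and its reverse
    complement at the scaffold start (plant telomeres read TTTAGGG toward the
    chromosome end on the forward strand).  A hit requires at least
    ``min_copies`` exact, non-overlapping copies within the window; windows
    larger than the sequence are clipped.
    """
    if not repeat_unit:
        raise ValueError("repeat_unit must be non-empty")
    seqs = _load_sequences(fasta)
    rc_unit = reverse_complement(repeat_unit)
    hits: list[TelomereHit] = []
    for name, seq in seqs.items():
        seq_u = seq.upper()
        w = min(terminal_window, len(seq_u))
        head, tail = seq_u[:w], seq_u[len(seq_u) - w :]
        n, (s, e) = _count_nonoverlapping(head, rc_unit.upper())
        if n >= min_copies:
            hits.append(TelomereHit(name, "start", Interval(name, s, e), n))
        n, (s, e) = _count_nonoverlapping(tail, repeat_unit.upper())
        if n >= min_copies:
            off = len(seq_u) - w
            hits.append(TelomereHit(name, "end", Interval(name, off + s, off + e), n))
    return hits


def gaps_table(maps: list[ContigMap]) -> pd.DataFrame:
    rows = [
        {"scaffold": m.scaffold, "gap_start": g.start, "gap_end": g.end}
        for m in maps
        for g in m.gaps
    ]
    return pd.DataFrame(rows, columns=["scaffold", "gap_start", "gap_end"])


def telomeres_table(hits: list[TelomereHit]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": h.scaffold,
            "side": h.side,
            "span_start": h.span.start,
            "span_end": h.span.end,
            "repeat_copies": h.repeat_copies,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["scaffold", "side", "span_start", "span_end", "repeat_copies"]
    )


def contig_maps_from_table(df: pd.DataFrame, scaffold_lens: Mapping[str, int]) -> dict[str, ContigMap]:
    """Rebuild ContigMaps from a gaps TSV plus scaffold lengths."""
    maps = {
        name: ContigMap(scaffold=name, scaffold_len=length)
        for name, length in scaffold_lens.items()
    }
    for row in df.itertuples(index=False):
        maps[row.scaffold].gaps.append(
            Interval(row.scaffold, int(row.gap_start), int(row.gap_end))
        )
    return maps
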