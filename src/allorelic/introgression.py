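"""Dual-reference introgression assignment and donor/recipient segmentation.

A scaffold's species of origin is decided by aligning it to two candidate
references and comparing the fraction of the scaffold covered by filtered
alignments (coverage, not identity, is the discriminating signal: a diverged
wild-relative haplotype still aligns at high identity in conserved regions
but covers far less of the reference).  Within a scaffold, breakpoints
between recipient and donor sequence are found from windowed best-placement
read counts with a run-length majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_core import AlignmentRecord, Interval, union_length


@dataclass(frozen=True)
class OriginSummary:
    """Per-scaffold dual-reference alignment summary and origin call."""

    scaffold: str
    scaffold_len: int
    aligned_frac_ref1: float
    identity_ref1: float
    aligned_frac_ref2: float
    identity_ref2: float
    origin: str  # "ref1", "ref2" or "ambiguous"


@dataclass(frozen=True)
class SourceSegment:
    """A maximal run of windows assigned to one source (parent/donor)."""

    scaffold: str
    span: Interval
    source: str
    n_windows: int


def decide_origin(frac1: float, frac2: float, margin: float = 0.1) -> str:
    """Origin is the reference with higher aligned fraction, by >= ``margin``."""
    if frac1 - frac2 >= margin:
        return "ref1"
    if frac2 - frac1 >= margin:
        return "ref2"
    return "ambiguous"


def _coverage_and_identity(
    alignments: Sequence[AlignmentRecord], scaffold: str, length: int
) -> tuple[float, float]:
    mine = [r for r in alignments if r.query.seq_name == scaffold]
    if not mine:
        return 0.0, float("nan")
    covered = union_length((r.query.start, r.query.end) for r in mine)
    wsum = sum(len(r.query) for r in mine)
    ident = sum(len(r.query) * r.identity for r in mine) / wsum
    return covered / length, ident


def summarize_origin(
    alignments_ref1: Sequence[AlignmentRecord],
    alignments_ref2: Sequence[AlignmentRecord],
    scaffold_lens: Mapping[str, int],
    margin: float = 0.1,
) -> list[OriginSummary]:
    """Summarize each query scaffold against two references and call its origin.

    ``aligned_frac`` is computed on the union of query intervals (overlapping
    alignments are not double-counted); identity is alignment-length-weighted
    over aligned regions.  Inputs are expected pre-filtered (e.g. blocks
    > 10 kb with identity > 0.85).
    """
    seen = {r.query.seq_name for r in alignments_ref1} | {
        r.query.seq_name for r in alignments_ref2
    }
    missing = seen - set(scaffold_lens)
    if missing:
        raise KeyError(f"scaffold length missing for {sorted(missing)}")
    out = []
    for name, length in scaffold_lens.items():
        f1, i1 = _coverage_and_identity(alignments_ref1, name, length)
        f2, i2 = _coverage_and_identity(alignments_ref2, name, length)
        out.append(
            OriginSummary(name, length, f1, i1, f2, i2, decide_origin(f1, f2, margin))
        )
    return out


WindowVotes = Sequence[tuple[Interval, Mapping[str, int]]]


def votes_from_read_paf(
    records: Sequence[AlignmentRecord],
    source_of: Mapping[str, str],
    scaffold_lens: Mapping[str, int],
    window: int = 100_000,
) -> dict[str, list[tuple[Interval, dict[str, int]]]]:
    """Bin best-placement read mappings into per-window source counts.

    Each record is one read's single best placement on the assembly; its
    target-midpoint window receives one vote for the read's source
    (``source_of`` maps read name to a source label).  Returns, per scaffold,
    an ordered list of (window, counts) covering the whole scaffold.
    """
    votes: dict[str, list[tuple[Interval, dict[str, int]]]] = {}
    for name, length in scaffold_lens.items():
        n_win = max(1, -(-length // window))
        votes[name] = [
            (Interval(name, i * window, min((i + 1) * window, length)), {})
            for i in range(n_win)
        ]
    for rec in records:
        tgt = rec.target
        if tgt.seq_name not in votes:
            continue
        src = source_of[rec.query.seq_name]
        mid = (tgt.start + tgt.end) // 2
        _, counts = votes[tgt.seq_name][min(mid // window, len(votes[tgt.seq_name]) - 1)]
        counts[src] = counts.get(src, 0) + 1
    return votes


def _majority(counts: Mapping[str, int]) -> Optional[str]:
    if not counts:
        return None
    best = max(counts.values())
    winners = [s for s, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else None  # tie -> no call


def segment_sources(
    window_votes: WindowVotes, min_run: int = 5
) -> list[SourceSegment]:
    """Segment ordered windows into source tracts by run-length majority.

    Each window gets its majority source (ties and empty windows are
    no-calls); runs of at least ``min_run`` identical labels stand, while
    shorter runs (and no-calls) are merged into the flanking run with more
    votes.  Breakpoints fall on window boundaries between adjacent segments.
    """
    if not window_votes:
        return []
    labels = [_majority(c) for _, c in window_votes]
    weights = [sum(c.values()) for _, c in window_votes]
    if all(lab is None for lab in labels):
        return []

    # run-length encode as [label, start, end)
    runs: list[list] = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i + 1
        else:
            runs.append([lab, i, i + 1])

    def run_votes(r: list) -> int:
        return sum(weights[r[1]: r[2]])

    def merge_pass() -> bool:
        # absorb the weakest offending run into its stronger flank
        candidates = [
            k for k, r in enumerate(runs)
            if r[0] is None or (r[2] - r[1] < min_run and len(runs) > 1)
        ]
        if not candidates:
            return False
        k = min(candidates, key=lambda k: (runs[k][2] - runs[k][1], k))
        left = runs[k - 1] if k > 0 else None
        right = runs[k + 1] if k + 1 < len(runs) else None
        if left is None and right is None:
            return False
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            target = left if run_votes(left) >= run_votes(right) else right
        target_lab = target[0]
        runs[k][0] = target_lab
        # merge adjacent equal-label runs
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs[:] = merged
        return True

    while merge_pass():
        pass

    segments = []
    for lab, i, j in runs:
        if lab is None:
            continue
        scaffold = window_votes[i][0].seq_name
        span = Interval(scaffold, window_votes[i][0].start, window_votes[j - 1][0].end)
        segments.append(SourceSegment(scaffold, span, lab, j - i))
    return segments


def breakpoints(segments: Sequence[SourceSegment]) -> list[int]:
    """Window-boundary positions between adjacent segments of one scaffold."""
    return [
        seg.span.start
        for prev, seg in zip(segments, segments[1:])
        if prev.span.seq_name == seg.span.seq_name
    ]


def origin_table(summaries: Sequence[OriginSummary]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": s.scaffold,
            "scaffold_len": s.scaffold_len,
            "aligned_frac_ref1": s.aligned_frac_ref1,
            "identity_ref1": s.identity_ref1,
            "aligned_frac_ref2": s.aligned_frac_ref2,
            "identity_ref2": s.identity_ref2,
            "origin": s.origin,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["scaffold", "scaffold_len", "aligned_frac_ref1", "identity_ref1",
                 "aligned_frac_ref2", "identity_ref2", "origin"],
    )


def segments_bed(segments: Sequence[SourceSegment]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": s.scaffold,
            "start": s.span.start,
            "end": s.span.end,
            "source": s.source,
            "n_windows": s.n_windows,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "source", "n_windows"])
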