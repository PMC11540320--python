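"""Windowed competitive-ancestry classification of an allotetraploid assembly.

Both progenitor genomes are aligned to the tetraploid; per fixed-width window
each ancestor's length-weighted alignment identity is computed and the window
is awarded to the better-aligning ancestor.  Comparing winners across a
homeolog pair distinguishes the expected AABB configuration from tetrasomic
regions (one ancestor wins on both homeologs) and subgenome exchanges (each
ancestor wins on the opposite homeolog).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io_core import AlignmentRecord, Interval

LABELS = ("expected", "tetrasomic_A", "tetrasomic_B", "exchanged", "ambiguous")


@dataclass(frozen=True)
class AncestryWindow:
    """One fixed-width window with per-ancestor alignment summaries.

    ``identity_X`` is NaN when ancestor X covers less than the coverage floor;
    ``winner`` is "A", "B" or "none".
    """

    scaffold: str
    window: Interval
    aligned_bp_A: int
    aligned_bp_B: int
    identity_A: float
    identity_B: float
    winner: str


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of identically labeled homeolog window pairs."""

    homeolog_pair: tuple[str, str]
    region_A: Interval
    region_B: Interval
    label: str
    n_windows: int
    n_genes: int = 0


def make_windows(scaffold: str, length: int, window: int) -> list[Interval]:
    """Fixed windows anchored at 0; a final partial window is kept when it
    covers at least half the window width."""
    if window <= 0:
        raise ValueError("window size must be positive")
    out = []
    n_full = length // window
    for i in range(n_full):
        out.append(Interval(scaffold, i * window, (i + 1) * window))
    rem = length - n_full * window
    if rem >= window / 2:
        out.append(Interval(scaffold, n_full * window, length))
    return out


def _accumulate(
    alignments: Sequence[AlignmentRecord],
    windows: Mapping[str, list[Interval]],
) -> dict[tuple[str, int], tuple[float, float]]:
    """Per (scaffold, window index): (sum of overlap, sum of overlap*identity)."""
    acc: dict[tuple[str, int], list[float]] = {}
    for rec in alignments:
        t = rec.target
        wins = windows.get(t.seq_name)
        if not wins:
            continue
        wsize = len(wins[0])
        first = max(0, t.start // wsize)
        for i in range(first, len(wins)):
            w = wins[i]
            if w.start >= t.end:
                break
            ov = t.overlap_len(w)
            if ov > 0:
                cell = acc.setdefault((t.seq_name, i), [0.0, 0.0])
                cell[0] += ov
                cell[1] += ov * rec.identity
    return {k: (v[0], v[1]) for k, v in acc.items()}


def window_identity(
    alignments_A: Sequence[AlignmentRecord],
    alignments_B: Sequence[AlignmentRecord],
    scaffold_lens: Mapping[str, int],
    window: int = 100_000,
    min_cov_frac: float = 0.1,
    tie_margin: float = 0.002,
) -> list[AncestryWindow]:
    """Compute per-window length-weighted identity for each ancestor and pick a winner.

    Each alignment contributes its window overlap and overlap x identity;
    identity_X = sum(overlap x identity) / sum(overlap).  Windows where an
    ancestor covers less than ``min_cov_frac`` of the window have identity NaN
    for that ancestor.  The winner must have non-NaN identity and, when both
    ancestors are callable, exceed the other by at least ``tie_margin``.
    """
    windows = {
        name: make_windows(name, length, window)
        for name, length in scaffold_lens.items()
    }
    acc_A = _accumulate(alignments_A, windows)
    acc_B = _accumulate(alignments_B, windows)

    out: list[AncestryWindow] = []
    for name in scaffold_lens:
        for i, w in enumerate(windows[name]):
            floor = min_cov_frac * len(w)
            cov_A, wid_A = acc_A.get((name, i), (0.0, 0.0))
            cov_B, wid_B = acc_B.get((name, i), (0.0, 0.0))
            id_A = wid_A / cov_A if cov_A >= floor and cov_A > 0 else math.nan
            id_B = wid_B / cov_B if cov_B >= floor and cov_B > 0 else math.nan
            winner = "none"
            if not math.isnan(id_A) and (math.isnan(id_B) or id_A - id_B >= tie_margin):
                winner = "A"
            elif not math.isnan(id_B) and (math.isnan(id_A) or id_B - id_A >= tie_margin):
                winner = "B"
            out.append(
                AncestryWindow(name, w, int(cov_A), int(cov_B), id_A, id_B, winner)
            )
    return out


def classify_homeolog_windows(
    windows_on_A_homeolog: Sequence[AncestryWindow],
    windows_on_B_homeolog: Sequence[AncestryWindow],
    mode: str = "competitive",
) -> list[str]:
    """Label rank-paired homeolog windows by their ancestor winners.

    expected: A wins on the A-homeolog and B on the B-homeolog;
    tetrasomic_X: ancestor X wins on both; exchanged: winners are swapped;
    ambiguous: either winner is "none".  ``mode`` records whether the inputs
    came from competitive (both ancestors vs whole assembly) or
    subgenome-specific alignments; the labeling rule is identical.
    """
    if mode not in ("competitive", "subgenome_specific"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(windows_on_A_homeolog) != len(windows_on_B_homeolog):
        raise ValueError("paired window lists differ in length")
    labels = []
    for wa, wb in zip(windows_on_A_homeolog, windows_on_B_homeolog):
        pair = (wa.winner, wb.winner)
        if "none" in pair:
            labels.append("ambiguous")
        elif pair == ("A", "B"):
            labels.append("expected")
        elif pair == ("A", "A"):
            labels.append("tetrasomic_A")
        elif pair == ("B", "B"):
            labels.append("tetrasomic_B")
        else:  # ("B", "A")
            labels.append("exchanged")
    return labels


def _bridge(labels: list[str]) -> list[str]:
    """Bridge a single ambiguous window flanked by the same label."""
    out = list(labels)
    for i in range(1, len(out) - 1):
        if (
            out[i] == "ambiguous"
            and out[i - 1] == out[i + 1]
            and out[i - 1] != "ambiguous"
        ):
            out[i] = out[i - 1]
    return out


def merge_regions(
    labels: Sequence[str],
    windows_on_A_homeolog: Sequence[AncestryWindow],
    windows_on_B_homeolog: Sequence[AncestryWindow],
    min_run: int = 3,
) -> list[RegionCall]:
    """Merge ordered labeled window pairs into maximal regions.

    Runs of at least ``min_run`` identical non-ambiguous labels become
    RegionCalls; shorter runs are absorbed into ambiguous.  A single
    ambiguous window inside a run of one label is bridged first.
    """
    if not labels:
        return []
    lab = _bridge(list(labels))
    regions: list[RegionCall] = []
    i = 0
    n = len(lab)
    while i < n:
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        if lab[i] != "ambiguous" and j - i >= min_run:
            wa0, wa1 = windows_on_A_homeolog[i], windows_on_A_homeolog[j - 1]
            wb0, wb1 = windows_on_B_homeolog[i], windows_on_B_homeolog[j - 1]
            regions.append(
                RegionCall(
                    homeolog_pair=(wa0.scaffold, wb0.scaffold),
                    region_A=Interval(wa0.scaffold, wa0.window.start, wa1.window.end),
                    region_B=Interval(wb0.scaffold, wb0.window.start, wb1.window.end),
                    label=lab[i],
                    n_windows=j - i,
                )
            )
        i = j
    return regions


def genes_in_regions(
    regions: Sequence[RegionCall], genes: Sequence[Interval]
) -> tuple[list[RegionCall], int, float]:
    """Annotate regions with overlapping gene counts (>= 1 bp, deduplicated).

    Returns the annotated regions, the deduplicated total number of genes in
    any region, and that total as a fraction of all genes.
    """
    annotated = []
    hit_any: set[int] = set()
    for reg in regions:
        hits = {
            gi
            for gi, g in enumerate(genes)
            if g.overlaps(reg.region_A) or g.overlaps(reg.region_B)
        }
        hit_any |= hits
        annotated.append(
            RegionCall(reg.homeolog_pair, reg.region_A, reg.region_B,
                       reg.label, reg.n_windows, n_genes=len(hits))
        )
    frac = len(hit_any) / len(genes) if genes else 0.0
    return annotated, len(hit_any), frac


def windows_table(windows: Sequence[AncestryWindow]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": w.scaffold,
            "start": w.window.start,
            "end": w.window.end,
            "aligned_bp_A": w.aligned_bp_A,
            "aligned_bp_B": w.aligned_bp_B,
            "identity_A": w.identity_A,
            "identity_B": w.identity_B,
            "winner": w.winner,
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "aligned_bp_A", "aligned_bp_B",
                 "identity_A", "identity_B", "winner"],
    )


def regions_table(regions: Sequence[RegionCall]) -> pd.DataFrame:
    rows = [
        {
            "scaffold_A": r.homeolog_pair[0],
            "scaffold_B": r.homeolog_pair[1],
            "start_A": r.region_A.start,
            "end_A": r.region_A.end,
            "start_B": r.region_B.start,
            "end_B": r.region_B.end,
            "label": r.label,
            "n_windows": r.n_windows,
            "n_genes": r.n_genes,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=["scaffold_A", "scaffold_B", "start_A", "end_A", "start_B",
                 "end_B", "label", "n_windows", "n_genes"],
    )
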