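"""Inversion calling, contig-breakpoint filtering and boundary enrichment.

Inversions between two assemblies appear as runs of alignment blocks whose
strand opposes the flanking syntenic chain and whose query order is reversed.
Because a mis-oriented contig produces exactly the same signature, calls whose
boundaries fall near contig breakpoints (N-gap edges) in either assembly are
flagged and excluded from the filtered set; a permutation test quantifies how
strongly inversion boundaries concentrate near breakpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assembly_qc import ContigMap
from .io_core import AlignmentRecord, Interval, union_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InversionCall:
    """A strand-discordant block run between two assemblies."""

    query_region: Interval
    target_region: Interval
    n_blocks: int
    source: str = "internal"  # or "imported"

    @property
    def size(self) -> int:
        return len(self.query_region)


@dataclass(frozen=True)
class BoundaryClass:
    """Contig-breakpoint proximity of one inversion, on both assemblies."""

    near_query_break: bool
    near_target_break: bool
    min_dist_query: float
    min_dist_target: float


@dataclass(frozen=True)
class EnrichmentResult:
    observed_fraction: float
    expected_fraction: float
    enrichment: float
    perm_p: Optional[float]
    n_perm: int


# ---------------------------------------------------------------------------
# calling


def call_inversions(
    alignments: Sequence[AlignmentRecord],
    min_block: int = 10_000,
    max_chain_gap: int = 100_000,
) -> list[InversionCall]:
    """Call inversions from filtered whole-genome alignments of two assemblies.

    Per target sequence, blocks sorted by target position define a
    majority-strand syntenic chain (majority by aligned length).  Maximal runs
    of opposite-strand blocks whose query coordinates run counter to the chain,
    with adjacent target gaps <= ``max_chain_gap``, are merged into single
    calls; calls spanning less than ``min_block`` on the query are dropped.
    A run that jumps between query chromosomes is split with a warning.
    """
    calls: list[InversionCall] = []
    by_target: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_target.setdefault(rec.target.seq_name, []).append(rec)

    for tname in sorted(by_target):
        recs = sorted(by_target[tname], key=lambda r: (r.target.start, r.target.end))
        strand_bp = {"+": 0, "-": 0}
        for r in recs:
            strand_bp[r.strand] += len(r.target)
        majority = "+" if strand_bp["+"] >= strand_bp["-"] else "-"
        minority = "-" if majority == "+" else "+"

        run: list[AlignmentRecord] = []
        for r in recs:
            if r.strand != minority:
                calls.extend(_close_run(run, minority, min_block))
                run = []
                continue
            if run:
                prev = run[-1]
                gap = r.target.start - prev.target.end
                same_query = r.query.seq_name == prev.query.seq_name
                # query order must run counter to the majority chain
                if minority == "-":
                    ordered = r.query.start <= prev.query.start
                else:
                    ordered = r.query.start >= prev.query.start
                if not same_query:
                    logger.warning(
                        "inversion candidate on %s spans query chromosomes %s/%s; split",
                        tname, prev.query.seq_name, r.query.seq_name,
                    )
                if gap > max_chain_gap or not same_query or not ordered:
                    calls.extend(_close_run(run, minority, min_block))
                    run = []
            run.append(r)
        calls.extend(_close_run(run, minority, min_block))

    calls.sort(key=lambda c: (c.target_region.seq_name, c.target_region.start))
    return calls


def _close_run(
    run: list[AlignmentRecord], minority: str, min_block: int
) -> list[InversionCall]:
    if not run:
        return []
    qname = run[0].query.seq_name
    q_start = min(r.query.start for r in run)
    q_end = max(r.query.end for r in run)
    t_start = min(r.target.start for r in run)
    t_end = max(r.target.end for r in run)
    if q_end - q_start < min_block:
        return []
    return [
        InversionCall(
            query_region=Interval(qname, q_start, q_end, minority),
            target_region=Interval(run[0].target.seq_name, t_start, t_end, "+"),
            n_blocks=len(run),
        )
    ]


def import_syri(path: str) -> list[InversionCall]:
    """Import inversions from a SyRI annotation table (rows labeled INV).

    SyRI coordinates are 1-based inclusive; reference columns map to the
    target side and query columns to the query side.
    """
    calls = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11 or cols[10] != "INV":
                continue
            target = Interval(cols[0], int(cols[1]) - 1, int(cols[2]), "+")
            query = Interval(cols[5], int(cols[6]) - 1, int(cols[7]), "-")
            calls.append(
                InversionCall(query_region=query, target_region=target,
                              n_blocks=1, source="imported")
            )
    return calls


# ---------------------------------------------------------------------------
# breakpoint proximity


def _min_endpoint_distance(region: Interval, breakpoints: Sequence[int]) -> float:
    if not breakpoints:
        return math.inf
    bps = np.asarray(breakpoints)
    return float(
        min(np.abs(bps - region.start).min(), np.abs(bps - region.end).min())
    )


def classify_boundaries(
    inversions: Sequence[InversionCall],
    query_maps: Mapping[str, ContigMap],
    target_maps: Mapping[str, ContigMap],
    d: int = 2000,
) -> list[BoundaryClass]:
    """Flag inversions whose boundaries lie within ``d`` bp of a contig breakpoint.

    An inversion is near a break on one assembly when EITHER endpoint of its
    region on that assembly is within ``d`` of ANY breakpoint on that sequence.
    """
    classes = []
    for inv in inversions:
        for side, maps in (("query", query_maps), ("target", target_maps)):
            region = getattr(inv, f"{side}_region")
            if region.seq_name not in maps:
                raise KeyError(
                    f"sequence {region.seq_name!r} missing from {side} contig maps"
                )
        dq = _min_endpoint_distance(
            inv.query_region, query_maps[inv.query_region.seq_name].breakpoints
        )
        dt = _min_endpoint_distance(
            inv.target_region, target_maps[inv.target_region.seq_name].breakpoints
        )
        classes.append(BoundaryClass(dq <= d, dt <= d, dq, dt))
    return classes


def filter_inversions(
    inversions: Sequence[InversionCall], classes: Sequence[BoundaryClass]
) -> tuple[list[InversionCall], dict]:
    """Drop breakpoint-proximal calls and tally the accounting categories.

    The two "near" counts each include calls flagged on both assemblies (so
    their percentages need not sum to 100 with the filtered percentage), while
    the filtered set requires both flags false.  Percentages are rounded to
    one decimal.
    """
    if len(inversions) != len(classes):
        raise ValueError("classes must parallel inversions")
    filtered = [
        inv for inv, c in zip(inversions, classes)
        if not c.near_query_break and not c.near_target_break
    ]
    total = len(inversions)
    n_q = sum(c.near_query_break for c in classes)
    n_t = sum(c.near_target_break for c in classes)

    def pct(n: int) -> float:
        return round(100.0 * n / total, 1) if total else float("nan")

    tally = {
        "total": total,
        "near_query_break": n_q,
        "near_query_break_pct": pct(n_q),
        "near_target_break": n_t,
        "near_target_break_pct": pct(n_t),
        "filtered": len(filtered),
        "filtered_pct": pct(len(filtered)),
        "filtered_gt_100kb": sum(inv.size > 100_000 for inv in filtered),
        "filtered_gt_1Mb": sum(inv.size > 1_000_000 for inv in filtered),
    }
    return filtered, tally


def genes_in_inversions(
    filtered: Sequence[InversionCall], genes: Sequence[Interval]
) -> tuple[int, float]:
    """Count genes overlapping filtered inversions (query side) and their density.

    A gene counts once if it overlaps any filtered inversion by >= 1 bp;
    density is genes per kb of total filtered query span.  With zero filtered
    inversions the density is undefined (NaN).
    """
    if not filtered:
        return 0, float("nan")
    n = sum(
        1 for g in genes if any(g.overlaps(inv.query_region) for inv in filtered)
    )
    span_kb = sum(inv.size for inv in filtered) / 1000.0
    return n, n / span_kb


# ---------------------------------------------------------------------------
# enrichment


def boundary_enrichment(
    inversions: Sequence[InversionCall],
    maps: Mapping[str, ContigMap],
    d: int = 2000,
    n_perm: int = 1000,
    *,
    seed: int,
    side: str = "query",
) -> EnrichmentResult:
    """Quantify concentration of inversion boundaries near contig breakpoints.

    observed_fraction: boundaries (two per inversion, on the ``side`` assembly)
    whose distance to the nearest breakpoint is <= ``d``, over all boundaries.
    expected_fraction: assembly bases within ``d`` of any breakpoint (intervals
    [b-d, b+d) unioned and clipped to sequence ends) over total assembly length.
    The permutation null redraws the observed number of boundaries uniformly
    per sequence; perm_p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if side not in ("query", "target"):
        raise ValueError("side must be 'query' or 'target'")
    total_len = sum(m.scaffold_len for m in maps.values())
    if total_len <= 0:
        raise ValueError("total assembly length must be positive")

    near_bp = 0
    for m in maps.values():
        near_bp += union_length(
            (max(0, b - d), min(m.scaffold_len, b + d)) for b in m.breakpoints
        )
    expected = near_bp / total_len

    if not inversions:
        return EnrichmentResult(0.0, expected, 0.0, 1.0, n_perm)

    # boundaries grouped per sequence
    by_seq: dict[str, list[int]] = {}
    for inv in inversions:
        region = inv.query_region if side == "query" else inv.target_region
        by_seq.setdefault(region.seq_name, []).extend([region.start, region.end])

    bps_sorted = {name: np.sort(np.asarray(m.breakpoints)) for name, m in maps.items()}

    def frac_near(boundaries: Mapping[str, np.ndarray]) -> float:
        near = 0
        total = 0
        for name, pos in boundaries.items():
            pos = np.asarray(pos)
            total += pos.size
            bps = bps_sorted.get(name)
            if bps is None or bps.size == 0:
                continue
            idx = np.searchsorted(bps, pos)
            left = np.where(idx > 0, np.abs(pos - bps[np.maximum(idx - 1, 0)]), np.inf)
            right = np.where(
                idx < bps.size, np.abs(bps[np.minimum(idx, bps.size - 1)] - pos), np.inf
            )
            near += int(np.sum(np.minimum(left, right) <= d))
        return near / total if total else 0.0

    observed = frac_near(by_seq)
    if expected > 0:
        enrichment = observed / expected
    else:
        enrichment = math.inf if observed > 0 else 0.0
        if observed > 0:
            logger.warning("no breakpoint-proximal bases; enrichment is infinite")

    rng = np.random.default_rng(seed)
    perm_ge = 0
    for _ in range(n_perm):
        perm = {
            name: rng.integers(0, maps[name].scaffold_len, size=len(pos))
            for name, pos in by_seq.items()
            if name in maps
        }
        if frac_near(perm) >= observed:
            perm_ge += 1
    perm_p = (1 + perm_ge) / (1 + n_perm)
    return EnrichmentResult(observed, expected, enrichment, perm_p, n_perm)


def tally_table(tallies: Mapping[str, dict]) -> pd.DataFrame:
    """Assemble per-comparison tallies into one report table."""
    rows = []
    for name, tally in tallies.items():
        rows.append({"comparison": name, **tally})
    return pd.DataFrame(rows)
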