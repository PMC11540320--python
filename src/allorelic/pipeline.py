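"""End-to-end pipeline over a fixture directory (or equivalently named inputs).

Runs assembly QC, inversion calling + breakpoint filtering + enrichment,
the windowed ancestry scan, dual-reference introgression assignment with
segmentation, and trio classification, writing one TSV per stage and
returning the headline numbers as a flat dict.  Stage parameters mirror the
alignment filters used for each analysis (10 kb / 0.7 / mapq 40 for windowed
identity; 10 kb / 0.85 for origin summaries).
"""

from __future__ import annotations

import json
import os
from typing import Optional

import pandas as pd

from . import ancestry, assembly_qc, introgression, inversions, io_core, trio
from .simulate import Fixture


def run_full(
    fixture: Fixture,
    outdir: str,
    seed: int = 0,
    window: int = 100_000,
    d: int = 2000,
    n_perm: int = 1000,
    min_run_regions: int = 3,
    min_run_segments: int = 3,
    header_lines: tuple = (),
) -> dict:
    os.makedirs(outdir, exist_ok=True)
    results: dict = {}
    paths = fixture.paths
    truth = fixture.truth
    lens = truth["scaffold_lens"]
    main = truth["main_scaffolds"]

    # --- assembly QC ------------------------------------------------------
    gap_maps = assembly_qc.find_contig_gaps(paths["tetraploid"])
    maps = {m.scaffold: m for m in gap_maps}
    io_core.write_report(
        assembly_qc.gaps_table(gap_maps), os.path.join(outdir, "gaps.tsv"), header_lines
    )
    results["n_contig_gaps"] = sum(len(m.gaps) for m in gap_maps)

    # --- inversions -------------------------------------------------------
    aln_filter = io_core.AlignmentFilter(10_000, 0.7, 40)
    aln_A = io_core.read_paf(paths["ancestorA_vs_tet"], aln_filter)
    aln_B = io_core.read_paf(paths["ancestorB_vs_tet"], aln_filter)
    calls = inversions.call_inversions(aln_A, min_block=10_000)
    # progenitor chromosomes carry no joins in the fixture; tetraploid maps are real
    query_maps = {
        rec.query.seq_name: assembly_qc.ContigMap(
            scaffold=rec.query.seq_name, scaffold_len=fixture.config.chrom_len
        )
        for rec in aln_A
    }
    classes = inversions.classify_boundaries(calls, query_maps, maps, d=d)
    filtered, tally = inversions.filter_inversions(calls, classes)
    genes = io_core.read_features(paths["genes"])
    enr = inversions.boundary_enrichment(
        calls, maps, d=d, n_perm=n_perm, seed=seed, side="target"
    )
    io_core.write_report(
        inversions.tally_table({"progenitorA_vs_tetraploid": tally}),
        os.path.join(outdir, "inversions.tsv"),
        header_lines,
    )
    results.update(
        n_inversions=tally["total"],
        n_inversions_filtered=tally["filtered"],
        enrichment_observed_fraction=enr.observed_fraction,
        enrichment_expected_fraction=enr.expected_fraction,
        enrichment=enr.enrichment,
        enrichment_perm_p=enr.perm_p,
    )

    # --- ancestry scan ----------------------------------------------------
    windows = ancestry.window_identity(
        aln_A, aln_B, {n: lens[n] for n in main}, window=window
    )
    by_scaf = {}
    for w in windows:
        by_scaf.setdefault(w.scaffold, []).append(w)
    regions_all = []
    for pair in truth["pairs"]:
        wa, wb = by_scaf[f"{pair}_A"], by_scaf[f"{pair}_B"]
        labels = ancestry.classify_homeolog_windows(wa, wb)
        regions_all.extend(ancestry.merge_regions(labels, wa, wb, min_run=min_run_regions))
    regions_all, n_genes_regions, frac_genes = ancestry.genes_in_regions(
        regions_all, genes
    )
    io_core.write_report(
        ancestry.windows_table(windows), os.path.join(outdir, "ancestry_windows.tsv"),
        header_lines,
    )
    io_core.write_report(
        ancestry.regions_table(regions_all), os.path.join(outdir, "ancestry_regions.tsv"),
        header_lines,
    )
    results.update(
        n_regions=len(regions_all),
        n_exchanged_regions=sum(r.label == "exchanged" for r in regions_all),
        n_tetrasomic_regions=sum(r.label.startswith("tetrasomic") for r in regions_all),
        genes_in_nonexpected_regions_frac=_nonexpected_gene_frac(regions_all, genes),
    )

    # --- introgression ----------------------------------------------------
    origin_filter = io_core.AlignmentFilter(10_000, 0.85)
    o1 = io_core.read_paf(paths["origin_ref1"], origin_filter)
    o2 = io_core.read_paf(paths["origin_ref2"], origin_filter)
    origin_lens = {
        name: lens[name]
        for name in {r.query.seq_name for r in o1} | {r.query.seq_name for r in o2}
    }
    summaries = introgression.summarize_origin(o1, o2, origin_lens)
    io_core.write_report(
        introgression.origin_table(summaries), os.path.join(outdir, "origin.tsv"),
        header_lines,
    )
    for s in summaries:
        results[f"aligned_frac_ref1[{s.scaffold}]"] = s.aligned_frac_ref1
        results[f"aligned_frac_ref2[{s.scaffold}]"] = s.aligned_frac_ref2

    reads = io_core.read_paf(paths["reads_vs_tet"])
    votes = introgression.votes_from_read_paf(
        reads, truth["read_sources"],
        {truth["read_scaffold"]: lens[truth["read_scaffold"]]}, window=window,
    )
    segments = introgression.segment_sources(
        votes[truth["read_scaffold"]], min_run=min_run_segments
    )
    io_core.write_report(
        introgression.segments_bed(segments), os.path.join(outdir, "segments.tsv"),
        header_lines,
    )
    results["n_source_segments"] = len(segments)
    results["n_source_breakpoints"] = len(introgression.breakpoints(segments))

    # --- trio -------------------------------------------------------------
    smp = truth["trio"]["samples"]
    sites, _ = trio.classify_trio(paths["trio"], smp["p1"], smp["p2"], smp["off"])
    summary = trio.summarize_trio(sites)
    io_core.write_report(
        trio.summary_table(summary), os.path.join(outdir, "trio.tsv"), header_lines
    )
    results.update(
        n_fixed_diff=summary.n_fixed_diff,
        pct_offspring_het=summary.pct_het,
        n_nonparental=summary.n_nonparental,
    )

    with open(os.path.join(outdir, "results.json"), "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    return results


def _nonexpected_gene_frac(regions, genes) -> float:
    non_expected = [r for r in regions if r.label not in ("expected", "ambiguous")]
    _, n, frac = ancestry.genes_in_regions(non_expected, genes)
    return frac
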