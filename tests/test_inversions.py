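"""Inversion calling, breakpoint proximity filtering and enrichment."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from allorelic.assembly_qc import ContigMap
from allorelic.inversions import (
    BoundaryClass,
    InversionCall,
    boundary_enrichment,
    call_inversions,
    classify_boundaries,
    filter_inversions,
    genes_in_inversions,
    import_syri,
)
from allorelic.io_core import AlignmentRecord, Interval


def _block(qs, qe, ts, te, strand="+", q="q1", t="t1", identity=0.95):
    blen = te - ts
    return AlignmentRecord(
        Interval(q, qs, qe, strand), Interval(t, ts, te),
        n_matches=int(blen * identity), block_len=blen, mapq=60,
    )


def test_single_discordant_block_is_one_inversion():
    recs = [
        _block(0, 100_000, 0, 100_000, "+"),
        _block(100_000, 200_000, 100_000, 200_000, "-"),
        _block(200_000, 300_000, 200_000, 300_000, "+"),
        _block(300_000, 400_000, 300_000, 400_000, "+"),
    ]
    calls = call_inversions(recs, min_block=10_000)
    assert len(calls) == 1
    assert (calls[0].query_region.start, calls[0].query_region.end) == (100_000, 200_000)
    assert (calls[0].target_region.start, calls[0].target_region.end) == (100_000, 200_000)


def test_collinear_alignment_has_no_inversions():
    recs = [_block(i * 50_000, (i + 1) * 50_000, i * 50_000, (i + 1) * 50_000) for i in range(6)]
    assert call_inversions(recs) == []


def test_adjacent_reversed_blocks_merge_into_one_call():
    # two '-' blocks whose query order is reversed along the target
    recs = [
        _block(0, 100_000, 0, 100_000, "+"),
        _block(160_000, 200_000, 100_000, 140_000, "-"),
        _block(100_000, 160_000, 140_000, 200_000, "-"),
        _block(200_000, 300_000, 200_000, 300_000, "+"),
    ]
    calls = call_inversions(recs, min_block=10_000)
    assert len(calls) == 1
    assert calls[0].n_blocks == 2
    assert (calls[0].query_region.start, calls[0].query_region.end) == (100_000, 200_000)


def test_distant_reversed_blocks_stay_separate():
    recs = [
        _block(0, 100_000, 0, 100_000, "+"),
        _block(150_000, 160_000+ 40_000, 100_000, 150_000, "-"),
        _block(400_000, 500_000, 400_000, 500_000, "-"),
        _block(600_000, 700_000, 600_000, 700_000, "+"),
        _block(700_000, 900_000, 700_000, 900_000, "+"),
    ]
    calls = call_inversions(recs, min_block=10_000, max_chain_gap=100_000)
    assert len(calls) == 2


def test_truth_recovery_on_synthetic_fixture(fixture):
    """Every planted inversion is called with >= 0.9 reciprocal overlap."""
    from allorelic.io_core import AlignmentFilter, read_paf

    recs = read_paf(fixture.paths["ancestorA_vs_tet"], AlignmentFilter(10_000, 0.7, 40))
    calls = call_inversions(recs, min_block=10_000)
    truth = fixture.truth["inversions"]
    assert len(calls) == len(truth)
    for t in truth:
        t_iv = Interval(t["scaffold"], t["start"], t["end"])
        best = max(calls, key=lambda c: c.target_region.overlap_len(t_iv))
        ov = best.target_region.overlap_len(t_iv)
        assert ov >= 0.9 * len(t_iv) and ov >= 0.9 * best.size


def test_calling_is_symmetric_under_assembly_swap(fixture):
    from allorelic.io_core import AlignmentFilter, read_paf

    recs = read_paf(fixture.paths["ancestorA_vs_tet"], AlignmentFilter(10_000, 0.7, 40))
    swapped = [
        AlignmentRecord(
            Interval(r.target.seq_name, r.target.start, r.target.end, r.query.strand),
            Interval(r.query.seq_name, r.query.start, r.query.end, "+"),
            r.n_matches, r.block_len, r.mapq,
        )
        for r in recs
    ]
    assert len(call_inversions(recs)) == len(call_inversions(swapped))


def _map(name, length, gap_edges):
    m = ContigMap(scaffold=name, scaffold_len=length)
    for s, e in gap_edges:
        m.gaps.append(Interval(name, s, e))
    return m


def test_boundary_classification_example():
    inv = InversionCall(
        Interval("q", 51_500, 80_000, "-"), Interval("t", 200_000, 230_000), 1
    )
    qmaps = {"q": _map("q", 1_000_000, [(40_000, 50_000)])}  # query start 1500 bp from gap edge
    tmaps = {"t": _map("t", 1_000_000, [(500_000, 510_000)])}
    (c,) = classify_boundaries([inv], qmaps, tmaps, d=2000)
    assert c.near_query_break and not c.near_target_break
    assert c.min_dist_query == 1500


def test_no_gaps_means_no_flags():
    inv = InversionCall(Interval("q", 0, 10_000, "-"), Interval("t", 0, 10_000), 1)
    qmaps = {"q": _map("q", 1_000_000, [])}
    tmaps = {"t": _map("t", 1_000_000, [])}
    (c,) = classify_boundaries([inv], qmaps, tmaps)
    assert not c.near_query_break and not c.near_target_break
    assert math.isinf(c.min_dist_query)


def test_classification_matches_bruteforce_distances():
    rng = np.random.default_rng(23)
    qmap = _map("q", 2_000_000, [(int(s), int(s) + 100) for s in rng.integers(0, 1_900_000, 5)])
    tmap = _map("t", 2_000_000, [(int(s), int(s) + 100) for s in rng.integers(0, 1_900_000, 5)])
    invs = []
    for _ in range(10):
        qs, ts = int(rng.integers(0, 1_500_000)), int(rng.integers(0, 1_500_000))
        invs.append(
            InversionCall(Interval("q", qs, qs + 50_000, "-"), Interval("t", ts, ts + 50_000), 1)
        )
    d = 2000
    classes = classify_boundaries(invs, {"q": qmap}, {"t": tmap}, d=d)
    for inv, c in zip(invs, classes):
        bq = min(
            abs(e - b) for e in (inv.query_region.start, inv.query_region.end)
            for b in qmap.breakpoints
        )
        bt = min(
            abs(e - b) for e in (inv.target_region.start, inv.target_region.end)
            for b in tmap.breakpoints
        )
        assert (c.min_dist_query, c.min_dist_target) == (bq, bt)
        assert c.near_query_break == (bq <= d) and c.near_target_break == (bt <= d)


def test_missing_sequence_raises():
    inv = InversionCall(Interval("q", 0, 10_000, "-"), Interval("t", 0, 10_000), 1)
    with pytest.raises(KeyError, match="q"):
        classify_boundaries([inv], {}, {"t": _map("t", 1_000_000, [])})


def test_increasing_d_never_unflags():
    rng = np.random.default_rng(29)
    qmap = _map("q", 1_000_000, [(int(s), int(s) + 10) for s in rng.integers(0, 900_000, 8)])
    invs = [
        InversionCall(
            Interval("q", int(s), int(s) + 20_000, "-"),
            Interval("t", int(s), int(s) + 20_000), 1,
        )
        for s in rng.integers(0, 900_000, 15)
    ]
    tmaps = {"t": _map("t", 1_000_000, [])}
    prev = -1
    for d in (100, 1000, 5000, 50_000):
        classes = classify_boundaries(invs, {"q": qmap}, tmaps, d=d)
        n = sum(c.near_query_break for c in classes)
        assert n >= prev
        prev = n


def _dummy_calls(n, size=50_000):
    return [
        InversionCall(
            Interval("q", i * 100_000, i * 100_000 + size, "-"),
            Interval("t", i * 100_000, i * 100_000 + size), 1,
        )
        for i in range(n)
    ]


def test_filter_tally_enumeration():
    flags = [(False, False), (True, False), (False, True), (True, True)]
    classes = [BoundaryClass(a, b, 0 if a else 1e9, 0 if b else 1e9) for a, b in flags]
    filtered, tally = filter_inversions(_dummy_calls(4), classes)
    assert len(filtered) == 1
    assert tally["near_query_break"] == 2 and tally["near_target_break"] == 2
    assert tally["total"] == tally["filtered"] + sum(a or b for a, b in flags)


def test_all_clean_means_everything_filtered_through():
    calls = _dummy_calls(5)
    classes = [BoundaryClass(False, False, 1e9, 1e9)] * 5
    filtered, tally = filter_inversions(calls, classes)
    assert len(filtered) == tally["total"] == 5


def test_tally_conservation_with_random_flags():
    rng = np.random.default_rng(31)
    n = 60
    classes = [
        BoundaryClass(bool(a), bool(b), 0, 0)
        for a, b in rng.integers(0, 2, size=(n, 2))
    ]
    filtered, tally = filter_inversions(_dummy_calls(n), classes)
    any_flag = sum(c.near_query_break or c.near_target_break for c in classes)
    assert tally["filtered"] + any_flag == tally["total"] == n


def test_size_thresholded_counts():
    calls = [
        InversionCall(Interval("q", 0, 50_000, "-"), Interval("t", 0, 50_000), 1),
        InversionCall(Interval("q", 100_000, 300_000, "-"), Interval("t", 100_000, 300_000), 1),
        InversionCall(Interval("q", 1_000_000, 2_500_000, "-"), Interval("t", 1_000_000, 2_500_000), 1),
    ]
    classes = [BoundaryClass(False, False, 1e9, 1e9)] * 3
    _, tally = filter_inversions(calls, classes)
    assert tally["filtered_gt_100kb"] == 2 and tally["filtered_gt_1Mb"] == 1


def test_genes_in_inversions_arithmetic():
    inv = InversionCall(Interval("q", 0, 100_000, "-"), Interval("t", 0, 100_000), 1)
    genes = [Interval("q", 50, 60), Interval("q", 200_000, 200_100)]
    assert genes_in_inversions([inv], genes) == (1, pytest.approx(0.01))


def test_no_genes_gives_zero_density():
    inv = InversionCall(Interval("q", 0, 100_000, "-"), Interval("t", 0, 100_000), 1)
    assert genes_in_inversions([inv], []) == (0, 0.0)


def test_boundary_straddling_gene_counts():
    inv = InversionCall(Interval("q", 1000, 5000, "-"), Interval("t", 1000, 5000), 1)
    n, _ = genes_in_inversions([inv], [Interval("q", 4999, 6000)])
    assert n == 1


def test_zero_filtered_inversions_density_undefined():
    n, density = genes_in_inversions([], [Interval("q", 0, 10)])
    assert n == 0 and math.isnan(density)


def test_enrichment_clipped_interval_arithmetic():
    maps = {"q": SimpleNamespace(scaffold_len=1_000_000, breakpoints=[500_000])}
    invs = [
        InversionCall(Interval("q", 499_500, 600_000, "-"), Interval("t", 499_500, 600_000), 1),
        InversionCall(Interval("q", 501_000, 800_000, "-"), Interval("t", 501_000, 800_000), 1),
    ]
    res = boundary_enrichment(invs, maps, d=2000, n_perm=0, seed=0)
    assert res.expected_fraction == pytest.approx(4000 / 1_000_000)
    assert res.observed_fraction == pytest.approx(0.5)
    assert res.enrichment == pytest.approx(125.0)


def test_zero_inversions_vacuous_enrichment():
    maps = {"q": SimpleNamespace(scaffold_len=1_000_000, breakpoints=[500_000])}
    res = boundary_enrichment([], maps, d=2000, n_perm=10, seed=0)
    assert res.observed_fraction == 0.0 and res.enrichment == 0.0 and res.perm_p == 1.0


def test_permutation_p_super_uniform_under_null():
    """Null-generated boundaries give p-values no smaller than uniform."""
    rng = np.random.default_rng(37)
    L = 2_000_000
    maps = {
        "q": SimpleNamespace(
            scaffold_len=L, breakpoints=sorted(int(x) for x in rng.integers(0, L, 20))
        )
    }
    alpha = 0.25
    hits = 0
    reps = 50
    for rep in range(reps):
        invs = []
        for s in rng.integers(0, L - 50_000, 10):
            invs.append(
                InversionCall(
                    Interval("q", int(s), int(s) + 50_000, "-"),
                    Interval("t", int(s), int(s) + 50_000), 1,
                )
            )
        res = boundary_enrichment(invs, maps, d=2000, n_perm=200, seed=1000 + rep)
        if res.perm_p <= alpha:
            hits += 1
    bound = alpha * reps + 3 * math.sqrt(reps * alpha * (1 - alpha))
    assert hits <= bound


def test_syri_import_reads_inv_rows(tmp_path):
    p = tmp_path / "syri.out"
    p.write_text(
        "t1\t1001\t2000\t-\t-\tq1\t5001\t6000\tINV1\t-\tINV\t-\n"
        "t1\t3001\t4000\t-\t-\tq1\t7001\t8000\tSYN1\t-\tSYN\t-\n"
    )
    calls = import_syri(str(p))
    assert len(calls) == 1
    c = calls[0]
    assert (c.target_region.start, c.target_region.end) == (1000, 2000)
    assert (c.query_region.start, c.query_region.end) == (5000, 6000)
    assert c.source == "imported"
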