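"""Enhancer compilation, activity, gene linking, null and ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from nascentarch.core_model import ExpressionMatrix, SignalTrack, TssPeak
from nascentarch.bidirectional_analysis import BidirectionalPair
from nascentarch.enhancer_analysis import (
    EnhancerRecord,
    activity,
    activity_matrix,
    compile_enhancers,
    gene_correlations,
    null_distribution,
    rank,
    select_targets,
)


def _peak(pid, summit, strand, category="unstable", chrom="chr1", gene=None):
    return TssPeak(pid, chrom, summit - 50, summit + 50, strand,
                   summit=summit, category=category, assigned_gene=gene)


def _m(rows):
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# compile
# ---------------------------------------------------------------------------


def _compile(nc_pairs=(), uni=(), pc=(), lengths=None):
    peaks_by_id = {}
    for pair in nc_pairs:
        pass
    for p in list(uni) + list(pc):
        peaks_by_id[p.peak_id] = p
    return compile_enhancers(list(nc_pairs), list(uni), list(pc),
                             peaks_by_id, lengths)


def test_ncnc_pair_resized_to_500_centered():
    a, b = _peak("a", 10_000, "-"), _peak("b", 10_299, "+")
    pair = BidirectionalPair("a", "b", "ncTSS-ncTSS", 299)
    (rec,) = compile_enhancers([pair], [], [], {"a": a, "b": b})
    assert rec.width == 500
    assert (rec.start + rec.end) // 2 == (10_000 + 10_300) // 2
    assert rec.source == "bidirectional_nc"


def test_wide_ncnc_span_kept():
    a, b = _peak("a", 10_000, "-"), _peak("b", 10_799, "+")
    pair = BidirectionalPair("a", "b", "ncTSS-ncTSS", 799)
    (rec,) = compile_enhancers([pair], [], [], {"a": a, "b": b})
    assert rec.width == 800


def test_unidirectional_500_centered_on_summit():
    p = _peak("u", 20_000, "+")
    (rec,) = _compile(uni=[p])
    assert (rec.start, rec.end) == (19_750, 20_250)
    assert rec.source == "unidirectional_intergenic"


def test_candidate_trimmed_below_500_dropped():
    # promoter window [19930-400, 19930+100] eats the right flank: 430 bp left
    p = _peak("u", 20_000, "+")
    pc = _peak("g", 20_180, "+", "mRNA", gene="g1")
    assert _compile(uni=[p], pc=[pc]) == []


def test_candidate_trimmed_but_surviving_is_kept():
    a, b = _peak("a", 10_000, "-"), _peak("b", 10_799, "+")
    pair = BidirectionalPair("a", "b", "ncTSS-ncTSS", 799)
    pc = _peak("g", 10_149, "+", "mRNA", gene="g1")  # window [9749, 10250)
    (rec,) = compile_enhancers([pair], [], [pc],
                               {"a": a, "b": b, "g": pc})
    assert (rec.start, rec.end) == (10_250, 10_800)


def test_region_clipped_to_chromosome_with_warning():
    p = _peak("u", 200, "+")
    with pytest.warns(UserWarning, match="clipped"):
        out = _compile(uni=[p], lengths={"chr1": 100_000})
    assert out == [] or out[0].start >= 0


def test_no_overlap_with_pc_promoter_windows(micro_result):
    windows = []
    for p in micro_result.peaks:
        if p.category == "mRNA":
            from nascentarch.core_model import oriented_window
            windows.append((p.chrom,) + oriented_window(p.summit, p.strand,
                                                        400, 100))
    for rec in micro_result.enhancers:
        assert rec.width >= 500
        for chrom, lo, hi in windows:
            if chrom == rec.chrom:
                assert hi <= rec.start or lo >= rec.end


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------


def test_activity_sums_both_strands():
    track = SignalTrack({"chr1": 1_000})
    track.add("chr1", "+", 100, 105, 2.0)
    track.add("chr1", "-", 110, 115, 0.5)
    rec = EnhancerRecord("e", "chr1", 100, 120, "unidirectional_intergenic", ())
    assert activity(rec, track) == pytest.approx(12.5)


def test_activity_zero_track():
    rec = EnhancerRecord("e", "chr1", 100, 600, "unidirectional_intergenic", ())
    assert activity(rec, SignalTrack({"chr1": 1_000})) == 0.0


def test_activity_additive_over_partition(rng):
    track = SignalTrack({"chr1": 10_000})
    track.add_at("chr1", "+", rng.integers(0, 10_000, size=500))
    track.add_at("chr1", "-", rng.integers(0, 10_000, size=500))
    whole = EnhancerRecord("e", "chr1", 1_000, 2_000, "bidirectional_nc", ())
    left = EnhancerRecord("l", "chr1", 1_000, 1_500, "bidirectional_nc", ())
    right = EnhancerRecord("r", "chr1", 1_500, 2_000, "bidirectional_nc", ())
    assert activity(whole, track) == pytest.approx(
        activity(left, track) + activity(right, track)
    )


# ---------------------------------------------------------------------------
# gene correlations and target selection
# ---------------------------------------------------------------------------


def _linked_setup():
    rec = EnhancerRecord("e", "chr1", 10_000, 10_500,
                         "unidirectional_intergenic", ())
    rec.activity = np.array([1.0, 5, 3, 9, 2, 4])
    pc_in = _peak("gin", 10_100, "+", "mRNA", gene="gin")
    pc_near = _peak("gnear", 14_000, "+", "mRNA", gene="gnear")
    pc_far = _peak("gfar", 16_600, "+", "mRNA", gene="gfar")  # 6.1 kb away
    m = _m({
        "gin": [2.0, 10, 6, 18, 4, 8],          # proportional -> r = 1
        "gnear": [1.0, 1, 2, 1, 9, 1],
        "gfar": [1.0, 5, 3, 9, 2, 4],
    })
    return rec, [pc_in, pc_near, pc_far], m


def test_gene_inside_region_distance_zero_and_proportional_r_one():
    rec, pcs, m = _linked_setup()
    gene_correlations([rec], pcs, m)
    linked = {g: (d, r) for g, d, r in rec.linked_genes}
    assert linked["gin"][0] == 0
    assert linked["gin"][1] == pytest.approx(1.0)
    assert linked["gnear"][0] == 14_000 - 10_500 + 1


def test_gene_beyond_window_not_linked():
    rec, pcs, m = _linked_setup()
    gene_correlations([rec], pcs, m)
    assert "gfar" not in {g for g, _, _ in rec.linked_genes}


def test_select_targets_boundary_and_dedup():
    r1 = EnhancerRecord("e1", "chr1", 0, 500, "bidirectional_nc", ())
    r1.linked_genes = [("gA", 10, 0.5), ("gB", 10, 0.49)]
    r2 = EnhancerRecord("e2", "chr1", 900, 1_400, "bidirectional_nc", ())
    r2.linked_genes = [("gA", 10, 0.6), ("gC", 10, 0.2)]
    assert select_targets([r1, r2]) == ["gA"]


# ---------------------------------------------------------------------------
# null distribution
# ---------------------------------------------------------------------------


def _null_setup(rng, n_rec=5, n_pc=20):
    recs = []
    for i in range(n_rec):
        rec = EnhancerRecord(f"e{i}", f"chr{i % 2 + 1}", 0, 500,
                             "bidirectional_nc", ())
        rec.activity = rng.uniform(1, 100, size=6)
        recs.append(rec)
    pcs = [_peak(f"g{i}", 1_000 * i + 500, "+", "mRNA",
                 chrom=f"chr{i % 3 + 1}") for i in range(n_pc)]
    m = _m({f"g{i}": list(rng.uniform(1, 100, size=6)) for i in range(n_pc)})
    return recs, pcs, m


def test_null_deterministic_given_seed(rng):
    recs, pcs, m = _null_setup(rng)
    a = null_distribution(recs, pcs, m, 200, seed=5)
    b = null_distribution(recs, pcs, m, 200, seed=5)
    assert a == b and len(a) == 200


def test_null_zero_draws_empty(rng):
    recs, pcs, m = _null_setup(rng)
    assert null_distribution(recs, pcs, m, 0, seed=1) == []


def test_null_single_chromosome_is_an_error(rng):
    recs, pcs, m = _null_setup(rng)
    one_chrom = [r for r in recs if r.chrom == "chr1"]
    for r in one_chrom:
        r.chrom = "chr1"
    pcs1 = [p for p in pcs if p.chrom == "chr1"]
    with pytest.raises(ValueError, match="2 chromosomes"):
        null_distribution(one_chrom, pcs1, m, 10, seed=1)


# ---------------------------------------------------------------------------
# rank
# ---------------------------------------------------------------------------


def _ranked_records(n, rng):
    recs = []
    for i in range(n):
        rec = EnhancerRecord(f"e{i:03d}", "chr1", 0, 500, "bidirectional_nc", ())
        rec.activity = np.array([float(i), 0.0])
        recs.append(rec)
    return recs


def test_rank_disjoint_sets(rng):
    recs = _ranked_records(40, rng)
    top, bottom = rank(recs, "s0", ["s0", "s1"], n=10)
    assert len(top) == len(bottom) == 10
    assert not ({r.enhancer_id for r in top}
                & {r.enhancer_id for r in bottom})
    assert top[0].enhancer_id == "e039"
    assert bottom[-1].enhancer_id == "e000"


def test_rank_caps_with_warning(rng):
    recs = _ranked_records(10, rng)
    with pytest.warns(UserWarning, match="capped"):
        top, bottom = rank(recs, "s0", ["s0", "s1"], n=500)
    assert len(top) == len(bottom) == 5


def test_rank_invariant_under_permutation(rng):
    recs = _ranked_records(30, rng)
    top1, _ = rank(recs, "s0", ["s0", "s1"], n=5)
    shuffled = [recs[i] for i in rng.permutation(30)]
    top2, _ = rank(shuffled, "s0", ["s0", "s1"], n=5)
    assert [r.enhancer_id for r in top1] == [r.enhancer_id for r in top2]
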