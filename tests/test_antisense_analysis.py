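"""Antisense pairing geometry, proximal/distal rule, ratios, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from nascentarch.core_model import (
    ExpressionMatrix,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    TssPeak,
)
from nascentarch.antisense_analysis import (
    AntisensePair,
    classify_antisense,
    cluster_enrichment,
    correlated_pair_partition,
    find_antisense,
    pair_correlation,
    sense_antisense_ratio,
)


def _gene(gid="g1", start=10_000, end=14_000, strand="+"):
    return GeneModel(gene_id=gid, chrom="chr1", start=start, end=end,
                     strand=strand, biotype="protein_coding",
                     transcripts=[TranscriptModel(f"{gid}.1", start, end)])


def _simple_matrix(rows: dict[str, list[float]]):
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


def _peak(pid, summit, strand, category="unstable", gene=None):
    return TssPeak(pid, "chr1", summit - 50, summit + 50, strand,
                   summit=summit, category=category, assigned_gene=gene)


def _setup(anti_summit, gene=None):
    gene = gene or _gene()
    ann = GenomeAnnotation([("chr1", 100_000)], [gene])
    sense = _peak("sense", gene.tss, gene.strand, "mRNA", gene.gene_id)
    anti_strand = "-" if gene.strand == "+" else "+"
    anti = _peak("anti", anti_summit, anti_strand)
    matrix = _simple_matrix({"sense": [40, 10, 5, 1], "anti": [5, 2, 1, 1]})
    return ann, [sense, anti], matrix


# ---------------------------------------------------------------------------
# find_antisense
# ---------------------------------------------------------------------------


def test_antisense_inside_gene_body_is_paired():
    ann, peaks, m = _setup(anti_summit=11_600)    # 40% through a 4 kb gene
    (pair,) = find_antisense(peaks, ann, m)
    assert pair.gene_id == "g1" and pair.antisense_peak_id == "anti"
    assert pair.distance_from_gene_tss == 1_600


def test_antisense_within_tts_extension_is_paired():
    ann, peaks, m = _setup(anti_summit=14_149)    # 150 bp past the TTS
    (pair,) = find_antisense(peaks, ann, m)
    assert pair.distance_from_tts == -150


def test_antisense_beyond_extension_is_not_paired():
    ann, peaks, m = _setup(anti_summit=14_249)    # 250 bp past the TTS
    assert find_antisense(peaks, ann, m) == []


def test_antisense_same_strand_not_paired():
    gene = _gene()
    ann = GenomeAnnotation([("chr1", 100_000)], [gene])
    sense = _peak("sense", gene.tss, "+", "mRNA", "g1")
    inside_same = _peak("x", 11_000, "+")
    m = _simple_matrix({"sense": [1, 2, 3], "x": [1, 2, 3]})
    assert find_antisense([sense, inside_same], ann, m) == []


def test_antisense_multi_gene_overlap_resolved_to_nearest_tss():
    g1 = _gene("gA", 10_000, 16_000, "+")
    g2 = _gene("gB", 12_000, 18_000, "+")
    ann = GenomeAnnotation([("chr1", 100_000)], [g1, g2])
    peaks = [
        _peak("sA", 10_000, "+", "mRNA", "gA"),
        _peak("sB", 12_000, "+", "mRNA", "gB"),
        _peak("anti", 12_500, "-"),
    ]
    m = _simple_matrix({p.peak_id: [3, 2, 1] for p in peaks})
    (pair,) = find_antisense(peaks, ann, m)
    assert pair.gene_id == "gB"                   # 500 bp vs 2500 bp


def test_antisense_gene_without_sense_tss_dropped(caplog):
    gene = _gene()
    ann = GenomeAnnotation([("chr1", 100_000)], [gene])
    anti = _peak("anti", 11_000, "-")
    m = _simple_matrix({"anti": [1, 2, 3]})
    with caplog.at_level("INFO"):
        assert find_antisense([anti], ann, m) == []
    assert "no detected sense TSS" in caplog.text


# ---------------------------------------------------------------------------
# classify_antisense
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "length,offset,expected",
    [
        (4_000, 1_000, "proximal"),   # 25% in, 2999 bp from TTS
        (4_000, 3_500, "distal"),     # past the midpoint
        (1_500, 600, "distal"),       # 40% in but TTS distance 899 <= 1000
        (4_000, 2_000, "distal"),     # exactly 50%: boundary -> distal
    ],
)
def test_proximal_distal_rule(length, offset, expected):
    gene = _gene(end=10_000 + length)
    pair = AntisensePair("g1", "s", "a",
                         distance_from_gene_tss=offset,
                         distance_from_tts=length - 1 - offset)
    assert classify_antisense(pair, gene) == expected


def test_classification_is_deterministic_and_total(micro_result):
    classes = [a.antisense_class for a in micro_result.antisense_pairs]
    assert set(classes) <= {"proximal", "distal"}
    assert all(c is not None for c in classes)


# ---------------------------------------------------------------------------
# ratio and correlation
# ---------------------------------------------------------------------------


def test_ratio_max_over_max():
    pair = AntisensePair("g1", "sense", "anti")
    m = _simple_matrix({"sense": [40, 10, 2], "anti": [5, 1, 0]})
    assert sense_antisense_ratio(pair, m) == 8.0


def test_ratio_equal_maxima_is_one():
    pair = AntisensePair("g1", "sense", "anti")
    m = _simple_matrix({"sense": [7, 1, 0], "anti": [0, 7, 2]})
    assert sense_antisense_ratio(pair, m) == 1.0


def test_ratio_zero_antisense_flagged():
    pair = AntisensePair("g1", "sense", "anti")
    m = _simple_matrix({"sense": [7, 1, 0], "anti": [0, 0, 0]})
    assert math.isnan(sense_antisense_ratio(pair, m))
    assert not pair.ratio_defined


def test_ratio_excludes_mutant_samples():
    pair = AntisensePair("g1", "sense", "anti")
    df = pd.DataFrame({"s0": [10, 5], "s1": [20, 2], "mut": [999, 999]},
                      index=["sense", "anti"])
    m = ExpressionMatrix(df, mutant_samples=["mut"])
    assert sense_antisense_ratio(pair, m) == 4.0


def test_correlation_identical_profiles():
    pair = AntisensePair("g1", "sense", "anti")
    m = _simple_matrix({"sense": [1, 5, 3, 9], "anti": [1, 5, 3, 9]})
    assert pair_correlation(pair, m) == pytest.approx(1.0)


def test_correlation_negated_about_mean():
    pair = AntisensePair("g1", "sense", "anti")
    x = np.array([1.0, 5, 3, 9])
    m = _simple_matrix({"sense": list(x), "anti": list(2 * x.mean() - x)})
    assert pair_correlation(pair, m) == pytest.approx(-1.0)


def test_correlation_constant_vector_undefined():
    pair = AntisensePair("g1", "sense", "anti")
    m = _simple_matrix({"sense": [1, 5, 3], "anti": [2, 2, 2]})
    assert math.isnan(pair_correlation(pair, m))


def test_correlation_needs_three_samples():
    pair = AntisensePair("g1", "sense", "anti")
    m = _simple_matrix({"sense": [1, 5], "anti": [2, 3]})
    with pytest.raises(ValueError, match="3 samples"):
        pair_correlation(pair, m)


# ---------------------------------------------------------------------------
# cluster enrichment
# ---------------------------------------------------------------------------


def test_enrichment_null_case():
    stat, p = cluster_enrichment([20, 20], [100, 100], 0.2)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_enrichment_hand_computed_statistic():
    stat, p = cluster_enrichment([30, 10], [100, 100], 0.2)
    assert stat == pytest.approx(10.0)            # (10^2 + 10^2) / 20


def test_enrichment_single_cluster_is_an_error():
    with pytest.raises(ValueError, match="2 clusters"):
        cluster_enrichment([5], [10], 0.5)


def test_enrichment_zero_expected_is_an_error():
    with pytest.raises(ValueError, match="expected"):
        cluster_enrichment([0, 5], [10, 10], 0.0)


def test_enrichment_matches_textbook_chi_square(rng):
    for _ in range(100):
        k = int(rng.integers(2, 8))
        sizes = rng.integers(20, 200, size=k)
        frac = float(rng.uniform(0.05, 0.5))
        obs = rng.binomial(sizes, frac)
        stat, p = cluster_enrichment(obs, sizes, frac)
        exp = frac * sizes
        stat2, p2 = chisquare(obs, exp * (obs.sum() / exp.sum()))
        # same formula up to the expected-count normalization scipy applies;
        # check the raw statistic against a direct loop instead
        direct = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert stat == pytest.approx(direct)
        assert 0 <= p <= 1


# ---------------------------------------------------------------------------
# correlation partition
# ---------------------------------------------------------------------------


def test_partition_bounds():
    pairs = []
    for r in (0.6, -0.3, 0.1, math.nan):
        p = AntisensePair("g", "s", "a")
        p.pearson_r = r
        pairs.append(p)
    out = correlated_pair_partition(pairs)
    assert [p.pearson_r for p in out["positive"]] == [0.6]
    assert [p.pearson_r for p in out["negative"]] == [-0.3]
    assert len(out["other"]) == 2
    assert sum(map(len, out.values())) == 4
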