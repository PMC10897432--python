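"""Signal metrics: summits, 80%-widths, TMM, CV, heatmap rows.

The width oracle enumerates all windows (O(N^2)); the TMM oracle re-codes
the trimmed-mean-of-M-values definition with plain loops, independently of
the vectorized implementation, and one test cross-checks edgeR itself.
"""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from nascentarch.core_model import ExpressionMatrix, SignalTrack, TssPeak
from nascentarch.tss_metrics import (
    coefficient_of_variation,
    constitutive_set,
    find_summit,
    heatmap_matrix,
    tmm_normalize,
    width80,
)


def _track(counts: dict[int, float], strand="+") -> SignalTrack:
    t = SignalTrack({"chr1": 10_000})
    for pos, v in counts.items():
        t.add("chr1", strand, pos, pos + 1, v)
    return t


def _peak(start, end, strand="+"):
    return TssPeak("p", "chr1", start, end, strand)


# ---------------------------------------------------------------------------
# Summit
# ---------------------------------------------------------------------------


def test_summit_is_position_of_max_pileup():
    assert find_summit(_peak(0, 100), _track({10: 5, 12: 9, 20: 3})) == 12


def test_summit_tie_breaks_leftmost():
    assert find_summit(_peak(0, 100), _track({10: 5, 12: 5})) == 10


def test_summit_requires_signal():
    with pytest.raises(ValueError, match="no signal"):
        find_summit(_peak(0, 100), _track({}))


# ---------------------------------------------------------------------------
# width80
# ---------------------------------------------------------------------------


def width80_oracle(vals: np.ndarray, fraction: float) -> int:
    """All-windows enumeration: smallest window with >= ceil(frac*N) starts."""
    total = vals.sum()
    target = math.ceil(fraction * total - 1e-9)
    best = len(vals)
    for i in range(len(vals)):
        acc = 0.0
        for j in range(i, len(vals)):
            acc += vals[j]
            if acc >= target:
                best = min(best, j - i + 1)
                break
    return best


def test_width80_single_position():
    assert width80(_peak(0, 50), _track({10: 10})) == 1


def test_width80_concentrated_counts():
    # 50+30 of 100 starts within [100, 105] -> 6 bp window holds 80%
    assert width80(_peak(90, 120), _track({100: 50, 105: 30, 110: 20})) == 6


def test_width80_uniform_counts():
    assert width80(_peak(0, 10), _track({i: 1 for i in range(10)})) == 8


def test_width80_matches_all_windows_oracle(rng):
    track = SignalTrack({"chr1": 100_000})
    for k in range(200):
        start = int(rng.integers(0, 99_000))
        width = int(rng.integers(5, 60))
        n = int(rng.integers(1, 40))
        pos = start + rng.integers(0, width, size=n)
        track.add_at("chr1", "+", pos)
        peak = _peak(start, start + width)
        vals = track.values("chr1", "+", start, start + width)
        assert width80(peak, track) == width80_oracle(vals, 0.8), k
        track = SignalTrack({"chr1": 100_000})  # isolate peaks


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _avg_rank(values):
    """1-based average-tie ranks, coded independently of scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(mat: np.ndarray) -> np.ndarray:
    """Brute-force TMM factors from the published definition."""
    n_feat, n_samp = mat.shape
    lib = [float(mat[:, j].sum()) for j in range(n_samp)]
    q75 = [float(np.quantile(mat[:, j], 0.75)) / lib[j] for j in range(n_samp)]
    mean_q = sum(q75) / n_samp
    ref = min(range(n_samp), key=lambda j: abs(q75[j] - mean_q))

    factors = []
    for j in range(n_samp):
        M, A, w = [], [], []
        for i in range(n_feat):
            o, r = mat[i, j], mat[i, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            M.append(math.log2(po / pr))
            A.append(0.5 * (math.log2(po) + math.log2(pr)))
            w.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not M or max(abs(m) for m in M) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        loL, loS = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
        hiL, hiS = n + 1 - loL, n + 1 - loS
        rM, rA = _avg_rank(M), _avg_rank(A)
        num = den = 0.0
        for i in range(n):
            if loL <= rM[i] <= hiL and loS <= rA[i] <= hiS:
                num += M[i] / w[i]
                den += 1.0 / w[i]
        factors.append(2.0 ** (num / den) if den else 1.0)

    log_mean = sum(math.log(f) for f in factors) / n_samp
    return np.array([f / math.exp(log_mean) for f in factors])


def test_tmm_identical_libraries_give_unit_factors():
    df = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]})
    np.testing.assert_allclose(tmm_normalize(df).factors.values, [1.0, 1.0])


def test_tmm_proportional_libraries_give_unit_factors():
    a = np.array([4, 9, 100, 2, 55])
    df = pd.DataFrame({"a": a, "b": 2 * a})
    res = tmm_normalize(df)
    np.testing.assert_allclose(res.factors.values, [1.0, 1.0], atol=1e-12)
    # the doubling is absorbed by library size: CPM rows identical
    np.testing.assert_allclose(res.cpm["a"], res.cpm["b"])


def test_tmm_matches_brute_force_oracle(rng):
    for _ in range(20):
        mat = rng.negative_binomial(5, 0.3, size=(500, 4)) * rng.integers(
            1, 4, size=(500, 4)
        )
        df = pd.DataFrame(mat, columns=list("abcd"))
        res = tmm_normalize(df)
        np.testing.assert_allclose(
            res.factors.values, tmm_oracle(mat.astype(float)), atol=1e-8
        )


def test_tmm_scale_invariance_is_approximate(rng):
    """Scaling a library moves M/A values not at all, so factors are nearly
    invariant — but the inverse-variance weights depend on absolute counts,
    so the invariance is only approximate (the reference implementation
    shows the identical shift)."""
    mat = rng.negative_binomial(8, 0.4, size=(300, 3)).astype(float)
    df = pd.DataFrame(mat, columns=list("abc"))
    base = tmm_normalize(df).factors.values
    df2 = df.copy()
    df2["b"] = df2["b"] * 7.0
    np.testing.assert_allclose(tmm_normalize(df2).factors.values, base,
                               rtol=0.02)


def test_tmm_all_zero_sample_names_the_sample():
    df = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
    with pytest.raises(ValueError, match="empty"):
        tmm_normalize(df)


def test_tmm_cpm_invariant():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.poisson(40, size=(200, 3)), columns=list("abc"))
    res = tmm_normalize(df)
    assert abs(np.exp(np.mean(np.log(res.factors))) - 1) < 1e-9
    expected = df.values / (res.lib_sizes.values * res.factors.values) * 1e6
    np.testing.assert_allclose(res.cpm.values, expected)


def test_tmm_agrees_with_edger():
    """Cross-check the in-package TMM against the reference implementation."""
    if shutil.which("Rscript") is None:
        pytest.xfail("Rscript not on PATH")
    rng = np.random.default_rng(99)
    mat = rng.negative_binomial(6, 0.35, size=(400, 5))
    df = pd.DataFrame(mat, columns=[f"s{i}" for i in range(5)])
    ours = tmm_normalize(df).factors.values
    script = (
        "suppressMessages(library(edgeR));"
        "m <- matrix(scan('stdin', quiet=TRUE), ncol=5, byrow=TRUE);"
        "cat(sprintf('%.12f ', calcNormFactors(m, method='TMM')))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script],
        input="\n".join(" ".join(map(str, row)) for row in mat),
        capture_output=True, text=True, check=True,
    )
    theirs = np.array([float(x) for x in out.stdout.split()])
    np.testing.assert_allclose(ours, theirs, atol=1e-6)


# ---------------------------------------------------------------------------
# CV / constitutive set
# ---------------------------------------------------------------------------


def test_cv_constant_row_is_zero():
    assert coefficient_of_variation(np.array([20.0, 20, 20])) == 0.0


def test_cv_zero_mean_is_undefined():
    assert math.isnan(coefficient_of_variation(np.zeros(4)))


def test_constitutive_set_filters_min_expression_then_ranks(rng):
    n = 700
    vals = rng.uniform(60, 200, size=(n, 4))
    vals[0] = [49, 100, 100, 100]           # min below threshold: excluded
    df = pd.DataFrame(vals, index=[f"f{i}" for i in range(n)],
                      columns=list("abcd"))
    chosen = constitutive_set(ExpressionMatrix(df), min_cpm=50, top_n=500)
    assert len(chosen) == 500
    assert "f0" not in chosen
    cvs = {f: coefficient_of_variation(df.loc[f].to_numpy()) for f in df.index
           if df.loc[f].min() >= 50}
    cutoff = sorted(cvs.values())[499]
    assert all(cvs[f] <= cutoff for f in chosen)


def test_constitutive_set_warns_when_short():
    df = pd.DataFrame(np.full((3, 4), 60.0), index=list("xyz"),
                      columns=list("abcd"))
    with pytest.warns(UserWarning, match="3 features"):
        out = constitutive_set(ExpressionMatrix(df), min_cpm=50, top_n=500)
    assert sorted(out) == list("xyz")


# ---------------------------------------------------------------------------
# Heatmap rows
# ---------------------------------------------------------------------------


def test_heatmap_zero_window_row_is_zero():
    track = SignalTrack({"chr1": 1000})
    rows, flags = heatmap_matrix([("chr1", 100, 200, "+")], track)
    assert (rows == 0).all() and flags == [False]


def test_heatmap_sense_only_in_unit_interval_and_antisense_negative():
    track = SignalTrack({"chr1": 1000})
    # dense enough that the per-window 90th-percentile cap stays positive
    track.add_at("chr1", "+", np.repeat(np.arange(110, 160), 2))
    rows, _ = heatmap_matrix([("chr1", 100, 200, "+")], track)
    assert rows.min() >= 0 and rows.max() <= 1 and rows.max() > 0
    rows, _ = heatmap_matrix([("chr1", 100, 200, "-")], track)
    assert rows.max() <= 0 and rows.min() >= -1 and rows.min() < 0


def test_heatmap_trim_and_rescale_matches_direct_recomputation():
    track = SignalTrack({"chr1": 1000})
    vals = np.arange(10.0)
    for i, v in enumerate(vals):
        track.add("chr1", "+", 100 + i, 101 + i, v)
    rows, _ = heatmap_matrix([("chr1", 100, 110, "+")], track)
    capped = np.minimum(vals, np.percentile(vals, 90))
    expect = (capped - capped.min()) / (capped.max() - capped.min())
    np.testing.assert_allclose(rows[0], expect)


def test_heatmap_invariant_under_spike_above_cap(rng):
    track = SignalTrack({"chr1": 1000})
    track.add_at("chr1", "+", rng.integers(100, 200, size=80))
    base, _ = heatmap_matrix([("chr1", 100, 200, "+")], track)
    vals = track.values("chr1", "+", 100, 200)
    spike_pos = 100 + int(np.argmax(vals))
    track.add("chr1", "+", spike_pos, spike_pos + 1, 1000.0)
    spiked, _ = heatmap_matrix([("chr1", 100, 200, "+")], track)
    np.testing.assert_allclose(spiked, base)


def test_heatmap_off_chromosome_window_padded_and_flagged():
    track = SignalTrack({"chr1": 150})
    track.add("chr1", "+", 140, 150, 2.0)
    rows, flags = heatmap_matrix([("chr1", 100, 200, "+")], track)
    assert flags == [True]
    assert (rows[0][50:] == 0).all()


def test_heatmap_minus_window_reversed_downstream_rightward():
    track = SignalTrack({"chr1": 1000})
    for i in range(10):
        track.add("chr1", "-", 190 + i, 191 + i, float(i))
    rows, _ = heatmap_matrix([("chr1", 190, 200, "-")], track)
    # highest value sat at the genomic right edge; after the minus-strand
    # flip it appears at the left (downstream is rightward)
    assert rows[0][0] == 1.0 and rows[0][-1] == 0.0
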