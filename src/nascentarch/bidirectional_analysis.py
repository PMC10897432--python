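"""Bidirectional / divergent promoter detection and statistics.

An opposite-facing candidate is a minus-strand summit m and a plus-strand
summit p with m <= p (transcription pointing away from each other); pairs
with p - m <= 500 bp are accepted as bidirectional promoters.  Matching is
one pair per peak, greedy by ascending inter-TSS distance.  Pairs are typed
by member categories (mRNA -> protein-coding, everything else ->
non-coding): pcTSS-pcTSS, ncTSS-pcTSS (divergent), ncTSS-ncTSS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_model import AnalysisParameters, ExpressionMatrix, SignalTrack, TssPeak
from .antisense_analysis import pearson
from .tss_metrics import heatmap_matrix

__all__ = [
    "BidirectionalPair",
    "find_pairs",
    "correlation_distance_table",
    "max_cpm_ratio",
    "corr_groups",
    "paired_heatmap",
]

PAIR_TYPES = ("pcTSS-pcTSS", "ncTSS-pcTSS", "ncTSS-ncTSS")


@dataclass
class BidirectionalPair:
    peak_a_id: str                   # minus-strand member
    peak_b_id: str                   # plus-strand member
    pair_type: str
    inter_tss_distance: int
    pearson_r: float = math.nan
    max_cpm_ratio: float = math.nan  # >= 1 when defined
    corr_group: Optional[str] = None
    ratio_defined: bool = True


def _pair_type(cat_a: str, cat_b: str) -> str:
    pc = (cat_a == "mRNA") + (cat_b == "mRNA")
    return ("ncTSS-ncTSS", "ncTSS-pcTSS", "pcTSS-pcTSS")[pc]


def _candidates(peaks: Sequence[TssPeak], max_dist: int):
    """All divergent-geometry (minus, plus) summit pairs within max_dist."""
    by_chrom: dict[str, dict[str, list[TssPeak]]] = {}
    for p in peaks:
        if p.summit is None:
            continue
        by_chrom.setdefault(p.chrom, {"+": [], "-": []})[p.strand].append(p)
    for chrom, strands in sorted(by_chrom.items()):
        minus = sorted(strands["-"], key=lambda p: (p.summit, p.peak_id))
        plus = sorted(strands["+"], key=lambda p: (p.summit, p.peak_id))
        plus_summits = np.array([p.summit for p in plus])
        for m in minus:
            lo = int(np.searchsorted(plus_summits, m.summit, side="left"))
            hi = int(np.searchsorted(plus_summits, m.summit + max_dist,
                                     side="right"))
            for p in plus[lo:hi]:
                yield m, p, p.summit - m.summit


def find_pairs(
    peaks: Sequence[TssPeak],
    params: Optional[AnalysisParameters] = None,
) -> list[BidirectionalPair]:
    """Accepted bidirectional pairs: divergent geometry, distance <=
    ``bidir_max_dist``, greedy one-pair-per-peak matching by ascending
    distance (ties by leftmost minus member, then ids)."""
    params = params or AnalysisParameters()
    cands = sorted(
        _candidates(peaks, params.bidir_max_dist),
        key=lambda t: (t[2], t[0].summit, t[0].peak_id, t[1].peak_id),
    )
    used: set[str] = set()
    pairs: list[BidirectionalPair] = []
    for m, p, d in cands:
        if m.peak_id in used or p.peak_id in used:
            continue
        used.update((m.peak_id, p.peak_id))
        pairs.append(
            BidirectionalPair(
                peak_a_id=m.peak_id,
                peak_b_id=p.peak_id,
                pair_type=_pair_type(m.category, p.category),
                inter_tss_distance=d,
            )
        )
    return pairs


def correlation_distance_table(
    peaks: Sequence[TssPeak],
    matrix: ExpressionMatrix,
    max_dist: int = 2000,
) -> pd.DataFrame:
    """Every opposite-facing candidate up to ``max_dist`` (no 500 bp cut),
    with its pair type, inter-TSS distance and time-course Pearson r.

    One row per candidate; smoothing (for correlation-vs-distance plots) is
    left to the plotting layer.
    """
    rows = []
    for m, p, d in _candidates(peaks, max_dist):
        if m.peak_id not in matrix or p.peak_id not in matrix:
            continue
        r = pearson(
            matrix.row(m.peak_id, masked=True),
            matrix.row(p.peak_id, masked=True),
        )
        rows.append(
            dict(peak_a_id=m.peak_id, peak_b_id=p.peak_id,
                 pair_type=_pair_type(m.category, p.category),
                 distance=d, pearson_r=r)
        )
    return pd.DataFrame(
        rows, columns=["peak_a_id", "peak_b_id", "pair_type", "distance",
                       "pearson_r"]
    )


def max_cpm_ratio(pair: BidirectionalPair, matrix: ExpressionMatrix) -> float:
    """Max CPM of the higher-expressing member over the lower one (>= 1);
    order-free.  A zero lower maximum flags the pair (NaN)."""
    a = float(matrix.row(pair.peak_a_id, masked=True).max())
    b = float(matrix.row(pair.peak_b_id, masked=True).max())
    lo, hi = min(a, b), max(a, b)
    if lo == 0:
        pair.ratio_defined = False
        pair.max_cpm_ratio = math.nan
        return math.nan
    pair.ratio_defined = True
    pair.max_cpm_ratio = hi / lo
    return pair.max_cpm_ratio


@dataclass
class CorrGroupResult:
    groups: dict[str, list[BidirectionalPair]]
    median_log2_ratio: dict[str, float]
    pvalues: dict[tuple[str, str], float]    # Holm-adjusted rank-sum p


def corr_groups(
    pairs: Sequence[BidirectionalPair],
    bound: float = 0.25,
) -> CorrGroupResult:
    """Partition pairs by correlation (correlating: r > bound;
    anti-correlating: r < -bound; other) and compare the groups'
    log2 max-CPM-ratio distributions with two-sided rank-sum tests,
    Holm-corrected."""
    groups: dict[str, list[BidirectionalPair]] = {
        "correlating": [], "anti-correlating": [], "other": []
    }
    for p in pairs:
        r = p.pearson_r
        if not math.isnan(r) and r > bound:
            g = "correlating"
        elif not math.isnan(r) and r < -bound:
            g = "anti-correlating"
        else:
            g = "other"
        p.corr_group = g
        groups[g].append(p)

    def _ratios(g: str) -> np.ndarray:
        vals = [p.max_cpm_ratio for p in groups[g]
                if p.ratio_defined and not math.isnan(p.max_cpm_ratio)]
        return np.log2(np.asarray(vals)) if vals else np.array([])

    medians = {
        g: (float(np.median(_ratios(g))) if _ratios(g).size else math.nan)
        for g in groups
    }

    nonempty = [g for g in groups if _ratios(g).size > 0]
    raw: dict[tuple[str, str], float] = {}
    if len(nonempty) < 2:
        warnings.warn("all pairs fall in one correlation group; "
                      "between-group comparison skipped")
    else:
        for i, g1 in enumerate(nonempty):
            for g2 in nonempty[i + 1:]:
                _, pval = mannwhitneyu(_ratios(g1), _ratios(g2),
                                       alternative="two-sided")
                raw[(g1, g2)] = float(pval)
    adjusted: dict[tuple[str, str], float] = {}
    if raw:
        keys = list(raw)
        _, adj, _, _ = multipletests([raw[k] for k in keys], method="holm")
        adjusted = {k: float(a) for k, a in zip(keys, adj)}
    return CorrGroupResult(groups=groups, median_log2_ratio=medians,
                           pvalues=adjusted)


def paired_heatmap(
    pairs: Sequence[BidirectionalPair],
    peaks_by_id: dict[str, TssPeak],
    track: SignalTrack,
    half_width: int = 1000,
    trim_pct: float = 90.0,
) -> tuple[np.ndarray, list[BidirectionalPair]]:
    """Signal heatmap rows for pairs, sorted by inter-TSS distance.

    Divergent (ncTSS-pcTSS) windows anchor on the protein-coding member's
    summit in its orientation; ncTSS-ncTSS and pcTSS-pcTSS windows anchor on
    the midpoint between the two summits (plus orientation).  Returns the
    row matrix (values in [-1, 1]) and the row order.
    """
    order = sorted(
        pairs, key=lambda p: (p.inter_tss_distance, p.peak_a_id, p.peak_b_id)
    )
    windows = []
    for pair in order:
        a = peaks_by_id[pair.peak_a_id]
        b = peaks_by_id[pair.peak_b_id]
        if pair.pair_type == "ncTSS-pcTSS":
            pc = a if a.category == "mRNA" else b
            anchor, strand, chrom = pc.summit, pc.strand, pc.chrom
        else:
            anchor = (a.summit + b.summit) // 2
            strand, chrom = "+", a.chrom
        windows.append((chrom, anchor - half_width, anchor + half_width, strand))
    rows, _ = heatmap_matrix(windows, track, trim_pct)
    return rows, order
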