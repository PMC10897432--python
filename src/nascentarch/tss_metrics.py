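"""Per-peak signal metrics and normalization.

Covers the signal-level primitives of the pipeline: peak summits (maximum
5' read-start pileup), the 80%-width statistic (smallest contiguous window
holding 80% of a peak's read starts), trimmed-mean-of-M-values (TMM)
between-library normalization with counts-per-million output, expression
variability (coefficient of variation, constitutive-TSS selection), and the
percentile-trimmed, min-max-rescaled signal matrices used for strand-aware
read-density heatmaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_model import ExpressionMatrix, SignalTrack, TssPeak

__all__ = [
    "NormalizationResult",
    "find_summit",
    "width80",
    "tmm_normalize",
    "coefficient_of_variation",
    "constitutive_set",
    "heatmap_matrix",
]


# ---------------------------------------------------------------------------
# Summit and width
# ---------------------------------------------------------------------------


def find_summit(peak: TssPeak, track: SignalTrack) -> int:
    """Position of maximal read-start pileup within the peak; leftmost on ties.

    Raises ``ValueError("no signal")`` when the peak holds zero signal, so the
    caller may drop the peak.
    """
    if peak.end <= peak.start:
        raise ValueError(f"peak {peak.peak_id}: empty interval")
    vals = track.values(peak.chrom, peak.strand, peak.start, peak.end)
    if vals.sum() <= 0:
        raise ValueError(f"no signal in peak {peak.peak_id}")
    return peak.start + int(np.argmax(vals))


def width80(peak: TssPeak, track: SignalTrack, fraction: float = 0.8) -> int:
    """Length (bp) of the smallest window holding >= ceil(fraction * N) starts.

    N is the total read-start count within the peak.  Among equal-length
    minimal windows the leftmost is chosen.
    """
    vals = track.values(peak.chrom, peak.strand, peak.start, peak.end)
    total = vals.sum()
    if total <= 0:
        raise ValueError(f"no signal in peak {peak.peak_id}")
    target = math.ceil(fraction * total - 1e-9)
    best = vals.size
    left = 0
    acc = 0.0
    for right in range(vals.size):
        acc += vals[right]
        while acc - vals[left] >= target:
            acc -= vals[left]
            left += 1
        if acc >= target and (right - left + 1) < best:
            best = right - left + 1
    return best


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationResult:
    factors: pd.Series        # per-sample TMM scaling factor, geometric mean 1
    lib_sizes: pd.Series      # per-sample library size (column sum)
    cpm: pd.DataFrame         # count / (lib_size * factor) * 1e6

    def as_expression_matrix(self, mutant_samples: Sequence[str] = ()
                             ) -> ExpressionMatrix:
        return ExpressionMatrix(self.cpm, mutant_samples=mutant_samples)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     n_obs: float, n_ref: float,
                     logratio_trim: float = 0.3,
                     sum_trim: float = 0.05) -> float:
    """TMM factor of one library against the reference.

    Follows the published trimmed-mean-of-M-values definition: M and A values
    on library-size-scaled counts, double trimming (30% on M, 5% on A), and a
    mean of M weighted by the inverse approximate asymptotic (delta-method)
    variance.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        logR = np.log2(p_obs / p_ref)
        absE = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    fin = np.isfinite(logR) & np.isfinite(absE)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0

    n = logR.size
    loL = math.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = math.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rank_m = rankdata(logR)
    rank_a = rankdata(absE)
    keep = (rank_m >= loL) & (rank_m <= hiL) & (rank_a >= loS) & (rank_a <= hiS)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalize(counts: pd.DataFrame) -> NormalizationResult:
    """TMM-normalize a feature x sample raw count matrix and compute CPM.

    The reference library is the sample whose upper-quartile (of counts
    scaled by library size) is closest to the mean upper-quartile.  Factors
    are rescaled to have geometric mean 1 and CPM is computed against the
    effective library size (library size x factor).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    lib_sizes = mat.sum(axis=0)
    for j, s in enumerate(counts.columns):
        if lib_sizes[j] == 0:
            raise ValueError(f"sample {s!r} has an all-zero library")

    q75 = np.array(
        [np.quantile(mat[:, j], 0.75) / lib_sizes[j]
         for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.array(
        [
            _tmm_pair_factor(mat[:, j], mat[:, ref_idx],
                             lib_sizes[j], lib_sizes[ref_idx])
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))

    eff = lib_sizes * factors
    cpm = pd.DataFrame(
        mat / eff[np.newaxis, :] * 1e6,
        index=counts.index, columns=counts.columns,
    )
    return NormalizationResult(
        factors=pd.Series(factors, index=counts.columns),
        lib_sizes=pd.Series(lib_sizes.astype(int), index=counts.columns),
        cpm=cpm,
    )


# ---------------------------------------------------------------------------
# Expression variability
# ---------------------------------------------------------------------------


def coefficient_of_variation(row: np.ndarray) -> float:
    """Sample CV = sd / mean with the n-1 (unbiased) standard deviation.

    Returns NaN for a zero-mean row (CV undefined; such features are
    excluded from constitutive-set ranking).
    """
    row = np.asarray(row, dtype=float)
    mean = row.mean()
    if mean == 0:
        return float("nan")
    return float(row.std(ddof=1) / mean)


def constitutive_set(matrix: ExpressionMatrix, min_cpm: float = 50.0,
                     top_n: int = 500) -> list[str]:
    """Constitutively expressed features: lowest-CV features among those whose
    minimum expression across all samples is at least ``min_cpm``.

    Sorted ascending by CV (ties broken by feature id for determinism); if
    fewer than ``top_n`` features qualify, all are returned with a warning.
    """
    rows = matrix.values
    eligible = rows[rows.min(axis=1) >= min_cpm]
    cvs = {
        fid: coefficient_of_variation(eligible.loc[fid].to_numpy())
        for fid in eligible.index
    }
    ranked = sorted(
        (fid for fid, cv in cvs.items() if not math.isnan(cv)),
        key=lambda fid: (cvs[fid], fid),
    )
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} features pass the constitutive filter "
            f"(requested {top_n})"
        )
        return ranked
    return ranked[:top_n]


# ---------------------------------------------------------------------------
# Heatmap matrices
# ---------------------------------------------------------------------------


def _trim_rescale(vals: np.ndarray, trim_pct: float) -> np.ndarray:
    """Cap at the window's trim percentile, then min-max rescale to [0, 1].

    An all-equal window (including all-zero) maps to all zeros.
    """
    cap = np.percentile(vals, trim_pct)
    capped = np.minimum(vals, cap)
    lo, hi = capped.min(), capped.max()
    if hi == lo:
        return np.zeros_like(capped)
    return (capped - lo) / (hi - lo)


def heatmap_matrix(
    windows: Sequence[tuple[str, int, int, str]],
    track: SignalTrack,
    trim_pct: float = 90.0,
) -> tuple[np.ndarray, list[bool]]:
    """Strand-aware per-window signal rows in [-1, 1].

    ``windows`` are equal-length ``(chrom, start, end, strand)`` anchored
    regions.  Per window and strand, signal is trimmed to the window's
    ``trim_pct`` percentile and min-max rescaled to [0, 1]; the row is the
    rescaled sense-strand signal minus the rescaled antisense-strand signal.
    Minus-strand windows are reversed so downstream is rightward.  Windows
    running off a chromosome end are zero-padded and flagged.

    Returns ``(matrix, padded_flags)``.
    """
    if not windows:
        return np.zeros((0, 0)), []
    width = windows[0][2] - windows[0][1]
    if any(w[2] - w[1] != width for w in windows):
        raise ValueError("all windows must have equal length")

    rows = np.zeros((len(windows), width))
    flags: list[bool] = []
    for i, (chrom, start, end, strand) in enumerate(windows):
        anti = "-" if strand == "+" else "+"
        sense_vals, p1 = track.window(chrom, strand, start, end)
        anti_vals, p2 = track.window(chrom, anti, start, end)
        if strand == "-":
            sense_vals = sense_vals[::-1]
            anti_vals = anti_vals[::-1]
        rows[i] = _trim_rescale(sense_vals, trim_pct) - _trim_rescale(
            anti_vals, trim_pct
        )
        flags.append(bool(p1 or p2))
    return rows, flags
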