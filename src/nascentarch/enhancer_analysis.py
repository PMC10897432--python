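"""Candidate-enhancer compilation, activity scoring, gene linking, ranking.

Candidates come from bidirectional non-coding promoters (ncTSS-ncTSS pairs;
region spans both summits) and intergenic unidirectional ncTSSs (region
centered on the summit), all resized to at least 500 bp.  Candidates
overlapping a detected protein-coding promoter window (-400, +100) are
trimmed away from it and dropped when less than 500 bp survives — a
deterministic, reproducible stand-in for per-case curation.  Activity per
sample is the summed signal of both strands over the region; enhancers are
linked to protein-coding TSSs within 5 kbp by the Pearson correlation of
activity and expression, judged against an inter-chromosomal random-pair
null distribution; targets are genes with r >= 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core_model import (
    AcrPeak,
    AnalysisParameters,
    ExpressionMatrix,
    SignalTrack,
    TssPeak,
    oriented_window,
)
from .antisense_analysis import pearson
from .bidirectional_analysis import BidirectionalPair

__all__ = [
    "EnhancerRecord",
    "compile_enhancers",
    "activity",
    "activity_matrix",
    "attach_acrs",
    "gene_correlations",
    "null_distribution",
    "select_targets",
    "rank",
]


@dataclass
class EnhancerRecord:
    enhancer_id: str
    chrom: str
    start: int
    end: int
    source: str                      # "bidirectional_nc" | "unidirectional_intergenic"
    source_peaks: tuple[str, ...]
    activity: Optional[np.ndarray] = None     # per time-course sample
    overlapping_acr: Optional[str] = None
    linked_genes: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


def _resize(start: int, end: int, min_width: int) -> tuple[int, int]:
    width = end - start
    if width >= min_width:
        return start, end
    pad = min_width - width
    return start - pad // 2, end + (pad - pad // 2)


def _subtract(start: int, end: int, windows: list[tuple[int, int]]
              ) -> Optional[tuple[int, int]]:
    """Longest (leftmost on ties) sub-interval of [start, end) that avoids
    every window."""
    segments = [(start, end)]
    for lo, hi in windows:
        nxt = []
        for s, e in segments:
            if hi <= s or lo >= e:
                nxt.append((s, e))
                continue
            if s < lo:
                nxt.append((s, lo))
            if hi < e:
                nxt.append((hi, e))
        segments = nxt
    if not segments:
        return None
    return max(segments, key=lambda se: (se[1] - se[0], -se[0]))


def compile_enhancers(
    nc_nc_pairs: Sequence[BidirectionalPair],
    intergenic_nc_peaks: Sequence[TssPeak],
    pc_peaks: Sequence[TssPeak],
    peaks_by_id: dict[str, TssPeak],
    chrom_lengths: Optional[dict[str, int]] = None,
    params: Optional[AnalysisParameters] = None,
) -> list[EnhancerRecord]:
    """Build the candidate-enhancer set.

    ``nc_nc_pairs`` are accepted ncTSS-ncTSS bidirectional pairs (region =
    summit span, grown symmetrically to >= ``enhancer_min_width``);
    ``intergenic_nc_peaks`` are intergenic unidirectional ncTSSs (region =
    ``enhancer_min_width`` centered on the summit).  Candidates overlapping
    the (-400, +100) promoter window of any detected protein-coding TSS (in
    ``pc_peaks``) are trimmed, keeping the longest remainder, and dropped
    below ``enhancer_min_width``.  Regions are clipped to chromosome bounds
    with a warning.
    """
    params = params or AnalysisParameters()
    min_w = params.enhancer_min_width

    prom: dict[str, list[tuple[int, int]]] = {}
    for p in pc_peaks:
        if p.summit is None or p.category != "mRNA":
            continue
        lo, hi = oriented_window(
            p.summit, p.strand, params.acr_promoter_up, params.acr_promoter_down
        )
        prom.setdefault(p.chrom, []).append((lo, hi))

    raw: list[tuple[str, int, int, str, tuple[str, ...]]] = []
    for pair in nc_nc_pairs:
        if pair.pair_type != "ncTSS-ncTSS":
            continue
        a = peaks_by_id[pair.peak_a_id]
        b = peaks_by_id[pair.peak_b_id]
        lo = min(a.summit, b.summit)
        hi = max(a.summit, b.summit) + 1
        lo, hi = _resize(lo, hi, min_w)
        raw.append((a.chrom, lo, hi, "bidirectional_nc",
                    (pair.peak_a_id, pair.peak_b_id)))
    for p in intergenic_nc_peaks:
        lo, hi = p.summit - min_w // 2, p.summit + min_w - min_w // 2
        raw.append((p.chrom, lo, hi, "unidirectional_intergenic", (p.peak_id,)))

    records: list[EnhancerRecord] = []
    raw.sort(key=lambda r: (r[0], r[1], r[4]))
    for i, (chrom, lo, hi, source, src_peaks) in enumerate(raw):
        if chrom_lengths is not None:
            length = chrom_lengths.get(chrom)
            if length is not None and (lo < 0 or hi > length):
                warnings.warn(
                    f"enhancer candidate at {chrom}:{lo}-{hi} clipped to "
                    "chromosome bounds"
                )
                lo, hi = max(lo, 0), min(hi, length)
        seg = _subtract(lo, hi, prom.get(chrom, []))
        if seg is None or seg[1] - seg[0] < min_w:
            continue
        records.append(
            EnhancerRecord(
                enhancer_id=f"enh{i + 1:04d}",
                chrom=chrom, start=seg[0], end=seg[1],
                source=source, source_peaks=src_peaks,
            )
        )
    return records


def activity(record: EnhancerRecord, track: SignalTrack) -> float:
    """Summed signal of both strands over the region (empty region -> 0)."""
    return track.region_sum(record.chrom, "+", record.start, record.end) + \
        track.region_sum(record.chrom, "-", record.start, record.end)


def activity_matrix(
    records: Sequence[EnhancerRecord],
    tracks: dict[str, SignalTrack],
    samples: Optional[Sequence[str]] = None,
) -> None:
    """Fill each record's per-sample activity vector from per-sample tracks."""
    names = list(samples) if samples is not None else list(tracks)
    for rec in records:
        rec.activity = np.array([activity(rec, tracks[s]) for s in names])


def attach_acrs(records: Sequence[EnhancerRecord],
                acrs: Sequence[AcrPeak]) -> None:
    """Attach the first (leftmost) ACR overlapping each enhancer region."""
    trees: dict[str, IntervalTree] = {}
    for a in acrs:
        trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end, a.peak_id)
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(rec.start, rec.end),
                      key=lambda h: (h.begin, h.data))
        rec.overlapping_acr = hits[0].data if hits else None


def _edge_distance(summit: int, start: int, end: int) -> int:
    if start <= summit < end:
        return 0
    return start - summit if summit < start else summit - end + 1


def gene_correlations(
    records: Sequence[EnhancerRecord],
    pc_peaks: Sequence[TssPeak],
    matrix: ExpressionMatrix,
    params: Optional[AnalysisParameters] = None,
) -> None:
    """Link each enhancer to protein-coding TSSs within
    ``enhancer_gene_window`` bp (edge-to-summit; 0 when inside), storing the
    Pearson r between activity and expression over the time course.
    Constant vectors yield an undefined (NaN) correlation.
    """
    params = params or AnalysisParameters()
    window = params.enhancer_gene_window

    by_chrom: dict[str, list[TssPeak]] = {}
    for p in pc_peaks:
        if p.category == "mRNA" and p.summit is not None and p.peak_id in matrix:
            by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: (p.summit, p.peak_id))

    n_masked = len(matrix.timecourse_samples)
    for rec in records:
        if rec.activity is None:
            raise ValueError(f"{rec.enhancer_id}: activity not computed")
        act = np.asarray(rec.activity, dtype=float)[:n_masked]
        rec.linked_genes = []
        for p in by_chrom.get(rec.chrom, ()):
            dist = _edge_distance(p.summit, rec.start, rec.end)
            if dist > window:
                continue
            if act.std() == 0:
                r = math.nan
            else:
                r = pearson(act, matrix.row(p.peak_id, masked=True))
            gene = p.assigned_gene or p.peak_id
            rec.linked_genes.append((gene, dist, r))


def null_distribution(
    records: Sequence[EnhancerRecord],
    pc_peaks: Sequence[TssPeak],
    matrix: ExpressionMatrix,
    n_draws: int,
    seed: int,
) -> list[float]:
    """Correlations of random inter-chromosomal enhancer-pcTSS pairs.

    Draws ``n_draws`` uniform (enhancer, pcTSS) pairs constrained to lie on
    different chromosomes; deterministic given ``seed``.  Draws with an
    undefined correlation (constant vector) are redrawn.
    """
    pcs = [p for p in pc_peaks
           if p.category == "mRNA" and p.peak_id in matrix]
    chroms = {r.chrom for r in records} | {p.chrom for p in pcs}
    if len(chroms) < 2:
        raise ValueError("inter-chromosomal null needs at least 2 chromosomes")
    if n_draws == 0:
        return []
    if not records or not pcs:
        raise ValueError("empty enhancer or pcTSS set")

    n_masked = len(matrix.timecourse_samples)
    rng = np.random.default_rng(seed)
    out: list[float] = []
    attempts = 0
    while len(out) < n_draws and attempts < 50 * n_draws:
        attempts += 1
        rec = records[int(rng.integers(len(records)))]
        p = pcs[int(rng.integers(len(pcs)))]
        if rec.chrom == p.chrom:
            continue
        act = np.asarray(rec.activity, dtype=float)[:n_masked]
        if act.std() == 0:
            continue
        r = pearson(act, matrix.row(p.peak_id, masked=True))
        if math.isnan(r):
            continue
        out.append(r)
    return out


def select_targets(
    records: Sequence[EnhancerRecord],
    r_min: float = 0.5,
) -> list[str]:
    """Genes linked to any enhancer at r >= r_min (deduplicated, sorted)."""
    genes = {
        g for rec in records for (g, _, r) in rec.linked_genes
        if not math.isnan(r) and r >= r_min
    }
    return sorted(genes)


def rank(
    records: Sequence[EnhancerRecord],
    sample: str,
    samples: Sequence[str],
    n: int = 500,
) -> tuple[list[EnhancerRecord], list[EnhancerRecord]]:
    """Top-n and bottom-n enhancers by activity in the named sample.

    Ordering is descending activity with ties broken by id; n is capped at
    floor(count / 2) (with a warning) so the sets stay disjoint.
    """
    idx = list(samples).index(sample)
    ordered = sorted(
        records,
        key=lambda r: (-float(r.activity[idx]), r.enhancer_id),
    )
    cap = len(ordered) // 2
    if n > cap:
        warnings.warn(f"rank n={n} capped at {cap} to keep sets disjoint")
        n = cap
    return ordered[:n], ordered[len(ordered) - n:]
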