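"""Antisense TSS detection, proximal/distal classification and statistics.

A non-coding TSS whose summit lies on the opposite strand within a
protein-coding gene body (extended 200 bp past the TTS) is antisense to that
gene.  Each gene is represented by its highest-expressed sense TSS.  An
antisense TSS is *proximal* when it falls within the first half of the gene
body and more than 1 kbp from the TTS; all others are *distal* (boundary
equalities resolve to distal).  Sense:antisense expression ratios use the
maximum CPM per TSS across the time-course samples (exosome mutants
excluded), and sense/antisense coordination is summarized by Pearson
correlation over the same samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import chi2

from .core_model import (
    AnalysisParameters,
    ExpressionMatrix,
    GeneModel,
    GenomeAnnotation,
    TssPeak,
)

__all__ = [
    "AntisensePair",
    "find_antisense",
    "classify_antisense",
    "sense_antisense_ratio",
    "pair_correlation",
    "cluster_enrichment",
    "correlated_pair_partition",
]

logger = logging.getLogger(__name__)


@dataclass
class AntisensePair:
    gene_id: str
    sense_peak_id: str
    antisense_peak_id: str
    antisense_class: Optional[str] = None   # "proximal" | "distal"
    distance_from_gene_tss: int = 0         # oriented summit offset from gene TSS
    distance_from_tts: int = 0              # oriented; >= -200 via TTS extension
    ratio_sense_over_antisense: float = math.nan
    pearson_r: float = math.nan             # NaN = undefined (constant vector)
    ratio_defined: bool = True


def _oriented_offset(pos: int, anchor: int, strand: str) -> int:
    return pos - anchor if strand == "+" else anchor - pos


def representative_sense_peaks(
    peaks: Sequence[TssPeak],
    matrix: ExpressionMatrix,
) -> dict[str, TssPeak]:
    """Per gene, the assigned sense peak with the highest maximum CPM across
    the time-course samples (ties to the smallest peak id)."""
    best: dict[str, tuple[float, str, TssPeak]] = {}
    for p in peaks:
        if p.assigned_gene is None or p.peak_id not in matrix:
            continue
        mx = float(matrix.row(p.peak_id, masked=True).max())
        key = p.assigned_gene
        cand = (-mx, p.peak_id, p)
        if key not in best or cand < best[key]:
            best[key] = cand
    return {g: t[2] for g, t in best.items()}


def find_antisense(
    peaks: Sequence[TssPeak],
    annotation: GenomeAnnotation,
    matrix: ExpressionMatrix,
    params: Optional[AnalysisParameters] = None,
) -> list[AntisensePair]:
    """Pair non-coding TSSs with the protein-coding gene they are antisense to.

    The gene body is extended ``antisense_tts_ext`` bp past the TTS.  A
    non-coding summit inside several gene bodies pairs with the gene whose
    TSS is nearest.  Genes without a detected sense TSS drop the pair with a
    log entry.  Classes are left unset (see :func:`classify_antisense`).
    """
    params = params or AnalysisParameters()
    ext = params.antisense_tts_ext

    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation.genes:
        if g.biotype != "protein_coding":
            continue
        lo, hi = (g.start, g.end + ext) if g.strand == "+" else (g.start - ext, g.end)
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(lo, hi, g)

    reps = representative_sense_peaks(peaks, matrix)

    pairs: list[AntisensePair] = []
    for p in peaks:
        if p.category == "mRNA" or p.summit is None:
            continue
        anti_strand = "-" if p.strand == "+" else "+"
        hits = trees.get((p.chrom, anti_strand))
        if not hits:
            continue
        genes = [h.data for h in hits.at(p.summit)]
        if not genes:
            continue
        gene = min(
            genes,
            key=lambda g: (abs(p.summit - g.tss), g.gene_id),
        )
        rep = reps.get(gene.gene_id)
        if rep is None:
            logger.info(
                "antisense peak %s: gene %s has no detected sense TSS; dropped",
                p.peak_id, gene.gene_id,
            )
            continue
        pairs.append(
            AntisensePair(
                gene_id=gene.gene_id,
                sense_peak_id=rep.peak_id,
                antisense_peak_id=p.peak_id,
                distance_from_gene_tss=_oriented_offset(
                    p.summit, gene.tss, gene.strand
                ),
                distance_from_tts=_oriented_offset(
                    gene.tts, p.summit, gene.strand
                ),
            )
        )
    return pairs


def classify_antisense(
    pair: AntisensePair,
    gene: GeneModel,
    params: Optional[AnalysisParameters] = None,
) -> str:
    """Proximal iff the antisense summit sits strictly within the first half
    of the gene body AND strictly more than ``proximal_tts_min`` bp from the
    TTS; otherwise distal (boundary equalities -> distal)."""
    params = params or AnalysisParameters()
    proximal = (
        pair.distance_from_gene_tss < params.proximal_frac * gene.length
        and pair.distance_from_tts > params.proximal_tts_min
    )
    pair.antisense_class = "proximal" if proximal else "distal"
    return pair.antisense_class


def sense_antisense_ratio(
    pair: AntisensePair,
    matrix: ExpressionMatrix,
) -> float:
    """maxCPM(sense) / maxCPM(antisense) over the time-course samples.

    A zero antisense maximum leaves the ratio undefined (NaN) and flags the
    pair for exclusion from downstream densities.
    """
    sense = float(matrix.row(pair.sense_peak_id, masked=True).max())
    anti = float(matrix.row(pair.antisense_peak_id, masked=True).max())
    if anti == 0:
        pair.ratio_defined = False
        pair.ratio_sense_over_antisense = math.nan
        return math.nan
    pair.ratio_defined = True
    pair.ratio_sense_over_antisense = sense / anti
    return pair.ratio_sense_over_antisense


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson r; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if x.std() == 0 or y.std() == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def pair_correlation(
    pair: AntisensePair,
    matrix: ExpressionMatrix,
) -> float:
    """Pearson r between sense and antisense expression over the time course."""
    r = pearson(
        matrix.row(pair.sense_peak_id, masked=True),
        matrix.row(pair.antisense_peak_id, masked=True),
    )
    pair.pearson_r = r
    return r


def cluster_enrichment(
    observed: Sequence[int],
    cluster_sizes: Sequence[int],
    antisense_fraction: float,
) -> tuple[float, float]:
    """Chi-square test of observed vs expected antisense counts per cluster.

    Expected count per cluster = global antisense fraction x cluster size.
    Returns ``(statistic, p)`` with k-1 degrees of freedom.
    """
    observed = np.asarray(observed, dtype=float)
    sizes = np.asarray(cluster_sizes, dtype=float)
    if observed.shape != sizes.shape:
        raise ValueError("observed and cluster_sizes differ in length")
    if observed.size < 2:
        raise ValueError("need at least 2 clusters (0 degrees of freedom)")
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    expected = antisense_fraction * sizes
    if (expected == 0).any():
        raise ValueError("expected count of 0 in at least one cluster")
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=observed.size - 1))
    return stat, p


def correlated_pair_partition(
    pairs: Sequence[AntisensePair],
    positive_bound: float = 0.5,
    negative_bound: float = -0.25,
) -> dict[str, list[AntisensePair]]:
    """Disjoint partition by correlation: positive (r > 0.5), negative
    (r < -0.25), other (everything else, including undefined r)."""
    out: dict[str, list[AntisensePair]] = {
        "positive": [], "negative": [], "other": []
    }
    for p in pairs:
        r = p.pearson_r
        if not math.isnan(r) and r > positive_bound:
            out["positive"].append(p)
        elif not math.isnan(r) and r < negative_bound:
            out["negative"].append(p)
        else:
            out["other"].append(p)
    return out
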