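"""TSS-to-gene assignment, TSS categories, transcript filtering, ACR labels.

A TSS peak belongs to a same-strand transcript when its summit falls in the
transcript's annotated 5' region, in the window from 500 bp upstream to
200 bp downstream of the annotated TSS, or within the first 25% of the
transcript length.  Assigned peaks inherit a category from the gene biotype
(mRNA / lncRNA / otherNcRNA); unassigned peaks become putative-lncRNA TSSs
when a reconstructed transcript starts within 50 bp of the summit, and
unstable TSSs otherwise.  ACR peaks are labelled by a strict priority ladder
on their summit: Intergenic, overwritten by Intragenic, then TE, then
Promoter (later steps win).
"""

from __future__ import annotations

from typing import Optional, Sequence

import warnings

from intervaltree import IntervalTree

from .core_model import (
    AnalysisParameters,
    AcrPeak,
    BedInterval,
    GeneModel,
    GenomeAnnotation,
    LNCRNA_BIOTYPES,
    SMALL_RNA_BIOTYPES,
    TranscriptCandidate,
    TssPeak,
    oriented_window,
)

__all__ = ["assign_tss", "categorize_tss", "filter_transcripts", "annotate_acr"]


def _tx_tss(gene: GeneModel, tx) -> int:
    return tx.start if gene.strand == "+" else tx.end - 1


def _oriented_offset(pos: int, anchor: int, strand: str) -> int:
    """Signed offset of pos from anchor in transcription orientation."""
    return pos - anchor if strand == "+" else anchor - pos


def assign_tss(
    peaks: Sequence[TssPeak],
    annotation: GenomeAnnotation,
    params: Optional[AnalysisParameters] = None,
) -> list[TssPeak]:
    """Assign each peak (by summit) to a same-strand transcript's gene.

    A peak matches a transcript when its summit is (a) inside the annotated
    5' UTR, (b) within ``assign_upstream`` bp upstream to
    ``assign_downstream`` bp downstream of the annotated TSS, or (c) within
    the first ``assign_frac`` of the transcript length.  Among multiple
    matches the transcript with the nearest annotated TSS wins; exact ties
    go to the lexicographically smallest gene id.  Unmatched peaks stay
    unassigned.  Peaks are modified in place and returned.
    """
    params = params or AnalysisParameters()

    trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in annotation.genes:
        key = (gene.chrom, gene.strand)
        tree = trees.setdefault(key, IntervalTree())
        for tx in gene.transcripts:
            tss = _tx_tss(gene, tx)
            lo, hi = oriented_window(
                tss, gene.strand, params.assign_upstream, params.assign_downstream
            )
            lo = min(lo, tx.start)
            hi = max(hi, tx.end)
            tree.addi(lo, hi, (gene, tx))

    for peak in peaks:
        if peak.summit is None:
            raise ValueError(f"peak {peak.peak_id} has no summit")
        tree = trees.get((peak.chrom, peak.strand))
        peak.assigned_gene = None
        if tree is None:
            continue
        candidates = []
        for hit in tree.at(peak.summit):
            gene, tx = hit.data
            tss = _tx_tss(gene, tx)
            win_lo, win_hi = oriented_window(
                tss, gene.strand, params.assign_upstream, params.assign_downstream
            )
            offset = _oriented_offset(peak.summit, tss, gene.strand)
            in_utr = False
            if tx.five_prime_utr_end is not None:
                if gene.strand == "+":
                    in_utr = tx.start <= peak.summit < tx.five_prime_utr_end
                else:
                    in_utr = tx.five_prime_utr_end < peak.summit < tx.end
            in_window = win_lo <= peak.summit < win_hi
            tx_len = tx.end - tx.start
            in_head = 0 <= offset < params.assign_frac * tx_len
            if in_utr or in_window or in_head:
                candidates.append((abs(peak.summit - tss), gene.gene_id))
        if candidates:
            candidates.sort()
            peak.assigned_gene = candidates[0][1]
    return list(peaks)


def categorize_tss(
    peaks: Sequence[TssPeak],
    annotation: GenomeAnnotation,
    transcripts: Sequence[TranscriptCandidate] = (),
    params: Optional[AnalysisParameters] = None,
) -> list[TssPeak]:
    """Label every peak with exactly one of the five TSS categories.

    Requires :func:`assign_tss` to have run.  Assigned peaks map through the
    gene biotype; unassigned peaks become ``putativeLncRNA`` when a
    reconstructed same-strand transcript starts within ``tx_tss_tol`` bp of
    the summit, and ``unstable`` otherwise.
    """
    params = params or AnalysisParameters()
    genes = annotation.genes_by_id

    tx_5p: dict[tuple[str, str], list[int]] = {}
    for t in transcripts:
        tx_5p.setdefault((t.chrom, t.strand), []).append(t.five_prime)

    for peak in peaks:
        if peak.assigned_gene is not None:
            biotype = genes[peak.assigned_gene].biotype
            if biotype == "protein_coding":
                peak.category = "mRNA"
            elif biotype in LNCRNA_BIOTYPES:
                peak.category = "lncRNA"
            elif biotype in SMALL_RNA_BIOTYPES:
                peak.category = "otherNcRNA"
            else:
                warnings.warn(
                    f"peak {peak.peak_id}: biotype {biotype!r} outside the "
                    "known lists; categorized as otherNcRNA"
                )
                peak.category = "otherNcRNA"
        else:
            ends = tx_5p.get((peak.chrom, peak.strand), ())
            near = any(abs(e - peak.summit) <= params.tx_tss_tol for e in ends)
            peak.category = "putativeLncRNA" if near else "unstable"
    return list(peaks)


def filter_transcripts(
    candidates: Sequence[TranscriptCandidate],
    peaks: Sequence[TssPeak],
    params: Optional[AnalysisParameters] = None,
) -> list[TranscriptCandidate]:
    """Unify assembler candidates into a non-overlapping supported set.

    Drops candidates shorter than ``min_tx_len``, candidates whose 5' end is
    further than ``tx_tss_tol`` bp from every same-strand peak summit, and
    resolves remaining same-strand overlaps by keeping the longest candidate
    (ties to the leftmost, then smallest id).
    """
    params = params or AnalysisParameters()
    summits: dict[tuple[str, str], list[int]] = {}
    for p in peaks:
        if p.summit is not None:
            summits.setdefault((p.chrom, p.strand), []).append(p.summit)

    supported = []
    for c in candidates:
        if c.length < params.min_tx_len:
            continue
        near = any(
            abs(s - c.five_prime) <= params.tx_tss_tol
            for s in summits.get((c.chrom, c.strand), ())
        )
        if near:
            supported.append(c)

    kept: list[TranscriptCandidate] = []
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in sorted(supported, key=lambda c: (-c.length, c.chrom, c.start, c.tx_id)):
        tree = trees.setdefault((c.chrom, c.strand), IntervalTree())
        if not tree.overlap(c.start, c.end):
            tree.addi(c.start, c.end)
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start, c.tx_id))
    return kept


def annotate_acr(
    acrs: Sequence[AcrPeak],
    annotation: GenomeAnnotation,
    te_intervals: Sequence[BedInterval],
    peaks: Sequence[TssPeak],
    params: Optional[AnalysisParameters] = None,
) -> list[AcrPeak]:
    """Label ACRs by summit through the priority ladder (later rules win):

    1. Intergenic (default); 2. Intragenic when inside a gene detected in the
    initiation data (a gene with at least one assigned peak); 3. TE when
    inside a transposable-element interval; 4. Promoter when inside the
    oriented (-``acr_promoter_up``, +``acr_promoter_down``) window of any
    detected TSS summit.
    """
    params = params or AnalysisParameters()

    detected = {p.assigned_gene for p in peaks if p.assigned_gene is not None}
    gene_tree: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        if g.gene_id in detected:
            gene_tree.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)

    te_tree: dict[str, IntervalTree] = {}
    for t in te_intervals:
        te_tree.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)

    prom_tree: dict[str, IntervalTree] = {}
    for p in peaks:
        if p.summit is None:
            continue
        lo, hi = oriented_window(
            p.summit, p.strand, params.acr_promoter_up, params.acr_promoter_down
        )
        prom_tree.setdefault(p.chrom, IntervalTree()).addi(lo, hi)

    for acr in acrs:
        label = "Intergenic"
        if acr.chrom in gene_tree and gene_tree[acr.chrom].at(acr.summit):
            label = "Intragenic"
        if acr.chrom in te_tree and te_tree[acr.chrom].at(acr.summit):
            label = "TE"
        if acr.chrom in prom_tree and prom_tree[acr.chrom].at(acr.summit):
            label = "Promoter"
        acr.annotation = label
    return list(acrs)
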