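"""End-to-end orchestration of the analysis stages on in-memory objects.

The run order mirrors the analysis: quantify peaks from the per-sample
tracks, TMM-normalize to CPM, recompute summits and 80%-widths from the
pooled track, assign and categorize TSSs, label ACRs, then run the
antisense, bidirectional, enhancer and exosome-sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_model import (
    AcrPeak,
    AnalysisParameters,
    BedInterval,
    ExpressionMatrix,
    GenomeAnnotation,
    SignalTrack,
    TranscriptCandidate,
    TssPeak,
)
from . import antisense_analysis as anti
from . import bidirectional_analysis as bidir
from . import enhancer_analysis as enh
from . import exosome_analysis as exo
from . import feature_annotation as fa
from . import tss_metrics as tm

__all__ = ["PipelineInputs", "PipelineResult", "quantify_peaks", "run_pipeline"]


@dataclass
class PipelineInputs:
    annotation: GenomeAnnotation
    peaks: list[TssPeak]
    tracks: dict[str, SignalTrack]            # sample -> 5' read-start track
    acrs: list[AcrPeak] = field(default_factory=list)
    te_intervals: list[BedInterval] = field(default_factory=list)
    transcripts: list[TranscriptCandidate] = field(default_factory=list)
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    mutant_samples: list[str] = field(default_factory=list)
    counts: Optional[pd.DataFrame] = None     # optional pre-quantified counts


@dataclass
class PipelineResult:
    params: AnalysisParameters
    peaks: list[TssPeak]
    dropped_peaks: list[str]
    norm: tm.NormalizationResult
    cpm: ExpressionMatrix
    transcripts_kept: list[TranscriptCandidate]
    acrs: list[AcrPeak]
    antisense_pairs: list[anti.AntisensePair]
    bidirectional_pairs: list[bidir.BidirectionalPair]
    correlation_distance: pd.DataFrame
    enhancers: list[enh.EnhancerRecord]
    enhancer_targets: list[str]
    enhancer_top: list[enh.EnhancerRecord]
    enhancer_bottom: list[enh.EnhancerRecord]
    null_r: list[float]
    sensitivity_calls: dict[str, list[exo.SensitivityCall]]
    overlap_pvalues: dict[str, float]
    constitutive: list[str]

    @property
    def peaks_by_id(self) -> dict[str, TssPeak]:
        return {p.peak_id: p for p in self.peaks}


def quantify_peaks(peaks: Sequence[TssPeak],
                   tracks: dict[str, SignalTrack]) -> pd.DataFrame:
    """Per-peak, per-sample summed read starts over the peak interval."""
    data = {
        s: [t.region_sum(p.chrom, p.strand, p.start, p.end) for p in peaks]
        for s, t in tracks.items()
    }
    return pd.DataFrame(data, index=[p.peak_id for p in peaks])


def _intergenic_unidirectional(
    peaks: Sequence[TssPeak],
    annotation: GenomeAnnotation,
    paired_ids: set[str],
) -> list[TssPeak]:
    """Non-coding peaks outside every gene body and outside every accepted
    bidirectional pair: the unidirectional intergenic promoter set."""
    body: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        body.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    out = []
    for p in peaks:
        if p.category == "mRNA" or p.peak_id in paired_ids:
            continue
        tree = body.get(p.chrom)
        if tree is not None and tree.at(p.summit):
            continue
        out.append(p)
    return out


def run_pipeline(
    inputs: PipelineInputs,
    params: Optional[AnalysisParameters] = None,
    null_draws: int = 1000,
    null_seed: int = 0,
    rank_sample: str = "L57",
) -> PipelineResult:
    params = params or AnalysisParameters()
    peaks = list(inputs.peaks)
    pooled = SignalTrack.pooled(inputs.tracks.values())

    # summits and widths from the pooled track; zero-signal peaks dropped
    kept: list[TssPeak] = []
    dropped: list[str] = []
    for p in peaks:
        try:
            p.summit = tm.find_summit(p, pooled)
        except ValueError:
            dropped.append(p.peak_id)
            continue
        p.width80 = tm.width80(p, pooled, params.width_frac)
        kept.append(p)
    peaks = kept

    # quantification and TMM-CPM
    counts = inputs.counts
    if counts is None:
        counts = quantify_peaks(peaks, inputs.tracks)
    else:
        counts = counts.loc[[p.peak_id for p in peaks]]
    norm = tm.tmm_normalize(counts)
    cpm = norm.as_expression_matrix(inputs.mutant_samples)
    for p in peaks:
        p.expression = cpm.row(p.peak_id)

    # annotation
    fa.assign_tss(peaks, inputs.annotation, params)
    transcripts_kept = fa.filter_transcripts(inputs.transcripts, peaks, params)
    fa.categorize_tss(peaks, inputs.annotation, transcripts_kept, params)
    acrs = fa.annotate_acr(inputs.acrs, inputs.annotation,
                           inputs.te_intervals, peaks, params)

    # antisense architecture
    genes_by_id = inputs.annotation.genes_by_id
    antisense_pairs = anti.find_antisense(peaks, inputs.annotation, cpm, params)
    for pair in antisense_pairs:
        anti.classify_antisense(pair, genes_by_id[pair.gene_id], params)
        anti.sense_antisense_ratio(pair, cpm)
        anti.pair_correlation(pair, cpm)

    # bidirectional promoters
    pairs = bidir.find_pairs(peaks, params)
    for pair in pairs:
        bidir.max_cpm_ratio(pair, cpm)
        pair.pearson_r = anti.pearson(
            cpm.row(pair.peak_a_id, masked=True),
            cpm.row(pair.peak_b_id, masked=True),
        )
    bidir.corr_groups(pairs, params.corr_group_bound)
    corr_table = bidir.correlation_distance_table(peaks, cpm)

    # enhancers, scored on TMM-normalized tracks
    paired_ids = {p.peak_a_id for p in pairs} | {p.peak_b_id for p in pairs}
    nc_nc = [p for p in pairs if p.pair_type == "ncTSS-ncTSS"]
    uni = _intergenic_unidirectional(peaks, inputs.annotation, paired_ids)
    peaks_by_id = {p.peak_id: p for p in peaks}
    records = enh.compile_enhancers(
        nc_nc, uni, peaks, peaks_by_id,
        inputs.annotation.chrom_lengths, params,
    )
    samples = list(cpm.samples)
    norm_tracks = {
        s: inputs.tracks[s].scaled(
            1e6 / (norm.lib_sizes[s] * norm.factors[s])
        )
        for s in samples
    }
    enh.activity_matrix(records, norm_tracks, samples)
    enh.attach_acrs(records, acrs)
    pc_peaks = [p for p in peaks if p.category == "mRNA"]
    enh.gene_correlations(records, pc_peaks, cpm, params)
    targets = enh.select_targets(records, params.target_corr_min)
    null_r: list[float] = []
    if records and len(inputs.annotation.chromosomes) >= 2 and null_draws > 0:
        null_r = enh.null_distribution(records, pc_peaks, cpm,
                                       null_draws, null_seed)
    if rank_sample in samples and records:
        top, bottom = enh.rank(records, rank_sample, samples, params.rank_n)
    else:
        top, bottom = [], []

    # exosome sensitivity
    calls: dict[str, list[exo.SensitivityCall]] = {}
    for name, table in inputs.de_tables.items():
        assay = name.split("_", 1)[0]
        calls[name] = exo.classify(table, assay, params)
    overlap: dict[str, float] = {}
    by_assay: dict[str, list[str]] = {}
    for name in calls:
        by_assay.setdefault(name.split("_", 1)[0], []).append(name)
    for assay, names in by_assay.items():
        if len(names) != 2:
            continue
        sens = [
            {c.feature_id for c in calls[n] if c.call == "sensitive"}
            for n in names
        ]
        universe = len({c.feature_id for n in names for c in calls[n]})
        if universe:
            overlap[assay] = exo.overlap_test(sens[0], sens[1], universe)

    constitutive = tm.constitutive_set(cpm, params.const_min_cpm,
                                       params.const_top_n)

    return PipelineResult(
        params=params, peaks=peaks, dropped_peaks=dropped, norm=norm, cpm=cpm,
        transcripts_kept=transcripts_kept, acrs=acrs,
        antisense_pairs=antisense_pairs, bidirectional_pairs=pairs,
        correlation_distance=corr_table, enhancers=records,
        enhancer_targets=targets, enhancer_top=top, enhancer_bottom=bottom,
        null_r=null_r, sensitivity_calls=calls, overlap_pvalues=overlap,
        constitutive=constitutive,
    )
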