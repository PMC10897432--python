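"""Planted-truth benchmarking: score a pipeline run against simulator truth.

Used to quantify how well each detector recovers the feature classes the
simulator planted — classification accuracy, pair recovery, false positives
among truth peaks, enhancer-link recovery and the inter-chromosomal null.
"""

from __future__ import annotations

import math

import numpy as np

from .pipeline import PipelineResult
from .synthetic_data import SimulationResult

__all__ = ["evaluate_recovery"]


def _frac(num: int, den: int) -> float:
    return num / den if den else float("nan")


def evaluate_recovery(sim: SimulationResult, res: PipelineResult) -> dict:
    truth = sim.truth
    out: dict[str, float] = {}

    # TSS categories
    cats = {p.peak_id: p.category for p in res.peaks}
    n_ok = sum(cats.get(r.peak_id) == r.truth_category
               for r in truth.peaks.itertuples())
    out["category_recovery"] = _frac(n_ok, len(truth.peaks))

    # antisense pairs and classes
    det = {(a.gene_id, a.antisense_peak_id): a.antisense_class
           for a in res.antisense_pairs}
    n_ok = sum(det.get((r.gene_id, r.antisense_peak)) == r.truth_class
               for r in truth.antisense.itertuples())
    out["antisense_recovery"] = _frac(n_ok, len(truth.antisense))
    truth_keys = {(r.gene_id, r.antisense_peak)
                  for r in truth.antisense.itertuples()}
    out["antisense_false_positives"] = float(
        sum(1 for k in det if k not in truth_keys)
    )

    # bidirectional pairs by kind
    found = {(b.peak_a_id, b.peak_b_id): b.pair_type
             for b in res.bidirectional_pairs}
    pt = truth.pairs
    for kind, key in (("ncTSS-pcTSS", "divergent_recovery"),
                      ("ncTSS-ncTSS", "ncnc_recovery"),
                      ("pcTSS-pcTSS", "pcpc_recovery")):
        sub = pt[pt.kind == kind]
        n_ok = sum(found.get((r.minus_peak, r.plus_peak)) == kind
                   for r in sub.itertuples())
        out[key] = _frac(n_ok, len(sub))
    expected_keys = {
        (r.minus_peak, r.plus_peak)
        for r in pt[pt.kind.isin(["ncTSS-pcTSS", "ncTSS-ncTSS",
                                  "pcTSS-pcTSS"])].itertuples()
    }
    out["pair_false_positives"] = float(
        sum(1 for k in found if k not in expected_keys)
    )
    conv = pt[pt.kind == "convergent"]
    out["convergent_reported"] = float(sum(
        (r.minus_peak, r.plus_peak) in found
        or (r.plus_peak, r.minus_peak) in found
        for r in conv.itertuples()
    ))

    # enhancer sources and planted links
    compiled = {pk for rec in res.enhancers for pk in rec.source_peaks}
    n_src = sum(
        all(pk in compiled for pk in r.peaks.split(","))
        for r in truth.enhancer_sources.itertuples()
    )
    out["enhancer_source_recovery"] = _frac(n_src, len(truth.enhancer_sources))

    by_peak = {}
    for rec in res.enhancers:
        for pk in rec.source_peaks:
            by_peak[pk] = rec
    n_links = 0
    link_rs = []
    for r in truth.enhancer_links.itertuples():
        rec = by_peak.get(r.source_peaks.split(",")[0])
        best = -math.inf
        if rec is not None:
            for g, _, x in rec.linked_genes:
                if g == r.linked_gene and not math.isnan(x):
                    best = max(best, x)
        if best > -math.inf:
            link_rs.append(best)
        if best >= 0.5:
            n_links += 1
    out["enhancer_link_recovery"] = _frac(n_links, len(truth.enhancer_links))
    out["enhancer_link_mean_r"] = (
        float(np.mean(link_rs)) if link_rs else float("nan")
    )

    # ACR ladder labels
    acr_det = {a.peak_id: a.annotation for a in res.acrs}
    n_ok = sum(acr_det.get(r.acr_id) == r.truth_label
               for r in truth.acrs.itertuples())
    out["acr_recovery"] = _frac(n_ok, len(truth.acrs))

    # exosome calls
    calls = {}
    for name, lst in res.sensitivity_calls.items():
        assay, mutant = name.split("_", 1)
        for c in lst:
            calls[(assay, mutant, c.feature_id)] = c.call
    n_ok = sum(
        calls.get((r.assay, r.mutant, r.feature_id)) == r.truth_call
        for r in truth.exosome.itertuples()
    )
    out["exosome_call_accuracy"] = _frac(n_ok, len(truth.exosome))

    out["null_mean_r"] = (
        float(np.mean(res.null_r)) if res.null_r else float("nan")
    )
    return out
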