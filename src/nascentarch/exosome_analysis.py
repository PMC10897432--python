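"""Exosome-sensitivity calls and mutant-overlap testing.

Non-coding features are classified from mutant-vs-wild-type differential
tables (positive log2 fold change = higher in the mutant): *sensitive* when
significantly upregulated (log2FC >= 2 and q < 0.05), *insensitive* when
clearly unchanged and expressed (|log2FC| < 1, q > 0.05, and maximum
expression > 1 CPM for initiation data or > 0.1 TPM for steady-state RNA),
*unclassified* otherwise.  The two gates are provably disjoint
(|log2FC| >= 2 vs < 1).  Overlap of the sensitive sets between mutants is
tested with an upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .core_model import AnalysisParameters

__all__ = ["SensitivityCall", "classify", "overlap_test"]

ASSAYS = ("csRNA", "totalRNA")


@dataclass
class SensitivityCall:
    feature_id: str
    assay: str
    log2fc: float
    qvalue: float
    max_expression: float
    call: str                        # sensitive | insensitive | unclassified


def classify(
    table: pd.DataFrame,
    assay: str,
    params: Optional[AnalysisParameters] = None,
) -> list[SensitivityCall]:
    """Apply the sensitivity gates to a differential table.

    ``table`` needs columns ``feature_id``, ``log2FC``, ``qvalue`` and one of
    ``max_cpm`` / ``max_tpm`` / ``max_expression``.  The sensitive gate is
    upregulation-only (log2FC >= +2); a q value of exactly 0.05 satisfies
    neither gate.
    """
    params = params or AnalysisParameters()
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r} (expected one of {ASSAYS})")
    expr_col = next(
        (c for c in ("max_cpm", "max_tpm", "max_expression")
         if c in table.columns), None,
    )
    if expr_col is None:
        raise ValueError("table lacks a max_cpm/max_tpm/max_expression column")
    min_expr = params.exo_min_cpm if assay == "csRNA" else params.exo_min_tpm

    calls: list[SensitivityCall] = []
    for row in table.itertuples(index=False):
        lfc = float(getattr(row, "log2FC"))
        q = float(getattr(row, "qvalue"))
        mx = float(getattr(row, expr_col))
        if not (0 <= q <= 1):
            raise ValueError(
                f"feature {row.feature_id!r}: q value {q} outside [0, 1]"
            )
        if lfc >= params.exo_lfc_sens and q < params.exo_q:
            call = "sensitive"
        elif (abs(lfc) < params.exo_lfc_insens and q > params.exo_q
              and mx > min_expr):
            call = "insensitive"
        else:
            call = "unclassified"
        calls.append(
            SensitivityCall(
                feature_id=str(row.feature_id), assay=assay, log2fc=lfc,
                qvalue=q, max_expression=mx, call=call,
            )
        )
    return calls


def overlap_test(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: int,
) -> float:
    """Upper-tail hypergeometric p of the observed overlap of two sets.

    With N = universe, K = |A|, n = |B| and k = |A & B|, returns
    P(X >= k) for X ~ Hypergeometric(N, K, n).
    """
    a, b = set(set_a), set(set_b)
    K, n = len(a), len(b)
    k = len(a & b)
    if K > universe or n > universe:
        raise ValueError("set larger than the universe")
    if k > min(K, n):
        raise ValueError("overlap exceeds the smaller set")
    if universe <= 0:
        raise ValueError("universe must be positive")
    return float(hypergeom.sf(k - 1, universe, K, n))
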