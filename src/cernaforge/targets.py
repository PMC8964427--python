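"""Cis (genomic proximity) and trans (expression correlation) target calls.

A cis pair is a lncRNA locus and a gene locus on the same chromosome whose
span gap is at most the window (default 100 kb, boundary inclusive; strand
ignored). A trans pair is any lncRNA-gene pair whose expression correlation
exceeds the threshold in absolute value (default |r| > 0.999, strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._stats import pearson_matrix, spearman_matrix
from .io import ExpressionMatrix, TranscriptRecord, span_gap

__all__ = ["TargetPair", "predict_cis", "predict_trans"]


@dataclass(frozen=True)
class TargetPair:
    """A lncRNA-gene target call (``mode`` is "cis" or "trans")."""

    lncrna_id: str
    gene_id: str
    mode: str
    distance: int | None = None
    correlation: float | None = None


def predict_cis(
    lncs: Sequence[TranscriptRecord],
    genes: Sequence[TranscriptRecord],
    window: int = 100_000,
) -> list[TargetPair]:
    """Pair every lncRNA with genes whose span lies within ``window`` bp.

    Overlapping loci have distance 0. The gap is measured between whole
    transcript spans under half-open coordinates and the boundary is
    inclusive (gap == window still pairs).
    """
    pairs = []
    for lnc in lncs:
        for gene in genes:
            if lnc.chrom != gene.chrom:
                continue
            gap = span_gap(lnc.start, lnc.end, gene.start, gene.end)
            if gap <= window:
                pairs.append(TargetPair(lnc.transcript_id, gene.gene_id, "cis", distance=gap))
    return pairs


def predict_trans(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    threshold: float = 0.999,
    method: Literal["pearson", "spearman"] = "pearson",
    pseudocount: float = 1.0,
) -> list[TargetPair]:
    """Pair lncRNAs and genes with |correlation| > ``threshold`` (strict).

    Pearson (default) is computed on log2(FPKM + pseudocount); Spearman on
    ranks (transform-invariant). Zero-variance features are skipped with a
    warning. Both the correlation and its sign are reported.
    """
    shared = [s for s in lnc_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    a = np.log2(lnc_expr.values[shared].to_numpy() + pseudocount)
    b = np.log2(gene_expr.values[shared].to_numpy() + pseudocount)
    r = pearson_matrix(a, b) if method == "pearson" else spearman_matrix(a, b)

    for axis, ids in ((1, lnc_expr.feature_ids), (0, gene_expr.feature_ids)):
        degenerate = np.isnan(r).all(axis=axis)
        for fid in np.asarray(ids)[degenerate]:
            warnings.warn(f"{fid}: zero variance, skipped", stacklevel=2)

    pairs = []
    ii, jj = np.nonzero(np.abs(r) > threshold)
    lnc_ids, gene_ids = lnc_expr.feature_ids, gene_expr.feature_ids
    for i, j in zip(ii, jj):
        pairs.append(
            TargetPair(lnc_ids[i], gene_ids[j], "trans", correlation=float(r[i, j]))
        )
    return pairs
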