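"""FPKM quantification and stage-wise differential expression.

Fold changes are computed on group means with a pseudocount, the test is
Welch's two-sample t on log2(FPKM + pseudocount) (the statistic is
pluggable), and multiplicity is handled by Benjamini-Hochberg across all
features of a comparison. A feature is called differentially expressed when
FDR < ``alpha_fdr`` and |log2FC| > ``min_abs_log2fc`` (defaults 0.05 and 1).
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .io import ExpressionMatrix

__all__ = [
    "DEFAULT_COMPARISONS",
    "compute_fpkm",
    "differential_expression",
    "de_summary",
]

#: The study's four contiguous-period comparisons.
DEFAULT_COMPARISONS = (("4m", "1.5y"), ("1.5y", "3.5y"), ("3.5y", "6y"), ("4m", "6y"))


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    libsizes: pd.Series,
    layer: str = "mRNA",
    design: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (transcript length in bp * mapped fragments).

    ``counts`` is features x samples; ``lengths`` indexed by feature;
    ``libsizes`` indexed by sample.
    """
    lengths = lengths.reindex(counts.index)
    libsizes = libsizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    if libsizes.isna().any() or (libsizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    fpkm = counts.mul(1e9).div(lengths, axis=0).div(libsizes, axis=1)
    return ExpressionMatrix(values=fpkm, layer=layer, design=design)


def _welch_log2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t-test p-values per feature row; degenerate rows resolved by means."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    # zero within-group variance in both groups: the test statistic is
    # undefined; identical means carry no evidence (p=1), distinct means with
    # zero spread are maximally significant (p=0)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def differential_expression(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 1.0,
    alpha_fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Call DE features between two stages.

    Returns a DataFrame indexed by feature with columns ``log2fc`` (stage B
    relative to stage A), ``p_value``, ``fdr``, ``is_de`` and ``direction``
    (up/down in B). Features with all-zero FPKM in both groups are excluded
    before testing (their fold change is undefined and they would only
    dilute the FDR correction).
    """
    samples_a = expr.samples_in_stage(stage_a)
    samples_b = expr.samples_in_stage(stage_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per group, got {len(samples_a)} in {stage_a!r} "
            f"and {len(samples_b)} in {stage_b!r}"
        )
    values = expr.values
    keep = ~((values[samples_a] == 0).all(axis=1) & (values[samples_b] == 0).all(axis=1))
    values = values.loc[keep]

    mean_a = values[samples_a].mean(axis=1)
    mean_b = values[samples_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    log_a = np.log2(values[samples_a].to_numpy() + pseudocount)
    log_b = np.log2(values[samples_b].to_numpy() + pseudocount)
    pvals = (test or _welch_log2)(log_a, log_b)
    fdr = bh_qvalues(pvals)

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "is_de": (fdr < alpha_fdr) & (np.abs(log2fc) > min_abs_log2fc),
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=values.index,
    )
    result.attrs["comparison"] = (stage_a, stage_b)
    return result


def de_summary(results: Mapping[tuple[str, str], pd.DataFrame]) -> dict:
    """Per-comparison up/down counts plus Venn-style shared/unique sets.

    ``shared`` maps each non-empty combination of comparisons (a frozenset)
    to the features DE in exactly those comparisons (exact set algebra).
    """
    counts = {}
    de_sets: dict[tuple[str, str], frozenset[str]] = {}
    for comp, df in results.items():
        de = df[df["is_de"]]
        counts[comp] = {
            "up": int((de["direction"] == "up").sum()),
            "down": int((de["direction"] == "down").sum()),
            "total": int(len(de)),
        }
        de_sets[comp] = frozenset(de.index)

    all_features = frozenset().union(*de_sets.values()) if de_sets else frozenset()
    membership: dict[frozenset, set[str]] = {}
    for feat in all_features:
        key = frozenset(c for c, s in de_sets.items() if feat in s)
        membership.setdefault(key, set()).add(feat)
    return {"counts": counts, "de_sets": de_sets, "shared": membership}
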