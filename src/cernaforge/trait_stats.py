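"""Validation and phenotype statistics.

Covers the wet-lab side of the workflow: relative qPCR quantification by
the 2^-ddCt method against a reference gene and a calibrator group;
two-tailed Pearson correlation between lncRNA expression and trait values
(fatty acids, intramuscular fat); Duncan's multiple range test with
compact-letter display; and fatty-acid class sums and ratios (PUFA/SFA,
n-6/n-3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, pearson_matrix, pearson_pvalues

__all__ = [
    "ddct",
    "trait_correlation",
    "significance_stars",
    "duncan_groups",
    "fatty_acid_ratios",
]


def ddct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``records`` needs columns ``sample_id``, ``group``, ``target_id``,
    ``ct_target``, ``ct_reference``. Per sample, dCt = Ct(target) -
    Ct(reference); ddCt subtracts the calibrator group's mean dCt for that
    target; relative expression is 2^-ddCt, so the calibrator group has
    geometric mean 1 by construction. A global shift of all Ct values
    cancels out.
    """
    required = {"sample_id", "group", "target_id", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if records["ct_reference"].isna().any():
        bad = records.loc[records["ct_reference"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing reference Ct for samples: {bad}")
    out = records.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    calib = out[out["group"] == calibrator_group]
    if calib.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    calib_mean = calib.groupby("target_id")["dct"].mean()
    out["ddct"] = out["dct"] - out["target_id"].map(calib_mean)
    if out["ddct"].isna().any():
        bad = out.loc[out["ddct"].isna(), "target_id"].unique().tolist()
        raise ValueError(f"targets absent from calibrator group: {bad}")
    out["rel_expression"] = 2.0 ** (-out["ddct"])
    return out


def significance_stars(p: float) -> str:
    """'*', '**', '***' at 0.05 / 0.01 / 0.001; empty string otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trait_correlation(
    lnc_expr: pd.DataFrame,
    traits: pd.DataFrame,
    correct_bh: bool = False,
) -> pd.DataFrame:
    """Pearson r with two-tailed p for every lncRNA x trait pair.

    ``lnc_expr`` is features x samples, ``traits`` is samples x traits; the
    sample sets must intersect in >= 3 samples. Two-tailed p uses
    t = r*sqrt((n-2)/(1-r^2)) on n-2 df. Zero-variance pairs are reported
    with NaN. Per-cell stars mirror heat-map style reporting; no correction
    across the grid by default (``correct_bh=True`` adds BH q-values).
    """
    shared = [s for s in lnc_expr.columns if s in set(traits.index)]
    n = len(shared)
    if n < 3:
        raise ValueError("need >= 3 paired samples")
    x = lnc_expr[shared].to_numpy(dtype=float)
    y = traits.loc[shared].to_numpy(dtype=float).T  # traits x samples
    r = pearson_matrix(x, y)
    p = pearson_pvalues(r, n)

    rows = []
    for i, lnc in enumerate(lnc_expr.index):
        for j, trait in enumerate(traits.columns):
            rows.append(
                {
                    "lncrna_id": lnc,
                    "trait": trait,
                    "n": n,
                    "r": r[i, j],
                    "p_value": p[i, j],
                    "stars": "" if np.isnan(p[i, j]) else significance_stars(p[i, j]),
                }
            )
    out = pd.DataFrame(rows)
    if correct_bh:
        ok = out["p_value"].notna()
        out.loc[ok, "q_value"] = bh_qvalues(out.loc[ok, "p_value"].to_numpy())
    return out


def _duncan_nonsig(
    means: np.ndarray, nh: float, mse: float, df: int, alpha: float
) -> np.ndarray:
    """Boolean matrix over sorted means: True where a pair is NOT separated.

    Implements the protected step-down: spans are tested from widest to
    narrowest against the least significant range
    LSR_p = q_{1-(1-alpha)^(p-1)}(p, df) * sqrt(MSE / n_h); once a span is
    found non-significant, every pair inside it is declared non-significant
    without further testing.
    """
    k = len(means)
    nonsig = np.eye(k, dtype=bool)
    se = np.sqrt(mse / nh)
    lsr = {
        p: stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df) * se
        for p in range(2, k + 1)
    }
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                continue
            if means[j] - means[i] <= lsr[span]:
                nonsig[i : j + 1, i : j + 1] = True
    return nonsig


def duncan_groups(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Duncan's multiple range test with compact-letter display.

    One-way layout: the error mean square and df come from the pooled
    within-group ANOVA; unbalanced designs use the harmonic mean group size.
    Returns group -> letter string; two groups share a letter iff the test
    does not separate their means. All-identical groups share the single
    letter "a".
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
    ns = np.array([arrays[g].size for g in groups])
    df = int(ns.sum() - len(groups))
    mse = sum(((arrays[g] - arrays[g].mean()) ** 2).sum() for g in groups) / df
    nh = len(groups) / (1.0 / ns).sum()

    order = sorted(groups, key=lambda g: (arrays[g].mean(), g))
    means = np.array([arrays[g].mean() for g in order])
    if mse == 0.0:
        # no within-group spread: separate iff means differ at all
        nonsig = np.isclose(means[:, None], means[None, :])
    else:
        nonsig = _duncan_nonsig(means, nh, mse, df, alpha)

    # compact letters: maximal runs of mutually non-separated sorted means.
    # The non-separation relation is interval-closed (smaller spans have both
    # smaller mean differences and smaller least significant ranges), so each
    # run is fully described by its endpoints, and run ends are monotone in
    # run starts - an interval is redundant iff contained in its predecessor.
    intervals: list[tuple[int, int]] = []
    prev_end = -1
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and nonsig[i, j + 1]:
            j += 1
        if j > prev_end:
            intervals.append((i, j))
            prev_end = j
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(intervals):
        letter = chr(ord("a") + idx)
        for pos in range(i, j + 1):
            letters[order[pos]] += letter
    return letters


def fatty_acid_ratios(
    traits: pd.DataFrame, trait_classes: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample fatty-acid class sums and nutritional ratios.

    ``traits`` is samples x traits (g fatty acid / 100 g tissue);
    ``trait_classes`` is indexed by trait with columns ``saturation_class``
    (SFA/MUFA/PUFA/other) and ``omega_class`` (n-3/n-6/none). Returns
    per-sample SFA/MUFA/PUFA sums and the PUFA/SFA and n-6/n-3 ratios; a
    zero denominator yields NaN (reported missing, never an error).
    """
    unlabeled = [t for t in traits.columns if t not in trait_classes.index]
    if unlabeled:
        raise ValueError(f"traits without class labels: {unlabeled}")

    out = pd.DataFrame(index=traits.index)
    sat = trait_classes["saturation_class"]
    for cls in ("SFA", "MUFA", "PUFA"):
        members = [t for t in traits.columns if sat.get(t) == cls]
        out[cls] = traits[members].sum(axis=1) if members else 0.0
    omega = trait_classes["omega_class"]
    n6 = [t for t in traits.columns if omega.get(t) == "n-6"]
    n3 = [t for t in traits.columns if omega.get(t) == "n-3"]
    n6_sum = traits[n6].sum(axis=1) if n6 else pd.Series(0.0, index=traits.index)
    n3_sum = traits[n3].sum(axis=1) if n3 else pd.Series(0.0, index=traits.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["PUFA_SFA"] = (out["PUFA"] / out["SFA"]).replace([np.inf, -np.inf], np.nan)
        out["n6_n3"] = (n6_sum / n3_sum).replace([np.inf, -np.inf], np.nan)
    out.loc[out["SFA"] == 0, "PUFA_SFA"] = np.nan
    out.loc[n3_sum == 0, "n6_n3"] = np.nan
    return out
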