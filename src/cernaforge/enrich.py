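"""Over-representation analysis against user-supplied term annotation.

A generic GO/KEGG-style enrichment: for a study gene set of size n drawn
from a universe of N genes, a term annotating K universe genes and hitting
k study genes gets the exact upper-tail hypergeometric p-value P(X >= k),
with Benjamini-Hochberg q-values across tested terms. One-sided
(over-representation only); depletion is not tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._stats import bh_qvalues, hypergeom_upper_tail

__all__ = ["EnrichmentResult", "overrepresentation"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float


def overrepresentation(
    study: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test each annotation term for over-representation in the study set.

    ``annotation`` maps term -> gene set; genes outside the universe are
    ignored, and terms annotating no universe gene are skipped. Results are
    sorted by ascending p-value (ties broken by term ID).
    """
    universe_set = set(universe)
    study_set = set(study)
    strays = study_set - universe_set
    if strays:
        raise ValueError(f"study genes absent from universe: {sorted(strays)}")
    N, n = len(universe_set), len(study_set)
    term_names = term_names or {}

    rows = []
    for term in sorted(annotation):
        members = set(annotation[term]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & study_set)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((term, k, K, p))
    qs = bh_qvalues([r[3] for r in rows])
    results = [
        EnrichmentResult(term, term_names.get(term, term), k, n, K, N, p, float(q))
        for (term, k, K, p), q in zip(rows, qs)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per term)."""
    return pd.DataFrame([r.__dict__ for r in results])
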