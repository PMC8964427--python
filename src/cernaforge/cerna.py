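"""ceRNA (lncRNA-miRNA-mRNA) network inference.

The competing-endogenous-RNA screen proceeds in three steps:

(a) miRNA pairs: Spearman rank correlation between each lncRNA (or mRNA) and
    each miRNA; pairs with SCC < -0.7 are retained as negatively co-expressed
    (a sponge represses nothing, so its targets' repressor must anti-correlate);
(b) lncRNA-mRNA pairs: Pearson correlation; pairs with PCC > 0.9 are retained
    as co-expressed candidates;
(c) for each candidate lncRNA-mRNA pair, the miRNAs sponged by both (shared
    between their target sets AND individually passing screen (a) with both
    partners) are tested for over-representation with the exact upper-tail
    hypergeometric distribution; pairs with P < 0.05 and at least one shared
    miRNA become triads.

Both correlation cuts are strict inequalities, matching the screening rules
exactly at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from ._stats import hypergeom_upper_tail, bh_qvalues, pearson_matrix, spearman_matrix
from .io import ExpressionMatrix

__all__ = [
    "InteractionPair",
    "CeRNATriad",
    "CeRNANetwork",
    "screen_negative_pairs",
    "screen_coexpressed_pairs",
    "sponge_overlap_test",
    "build_cerna_network",
    "network_stats",
]


@dataclass(frozen=True)
class InteractionPair:
    """A screened co-expression edge between two RNA layers."""

    node_a: str
    node_b: str
    kind: Literal["lnc_mir", "mir_mrna", "lnc_mrna"]
    statistic: float
    p_value: float | None = None


@dataclass
class CeRNATriad:
    """A lncRNA-mRNA pair with its shared sponge miRNAs and hypergeometric p.

    ``x`` = shared sponge count, ``K``/``M`` = the lncRNA's and mRNA's sponge
    counts, ``N`` = miRNA universe size.
    """

    lncrna_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    x: int
    K: int
    M: int
    N: int
    p_hyper: float

    def __post_init__(self) -> None:
        if self.x != len(self.shared_mirnas):
            raise ValueError("x must equal |shared_mirnas|")
        if not (self.x <= min(self.K, self.M) <= max(self.K, self.M) <= self.N):
            raise ValueError("require x <= min(K, M) and K, M <= N")


@dataclass
class CeRNANetwork:
    """Kept triads plus the union of their constituent screened edges."""

    triads: list[CeRNATriad]
    edges: list[InteractionPair] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for t in self.triads:
            g.add_node(t.lncrna_id, layer="lncRNA")
            g.add_node(t.mrna_id, layer="mRNA")
            for m in t.shared_mirnas:
                g.add_node(m, layer="miRNA")
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, kind=e.kind, statistic=e.statistic)
        return g


def _correlation_pairs(
    expr_x: ExpressionMatrix,
    expr_y: ExpressionMatrix,
    kind: str,
    method: Literal["pearson", "spearman"],
    pseudocount: float,
) -> tuple[np.ndarray, list[str], list[str]]:
    shared = [s for s in expr_x.sample_ids if s in set(expr_y.sample_ids)]
    min_n = 3 if method == "pearson" else 4
    if len(shared) < min_n:
        raise ValueError(f"need >= {min_n} shared samples for {method} screening")
    a = expr_x.values[shared].to_numpy(dtype=float)
    b = expr_y.values[shared].to_numpy(dtype=float)
    if method == "pearson":
        a, b = np.log2(a + pseudocount), np.log2(b + pseudocount)
        r = pearson_matrix(a, b)
    else:
        r = spearman_matrix(a, b)  # rank-based: transform-free
    for axis, ids in ((1, expr_x.feature_ids), (0, expr_y.feature_ids)):
        for fid in np.asarray(ids)[np.isnan(r).all(axis=axis)]:
            warnings.warn(f"{fid}: zero variance, skipped in {kind} screen", stacklevel=3)
    return r, expr_x.feature_ids, expr_y.feature_ids


def screen_negative_pairs(
    expr_x: ExpressionMatrix,
    mir_expr: ExpressionMatrix,
    scc_cut: float = -0.7,
) -> list[InteractionPair]:
    """Retain (feature, miRNA) pairs with Spearman correlation < ``scc_cut``.

    ``expr_x`` may be the lncRNA or the mRNA layer; the edge kind follows it.
    Ties receive average ranks. The cut is strict (SCC == -0.7 is dropped).
    """
    kind = "lnc_mir" if expr_x.layer == "lncRNA" else "mir_mrna"
    r, x_ids, mir_ids = _correlation_pairs(expr_x, mir_expr, kind, "spearman", 1.0)
    pairs = []
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(r < scc_cut)
    for i, j in zip(ii, jj):
        a, b = x_ids[i], mir_ids[j]
        if kind == "mir_mrna":
            a, b = b, a  # miRNA listed first for mir->mRNA edges
        pairs.append(InteractionPair(a, b, kind, float(r[i, j])))
    return pairs


def screen_coexpressed_pairs(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    pcc_cut: float = 0.9,
    pseudocount: float = 1.0,
) -> list[InteractionPair]:
    """Retain lncRNA-mRNA pairs with Pearson correlation > ``pcc_cut`` (strict).

    Pearson is computed on log2(FPKM + pseudocount).
    """
    r, lnc_ids, mrna_ids = _correlation_pairs(lnc_expr, mrna_expr, "lnc_mrna", "pearson", pseudocount)
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(r > pcc_cut)
    return [
        InteractionPair(lnc_ids[i], mrna_ids[j], "lnc_mrna", float(r[i, j]))
        for i, j in zip(ii, jj)
    ]


def sponge_overlap_test(x: int, K: int, M: int, N: int) -> float:
    """Exact upper-tail hypergeometric p for a shared-sponge overlap.

    P(X >= x) where X counts shared miRNAs when the mRNA's M sponges are
    drawn from a universe of N miRNAs of which K sponge the lncRNA.
    """
    return hypergeom_upper_tail(x, K, M, N)


def build_cerna_network(
    neg_pairs: Iterable[InteractionPair],
    coexp_pairs: Iterable[InteractionPair],
    sponge_sets: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    universe: Iterable[str] | None = None,
    correct_bh: bool = False,
) -> CeRNANetwork:
    """Assemble triads from the screened pairs and the miRNA target sets.

    ``sponge_sets`` maps miRNA -> targeted features. A miRNA counts as a
    sponge of a gene only when it both targets it (sequence evidence) and
    forms a retained negative pair with it (expression evidence). The
    universe N defaults to every miRNA seen in ``sponge_sets`` or the
    negative screen; pass the expressed-miRNA set to pin it. Raw P < alpha
    by default (``correct_bh=True`` applies Benjamini-Hochberg first).

    Triads with zero shared sponges are discarded before testing (their p
    would be 1 regardless).
    """
    neg_pairs = list(neg_pairs)
    coexp_pairs = list(coexp_pairs)
    targets_of: dict[str, set[str]] = {m: set(t) for m, t in sponge_sets.items()}
    neg_partner: dict[str, set[str]] = {}
    for e in neg_pairs:
        mir, other = (e.node_a, e.node_b) if e.kind == "mir_mrna" else (e.node_b, e.node_a)
        neg_partner.setdefault(other, set()).add(mir)

    if universe is None:
        universe_set = set(targets_of)
        for mirs in neg_partner.values():
            universe_set |= mirs
    else:
        universe_set = set(universe)
    N = len(universe_set)

    def sponges(feature: str) -> set[str]:
        return {
            m
            for m in neg_partner.get(feature, set())
            if feature in targets_of.get(m, set()) and m in universe_set
        }

    candidates = []
    for pair in coexp_pairs:
        lnc, mrna = pair.node_a, pair.node_b
        s_lnc, s_mrna = sponges(lnc), sponges(mrna)
        shared = s_lnc & s_mrna
        if not shared:
            continue
        p = sponge_overlap_test(len(shared), len(s_lnc), len(s_mrna), N)
        candidates.append(
            CeRNATriad(lnc, mrna, frozenset(shared), len(shared), len(s_lnc), len(s_mrna), N, p)
        )

    if correct_bh and candidates:
        qs = bh_qvalues([t.p_hyper for t in candidates])
        kept = [t for t, q in zip(candidates, qs) if q < alpha]
    else:
        kept = [t for t in candidates if t.p_hyper < alpha]

    scc_of = {
        (e.node_a, e.node_b): e for e in neg_pairs
    }
    edges: dict[tuple[str, str, str], InteractionPair] = {}
    for t in kept:
        for mir in sorted(t.shared_mirnas):
            for a, b, kind in ((t.lncrna_id, mir, "lnc_mir"), (mir, t.mrna_id, "mir_mrna")):
                e = scc_of.get((a, b))
                if e is not None:
                    edges[(a, b, kind)] = e
    return CeRNANetwork(triads=kept, edges=sorted(edges.values(), key=lambda e: (e.node_a, e.node_b)))


def network_stats(network: CeRNANetwork) -> dict[str, int]:
    """Node and edge cardinalities of the assembled network."""
    lncs = {t.lncrna_id for t in network.triads}
    mrnas = {t.mrna_id for t in network.triads}
    mirs = set().union(*(t.shared_mirnas for t in network.triads)) if network.triads else set()
    return {
        "n_lncrna": len(lncs),
        "n_mirna": len(mirs),
        "n_mrna": len(mrnas),
        "n_triads": len(network.triads),
        "n_lnc_mir_edges": sum(1 for e in network.edges if e.kind == "lnc_mir"),
        "n_mir_mrna_edges": sum(1 for e in network.edges if e.kind == "mir_mrna"),
    }
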