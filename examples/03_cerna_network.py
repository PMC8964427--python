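"""Recover the planted ceRNA (lncRNA-miRNA-mRNA) network.

Three screening steps: Spearman < -0.7 for miRNA pairs (negative
co-expression), Pearson > 0.9 for lncRNA-mRNA pairs, then an exact
upper-tail hypergeometric test of the shared sponge-miRNA overlap
(P < 0.05) against the expressed-miRNA universe.
"""

from cernaforge import (
    SimConfig,
    build_cerna_network,
    network_stats,
    screen_coexpressed_pairs,
    screen_negative_pairs,
)
from cernaforge.simulate import simulate_all

bundle = simulate_all(SimConfig(seed=1))
lnc, mir, mrna = bundle["lnc"], bundle["mir"], bundle["mrna"]

neg = screen_negative_pairs(lnc, mir) + screen_negative_pairs(mrna, mir)
coexp = screen_coexpressed_pairs(lnc, mrna)
print(f"{len(neg)} negative miRNA pairs (SCC < -0.7), {len(coexp)} co-expressed lncRNA-mRNA pairs")

net = build_cerna_network(neg, coexp, bundle["sponge_sets"], alpha=0.05,
                          universe=mir.feature_ids)
print("network:", network_stats(net))

truth = {(l, m) for l, m, _ in bundle["truth"].planted_triads}
found = {(t.lncrna_id, t.mrna_id) for t in net.triads}
print(f"recall {len(found & truth)}/{len(truth)} planted triads, "
      f"{len(found - truth)} false triads")
for t in sorted(net.triads, key=lambda t: t.p_hyper)[:3]:
    print(f"  {t.lncrna_id} -| {sorted(t.shared_mirnas)} |- {t.mrna_id}  "
          f"x={t.x} K={t.K} M={t.M} N={t.N} p={t.p_hyper:.3g}")
# Each triad is a lncRNA and mRNA sponging the same miRNAs more often than
# chance would allow given the universe of expressed miRNAs.
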