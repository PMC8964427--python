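"""Validation-side statistics: 2^-ddCt qPCR, trait correlations, Duncan letters,
fatty-acid ratios.

qPCR Ct values are converted to fold changes relative to the earliest
stage; lncRNA expression is correlated with fatty-acid traits (two-tailed
Pearson); stage means are separated with Duncan's multiple range test; and
the trait table yields PUFA/SFA and n-6/n-3 nutritional ratios.
"""

import numpy as np

from cernaforge import SimConfig, ddct, duncan_groups, fatty_acid_ratios, trait_correlation
from cernaforge.simulate import simulate_all

bundle = simulate_all(SimConfig(seed=1))

rel = ddct(bundle["qpcr"], calibrator_group="4m")
target = rel["target_id"].iloc[0]
sub = rel[rel["target_id"] == target]
print(f"qPCR target {target}: mean fold change per stage (4m = calibrator)")
print(sub.groupby("group")["rel_expression"].mean().round(3).to_string())

letters = duncan_groups({g: grp["rel_expression"].to_numpy() for g, grp in sub.groupby("group")})
print("Duncan letters (groups sharing a letter are not separated at P < 0.05):", letters)

corr = trait_correlation(np.log2(bundle["lnc"].values + 1.0), bundle["traits"])
planted = {(l, t) for l, t, _ in bundle["truth"].planted_trait_pairs}
hits = corr[[tuple(x) in planted for x in corr[["lncrna_id", "trait"]].to_numpy()]]
print("planted lncRNA-trait correlations (population r = 0.8):")
print(hits[["lncrna_id", "trait", "r", "p_value", "stars"]].round(3).to_string(index=False))

ratios = fatty_acid_ratios(bundle["traits"], bundle["trait_classes"])
print("per-sample means: PUFA/SFA = %.3f, n-6/n-3 = %.3f"
      % (ratios["PUFA_SFA"].mean(), ratios["n6_n3"].mean()))
# Traits are simulated around 10 g/100 g each; with 4 PUFA and 3 SFA traits
# PUFA/SFA sits near 4/3, and with 2 n-6 vs 2 n-3 traits n-6/n-3 sits near 1.
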