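"""The repeated-measures inference battery on small synthetic tables.

Runs a one-way RM-ANOVA with Greenhouse-Geisser correction and FDR-corrected
post-hocs on a behavior table, a repeated-measures correlation, a dominance
analysis, and a cluster-based permutation test over a frequency chain.
"""

import numpy as np

import trackshift as ts

# behavior: hit rates declining across three intelligibility levels
beh = ts.gen_behavior(12, {"original": 0.95, "vocoded7": 0.85, "vocoded3": 0.70},
                      n_trials=24, seed=1)
wide = beh.pivot(index="subject", columns="condition", values="hit_rate")
wide = wide[["original", "vocoded7", "vocoded3"]]
res = ts.rm_anova_1way(wide.to_numpy(), effect="hit_rate")
print(f"hit-rate ANOVA: F({res.df1:.0f},{res.df2:.0f}) = {res.statistic:.2f}, "
      f"p_gg = {res.p_gg:.2g}, eta2p = {res.effect_size:.2f}")
for ph in ts.pairwise_posthoc(wide.to_numpy(), list(wide.columns), method="wilcoxon"):
    print(f"  {ph.effect}: W = {ph.statistic:.0f}, p_adj = {ph.p_adj:.3g}")

# repeated-measures correlation: common within-subject association
rng = np.random.default_rng(2)
subj = np.repeat([f"s{i}" for i in range(8)], 3)
x = np.tile([0.0, 1.0, 2.0], 8)
y = 0.7 * x + np.repeat(rng.standard_normal(8), 3) + 0.3 * rng.standard_normal(24)
r, df, p = ts.rmcorr(x, y, subj)
print(f"rmcorr: r = {r:.2f}, df = {df}, p = {p:.3g}")

# dominance analysis over a correlation matrix (last variable = outcome)
R = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.4], [0.6, 0.4, 1.0]])
dom, full = ts.dominance(R, outcome=2)
print(f"dominance weights {dom} sum to full-model R^2 = {full:.3f}")

# cluster permutation: an effect in bins 20-40 of a 100-bin frequency chain
data = rng.standard_normal((12, 3, 100))
data[:, 0, 20:40] += 1.5
res = ts.cluster_perm_F(data, n_perm=1000, seed=3)
for members, mass, p_val in res.significant:
    print(f"significant cluster: bins {members.min()}-{members.max()}, "
          f"mass = {mass:.1f}, p = {p_val:.3g}")
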