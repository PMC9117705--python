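"""Why Fisher's method needs a dependence correction.

Draws 20,000 null replicates of k = 10 two-sided p-values whose latent test
statistics share an exchangeable correlation of 0.7, then measures how
often each combiner rejects at alpha = 0.05.  Fisher's method assumes
independence and rejects far too often; Brown's moment-matched scaled
chi-square restores the nominal rate; Bonferroni is valid but conservative.
"""

import numpy as np
from scipy import stats

import ldpool as lp
from ldpool.combine import combine_rows

k, rho, reps, alpha = 10, 0.7, 20_000, 0.05
R = lp.LDMatrix(rho * np.ones((k, k)) + (1 - rho) * np.eye(k))

root = lp.make_sampling_root(R)
rng = np.random.default_rng(2)
Z = root.sample(reps, rng)
P = 2 * stats.norm.sf(np.abs(Z))  # two-sided null p-values under LD

fit = lp.brown_fit(R)
x2 = -2 * np.log(P).sum(axis=1)
rates = {
    "fisher (unadjusted)": np.mean(combine_rows(P, "fisher") <= alpha),
    "bonferroni": np.mean(combine_rows(P, "bonferroni") <= alpha),
    "brown (two-sided)": np.mean(stats.chi2.sf(x2 / fit.c, fit.f) <= alpha),
}
print(f"type-I error at alpha = {alpha} with k = {k}, exchangeable rho = {rho}:")
for name, rate in rates.items():
    print(f"  {name:22s} {rate:.4f}")
print(f"\nBrown fit: c = {fit.c:.3f}, f = {fit.f:.2f} "
      f"(independence would give c = 1, f = {2 * k})")
print("Fisher is inflated because LD makes small p-values arrive in bursts; "
      "Brown absorbs\nthe extra variance of X^2 into the scale c and reduced "
      "degrees of freedom f.")
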