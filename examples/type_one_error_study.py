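"""A miniature type-I error and power study.

Simulates three genes with weak, moderate and strong latent LD, runs the
case-control Monte Carlo harness (null phenotype, then a distributed
multi-SNP signal) and prints the rejection rates per method.  The pattern
to look for: unadjusted Fisher inflates with LD under the null, Bonferroni
stays below the nominal level, Brown and the empirical calibration hold it
— and under the alternative Brown retains more power than Bonferroni.
"""

import ldpool as lp

genes = [
    lp.simulate_genotypes(102, 20, {"kind": "ar1", "rho": rho},
                          ("uniform", 0.1, 0.5), seed=30 + i)
    for i, rho in enumerate([0.0, 0.5, 0.9])
]
methods = [
    ("bonferroni", "none"),
    ("fisher", "none"),
    ("fisher", "empirical"),
    ("fisher", "dependent"),   # Brown
    ("stouffer", "dependent"),  # Strube
]

null = lp.run_scenario(genes, lp.ScenarioSpec(causal="null", reps=1000),
                       methods, seed=1, s_empirical=10_000)
print("type-I error at alpha = 0.05 (1000 null replicates per gene):")
print(null.pivot(index="gene_id", columns=["method", "adjustment"],
                 values="rate").round(3).to_string())

alt = lp.run_scenario(
    genes,
    lp.ScenarioSpec(n=500, causal="pct20", effect_size=0.5, distributed=True, reps=500),
    methods, seed=2, s_empirical=10_000,
)
print("\npower, n = 500 (bootstrap), 20% causal SNPs, distributed effect 0.5 "
      "(500 replicates):")
print(alt.pivot(index="gene_id", columns=["method", "adjustment"],
                values="rate").round(3).to_string())
print("\ngene1/2/3 have latent LD rho = 0.0/0.5/0.9; rates are the fraction "
      "of replicates\nwith a combined gene p-value at or below 0.05.")
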