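"""Simulate a small study and scan it with the covariate-adjusted score test.

Builds 697 individuals x 60 independent SNPs with Age/Sex/Smoke/Population
covariates, simulates a trait with three causal SNPs, and runs the single-SNP
score test at every SNP.
"""
import numpy as np

from assocpower import (
    TraitModel,
    scan,
    simulate_covariates,
    simulate_genotypes_independent,
    simulate_traits,
)

rng = np.random.default_rng(1)
g = simulate_genotypes_independent(rng.uniform(0.05, 0.5, 60), 697, seed=2)
z = simulate_covariates(697, seed=3)
model = TraitModel(
    mu=10.0,
    covariate_effects=rng.normal(0, 0.2, size=z.values.shape[1]),
    snp_effects={"snp10": 0.25, "snp25": -0.2, "snp40": 0.3},
    error_sd=1.0,
)
y = simulate_traits(g, z, model, n_replicates=1, seed=4)[0]

results = sorted(scan(g, z, y), key=lambda r: r.p_value)
print("top 5 SNPs by score-test p-value (chi2 = u^2/v, 1 df):")
for r in results[:5]:
    flag = " <- causal" if r.snp_id in model.snp_effects else ""
    print(f"  {r.snp_id:>6}  chi2 = {r.chi2:6.2f}  p = {r.p_value:.2e}{flag}")
print(
    "\nSNPs marked causal carry true effects; any other SNP near the top owes\n"
    "its statistic to finite-sample correlation with the causal set."
)
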