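"""Simulate a PR-interval-like cohort and inspect its calibration.

Builds a synthetic population of 30,000 individuals whose PR interval is
driven by a 52-variant allele score explaining 5% of variance (mean
163 ms, SD 27 ms) and whose AF risk falls by 6% per 5 ms of genetically
longer PR (OR 0.94), at a 6.9% baseline prevalence.
"""

import numpy as np

import ecgmr

cfg = ecgmr.pr_interval_scenario(n_individuals=30_000, seed=1)
cohort = ecgmr.simulate_cohort(cfg)

weights = {v.id: v.beta_exposure for v in cohort.variants}
score = ecgmr.build_score(cohort.genotypes, weights, cohort.variant_ids)
r2 = ecgmr.variance_explained(score, cohort.exposure)

print(f"individuals: {cohort.n}, variants: {len(cohort.variants)}")
print(f"PR interval: mean {cohort.exposure.mean():.1f} ms, SD {cohort.exposure.std():.1f} ms")
print(f"AF prevalence: {cohort.outcome.mean():.4f}")
print(f"score variance explained: {r2:.4f}")
print(f"generative causal log-OR per ms: {cfg.causal_beta:.5f} (OR per 5 ms "
      f"{np.exp(5 * cfg.causal_beta):.3f})")
# The mean/SD/prevalence/R² echo the configured population; the causal
# log-OR is the quantity every downstream MR estimator tries to recover.
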