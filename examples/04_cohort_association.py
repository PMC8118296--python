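"""Individual-level association of a genetic score with AF risk.

Covariate-adjusted logistic regression of AF on the PR-interval score,
reported per 5 ms of genetically predicted PR interval, plus the quintile
display with floated-variance confidence intervals (so any two quintiles
can be compared without a fixed reference group).
"""

import numpy as np

import ecgmr

cfg = ecgmr.pr_interval_scenario(n_individuals=60_000, seed=3)
cohort = ecgmr.simulate_cohort(cfg)
weights = {v.id: v.beta_exposure for v in cohort.variants}
score = ecgmr.build_score(cohort.genotypes, weights, cohort.variant_ids)

per_ms = ecgmr.logistic_assoc(score, cohort.outcome, cohort.covariates,
                              outcome_label="af")
per_5ms = ecgmr.scale_per_5ms(per_ms)
lo, hi = per_5ms.or_ci
print(f"AF risk per 5 ms longer PR score: OR {per_5ms.odds_ratio:.3f} "
      f"(95% CI {lo:.3f}-{hi:.3f}), p = {per_5ms.p:.2g} [{per_5ms.significance_flag}]")

groups, max_err = ecgmr.quintile_contrasts(score, cohort.outcome, cohort.covariates)
print("\nquintiles of the score (cut-points defined among non-cases):")
for g in groups:
    clo, chi = g.ci
    print(f"  Q{g.group}: OR {np.exp(g.log_or):.3f} "
          f"(floated 95% CI {np.exp(clo):.3f}-{np.exp(chi):.3f})")
print(f"max relative error of reconstructed contrast variances: {max_err:.2%}")
# A protective per-5 ms OR below 1 shows up as a falling risk gradient
# across quintiles; floated variances let Q5 be compared to Q1 directly.
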