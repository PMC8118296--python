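"""Instrument strength of an ECG genetic score: R², F statistic, power.

Reports the strength of a simulated PR-interval score and the analytic
power at the published UK-Biobank dimensions (278,792 participants,
19,132 AF cases) to detect a 15% AF risk difference per SD of PR interval.
"""

import ecgmr

cfg = ecgmr.pr_interval_scenario(n_individuals=30_000, seed=2)
cohort = ecgmr.simulate_cohort(cfg)
weights = {v.id: v.beta_exposure for v in cohort.variants}
score = ecgmr.build_score(cohort.genotypes, weights, cohort.variant_ids)

report = ecgmr.strength_report(
    score, cohort.exposure,
    n=278_792, case_fraction=19_132 / 278_792, or_alt=1.15,
)
print(report.to_text())
# F far above the weak-instrument bound of 10 and power above 80% mean the
# score is strong enough for the score-on-outcome design at this scale.
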