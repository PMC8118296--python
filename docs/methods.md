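# Methods

## The causal question and the design

ECG intervals (P-wave duration, PR, QT; all in ms) correlate with atrial
fibrillation (AF) in observational data, but age, comorbidity and reverse
causation confound those associations. The MR design replaces the measured
interval with a weighted allele score built from variants discovered in
external GWAS. Under the instrumental-variable assumptions (relevance,
no confounding of the variant–outcome relation, exclusion restriction),
the score–outcome association identifies the causal effect of the
interval on AF risk. Effects are reported per 5 ms of genetically
predicted interval, as odds ratios from logistic regression.

Two estimation routes are implemented and cross-checked:

1. **Individual-level**: logistic regression of AF on the score, adjusted
   for sex, genotyping array and principal components (configurable;
   simulated PCs default to 10 null standard-normal columns — enough to
   exercise the adjustment machinery without paying for 40).
2. **Summary-data two-sample MR**: per-variant exposure betas from one
   sample and outcome log-ORs from a disjoint sample, combined by the
   ratio-based estimator suite.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes; it
is first-class, tested code, not a fixture.

- **Genotypes**: dosages g ∈ {0,1,2}, binomial(2, f) per variant. LD
  blocks use an equicorrelated Gaussian copula per haplotype: latent
  normals with pairwise correlation ρ thresholded at Φ⁻¹(f). Marginal
  frequencies are exact (HWE holds by construction); the induced allelic
  correlation is the tetrachoric-style function of ρ that the test-suite
  oracle enumerates from the bivariate normal CDF.
- **Exposure**: X = c + Σ w_j g_j + ε, ε Gaussian with variance chosen
  from the *realised* score variance so the score explains the target R²
  in expectation; c centres the mean (163 ms for the PR scenario). The
  shipped scenarios reproduce the published scale: 8 variants/R² 1.8%
  (P-wave, 97 ± 16 ms), 52/5.0% (PR, 163 ± 27 ms), 54/5.0% (QT,
  420 ± 26 ms). Weight magnitudes are shifted-half-normal, bounded away
  from zero because instruments that survived a genome-wide significance
  filter in a large discovery GWAS are never near-null; frequencies are
  U(0.05, 0.95).
- **Outcome**: logistic, P(Y=1) = expit(α + β(X − X̄) + confounder +
  Σ δ_j (g_j − ḡ_j)) with α = logit(K); centring keeps the marginal
  prevalence at K. Default K = 19,132/278,792 ≈ 6.9%, the UK-Biobank-like
  case fraction; the default causal effect is ln(0.94)/5 per ms for the
  PR scenario. Per-variant direct effects δ implement pleiotropy
  (directional or balanced) bypassing X. The outcome model is logistic
  rather than liability-threshold because the estimand is a log-OR.
  Cohorts are population samples (no case-control ascertainment).
- **Two-sample summary statistics**: a seeded permutation splits the
  cohort 50/50 (symmetric power); per-variant linear regression of X on
  dosage in one half, per-variant logistic regression of Y on dosage in
  the other. The logistic fits use a 2-parameter IRLS vectorised across
  variants, oracle-checked against statsmodels to ~1e-14; monomorphic or
  non-converged variants are excluded with a logged warning. Pairs are
  coded to the estimated lengthening allele, the same orientation the
  harmonisation step guarantees.
- `simulate_summary_pairs` draws harmonised pairs directly at the
  summary level (true betas plus Gaussian estimation noise). It exists
  for estimator calibration studies where individual-level simulation
  adds only runtime.

What the generator does **not** emulate: realistic genome-wide LD maps,
imputation uncertainty, relatedness, population stratification (simulated
PCs are null by default), sex chromosomes, case-control sampling, or
selection effects on the weights (winner's curse). Tests passing on this
generator therefore demonstrate correctness of the estimators under the
model's assumptions, not robustness to those real-data features.

## Instrument selection

Filtering is strict at P < 5×10⁻⁸. Clumping is greedy in ascending
p-value with removal at r² ≥ 0.01 for same-chromosome pairs within
±250 kb (1-based positions); missing r² for an in-window pair is treated
as r² = 1 — the conservative choice — and logged. Clumping is idempotent.
Harmonisation matches alleles directly, swapped, or strand-complemented;
A/T and C/G variants with effect-allele frequency in [0.42, 0.58] are
ambiguous and dropped; finally both betas are jointly re-signed so the
coded allele lengthens the interval (β_X ≥ 0). Every drop carries a
machine-readable reason code.

## Scores, strength, power

Scores are exact weighted dosage sums; missing dosages are mean-imputed
per variant (preserves the ms scale). Quintile cut-points are defined by
rank among a reference subset — the non-cases, to limit reverse-causation
leakage — and applied to everyone; ties at a cut-point go to the lower
group, broken by stable input order within the reference.

Power uses the normal approximation for a two-sided Wald test of a binary
outcome on a single allele-score instrument:

    power = Φ(|b|·s − z₁₋α/₂) + Φ(−|b|·s − z₁₋α/₂),  s = √(n R² K(1−K)),

with b the alternative log-OR per SD of the exposure. The second term
makes power equal α exactly at the null and is numerically irrelevant at
any detectable alternative. The formula is validated against Monte-Carlo
rejection rates (agreement within ±0.05 at n = 20,000, R² = 5%,
OR 1.3/SD). At the published PR dimensions (R² = 5%, n = 278,792,
K = 6.9%, OR 1.15/SD) it yields ≈ 98.7%, inside the 80–99% range the
design targets; the 8-variant P-wave score (R² = 1.8%) sits lower, near
the bottom of that range.

## Floated variances

For a k-level factor the logistic fit returns log-ORs b₂..b_k against a
reference level and their covariance V. Floated variances assign each
level its own variance λ so that λ_i + λ_j ≈ Var(b_i − b_j) for every
pair, freeing the display from one arbitrary reference. The algorithm
chooses the reference variance λ₀ by bounded one-dimensional minimisation
of the maximum relative error |2(V_ij − λ₀)|/Var(b_i − b_j) over
non-reference pairs, then λ_i = V_ii − λ₀ floored at a small positive
value. Reference contrasts are exact by construction, so the two-level
case is exactly identified; with a single non-reference level λ₀ splits
V₁₁ evenly. The achieved maximum relative error is returned on every call
rather than hidden; on well-conditioned designs it is far below the 10%
contract because the off-diagonal covariances of dummy-coded fits are
nearly equal.

## Summary-data estimators

All point estimators use the standard summarised-data formulation:
first-order Wald-ratio SEs and outcome-side weights w_j = 1/se_Yj²
(exposure-side noise ignored in the points — the NOME convention — but
propagated through the parametric bootstrap).

- **IVW**: β̂ = Σw β_X β_Y / Σw β_X², the weighted least-squares
  through-origin solution; fixed-effects SE (Σw β_X²)^(−1/2); the
  multiplicative random-effects SE inflates by √max(1, Q/(J−1)) with Q
  Cochran's statistic, so it never undercuts the fixed SE.
- **MR-Egger**: the same regression with a free intercept; the intercept
  estimates average directional pleiotropy under InSIDE. SEs use the
  multiplicative scale max(1, RSS/df); p-values use the t distribution
  with residual df — the convention of summary-data Egger — while CIs
  remain Wald ±1.96·se. With the intercept forced to zero the slope
  coincides exactly with fixed-effects IVW.
- **Weighted median**: weighted empirical quantile at cumulative weight
  0.5 with mid-point interpolation, weights β_X²/se_Y². SE by parametric
  bootstrap (default 1,000 draws, seed mandatory). Consistent while valid
  instruments carry ≥50% of weight; at finite summary noise it retains a
  small offset proportional to the per-ratio noise SD when invalid
  weight is substantial, which the breakdown tests quantify rather than
  assume away.
- **Weighted mode**: argmax of the Gaussian-kernel weighted density of
  ratio estimates; bandwidth = factor × 0.9·min(sd, 1.4826·MAD)·J^(−1/5)
  (modified Silverman), default factor 1, with a {0.5, 1, 2} sensitivity
  sweep reported in the estimate's notes.
- **MR-PRESSO**: observed leave-one-out weighted residual sum of squares
  against a simulated null (betas regenerated from the leave-one-out IVW
  fits at the observed SEs); per-variant outlier p-values are
  Bonferroni-corrected, so the simulated null must resolve J/α — the
  library warns when n_sim < J/α, where no variant could ever be flagged.
  The corrected estimate is IVW on the non-flagged variants; the
  distortion p compares the observed estimate shift to shifts from
  removing equally many random variants.
- **Meta-analysis**: fixed-effects inverse-variance pooling with a
  scale-compatibility guard (per-ms vs per-5 ms inputs refuse to pool).
- **Bidirectional MR**: the same IVW applied to pairs harmonised with AF
  liability as exposure and the ECG interval as outcome; when a forward
  estimate is supplied the reverse/forward effect ratio is reported.

## Numerical choices and degenerate inputs

Wald CIs (±1.959963984·se) and two-sided normal p-values throughout
(Egger's t-based p is the one deliberate exception, above); the
AssocResult p is consistent with its z to 1e-10 by construction.
Reporting flags follow the two-tailed convention p < 0.01 significant,
p < 0.05 suggestive; flags never alter estimates. Logistic fits abort on
non-convergence or boundary fitted probabilities (separation); designs
are rank-checked with the collinear columns named. Degenerate inputs
(constant scores, zero-variance instruments, all-flagged PRESSO, mixed
meta scales, double per-5 ms scaling) raise rather than guess.

## Known limitations

- Two-stage simulations at realistic instrument strength carry the
  inherent ~2% weak-instrument regression dilution (factor 1/(1+1/F̄))
  plus ~2% logistic non-collapsibility attenuation of the marginal
  per-variant log-ORs; estimator means in the recovery suites sit
  slightly toward the null of the generative conditional slope by exactly
  this margin. This is a property of the estimand, not an implementation
  artefact — IVW agrees with its algebraic oracle to 1e-10.
- Replicate counts in the simulation suites (200 for estimator recovery,
  100 for pleiotropy diagnostics, 500 for null calibration) and the
  default cohort sizes were chosen as the smallest giving stable
  Monte-Carlo comparisons at the stated tolerances.
- The CLI is a thin convenience layer; the library API is the primary
  interface and the only one the pipeline itself uses.
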