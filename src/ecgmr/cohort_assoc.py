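"""Individual-level association analyses for genetic ECG scores.

Linear regression of measured phenotypes on the score, logistic regression
of binary arrhythmia outcomes on the score (both covariate-adjusted),
per-5 ms rescaling for reporting, quintile contrasts with floated
variances so any pair of groups can be compared without a fixed reference,
and adjustment for a second score.

Two-tailed p < 0.01 is flagged significant and p < 0.05 suggestive, a
multiple-testing convention applied to reporting only — estimates are
never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .scores import GeneticScore, assign_quintiles

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5th percentile used for all Wald CIs

SIGNIFICANT_P = 0.01
SUGGESTIVE_P = 0.05


@dataclass
class AssocResult:
    """A single regression effect with its Wald CI and two-sided p."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    outcome_label: str
    scale: str  # "per-ms" | "per-5ms" | "per-quintile"
    family: str  # "linear" | "logistic"

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise ValueError("odds ratio only defined for logistic results")
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def significance_flag(self) -> str:
        """Reporting convention: p<0.01 significant, p<0.05 suggestive."""
        if self.p < SIGNIFICANT_P:
            return "significant"
        if self.p < SUGGESTIVE_P:
            return "suggestive"
        return "ns"


@dataclass
class FloatedGroupRisk:
    """Group log-OR with a floated variance enabling any pairwise contrast."""

    group: int
    log_or: float
    floated_variance: float

    @property
    def ci(self) -> tuple[float, float]:
        half = Z95 * np.sqrt(self.floated_variance)
        return float(self.log_or - half), float(self.log_or + half)


def _design(score_values: np.ndarray, covariates: Optional[pd.DataFrame]) -> pd.DataFrame:
    X = pd.DataFrame({"score": np.asarray(score_values, float)})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the collinear columns by projecting each on the rest
        bad = []
        for j, col in enumerate(X.columns):
            others = np.delete(arr, j, axis=1)
            resid = arr[:, j] - others @ np.linalg.lstsq(others, arr[:, j], rcond=None)[0]
            if np.abs(resid).max() < 1e-8 * max(1.0, np.abs(arr[:, j]).max()):
                bad.append(str(col))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _wrap(beta: float, se: float, n: int, outcome_label: str, scale: str, family: str) -> AssocResult:
    z = beta / se
    return AssocResult(
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        n=n,
        outcome_label=outcome_label,
        scale=scale,
        family=family,
    )


def linear_assoc(
    score: GeneticScore,
    phenotype: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    outcome_label: str = "phenotype",
) -> AssocResult:
    """OLS of a continuous phenotype on the score, covariate-adjusted.

    The returned beta is in phenotype units per ms of score. Also serves
    continuous non-ECG outcomes such as indexed left-atrial volume.
    """
    y = np.asarray(phenotype, float)
    X = _design(score.values, covariates)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    return _wrap(fit.params["score"], fit.bse["score"], len(y), outcome_label, "per-ms", "linear")


def logistic_assoc(
    score: GeneticScore,
    outcome: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    outcome_label: str = "outcome",
) -> AssocResult:
    """Maximum-likelihood logistic fit; beta is the log-OR per ms of score."""
    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = _design(score.values, covariates)
    _check_rank(X)
    fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    fitted = fit.predict(X)
    if fitted.max() > 1 - 1e-10 or fitted.min() < 1e-10:
        raise RuntimeError("quasi-separation detected: fitted probabilities at the boundary")
    logger.debug("logistic fit converged in %s iterations", fit.mle_retvals.get("iterations"))
    return _wrap(fit.params["score"], fit.bse["score"], len(y), outcome_label, "per-ms", "logistic")


def scale_per_5ms(result: AssocResult) -> AssocResult:
    """Rescale a per-ms effect to the per-5 ms reporting scale.

    Beta and SE multiply by 5 (OR per 5 ms = exp(5·beta_per_ms)); the
    p-value is unchanged. Double scaling is refused.
    """
    if result.scale != "per-ms":
        raise ValueError(f"result already on scale {result.scale!r}")
    return replace(
        result,
        beta=5.0 * result.beta,
        se=5.0 * result.se,
        ci_low=5.0 * result.beta - Z95 * 5.0 * result.se,
        ci_high=5.0 * result.beta + Z95 * 5.0 * result.se,
        scale="per-5ms",
    )


def float_variances(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Floated variances (λ_ref, λ_1..λ_k) from the covariance of non-reference log-ORs.

    Solves for the reference-group variance λ0 that minimises the maximum
    relative error of λ_i + λ_j against the exact contrast variance
    Var(b_i − b_j) = V_ii + V_jj − 2 V_ij over all non-reference pairs,
    then sets λ_i = V_ii − λ0 (floored at a small positive value).
    Reference contrasts λ0 + λ_i = V_ii are exact by construction, so the
    two-level case is exactly identified.

    Returns (lambdas, max_relative_error) with lambdas[0] the reference.
    """
    V = np.atleast_2d(np.asarray(cov, float))
    k = V.shape[0]
    if V.shape != (k, k):
        raise ValueError("covariance matrix must be square")
    eigvals = np.linalg.eigvalsh(V)
    if eigvals.min() <= 0:
        raise ValueError("covariance matrix is not positive-definite")
    floor = 1e-12 * float(np.max(np.diag(V)))
    if k == 1:
        lam0 = float(V[0, 0]) / 2.0
        return np.array([lam0, V[0, 0] - lam0]), 0.0
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    contrast_var = np.array([V[i, i] + V[j, j] - 2.0 * V[i, j] for i, j in pairs])
    offdiag = np.array([V[i, j] for i, j in pairs])

    def max_rel_err(lam0: float) -> float:
        # λ_i + λ_j − Var(b_i − b_j) = 2(V_ij − λ0)
        return float(np.max(np.abs(2.0 * (offdiag - lam0)) / contrast_var))

    lo = min(0.0, float(offdiag.min()))
    hi = max(float(offdiag.max()), float(np.diag(V).min()))
    res = optimize.minimize_scalar(max_rel_err, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-14})
    lam0 = float(res.x)
    lams = np.concatenate([[lam0], np.maximum(np.diag(V) - lam0, floor)])
    return lams, max_rel_err(lam0)


def quintile_contrasts(
    score: GeneticScore,
    outcome: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    reference_mask: Optional[np.ndarray] = None,
    n_groups: int = 5,
) -> tuple[list[FloatedGroupRisk], float]:
    """Per-quintile AF log-ORs with floated variances.

    Quintiles of the score are defined in the reference subset (by default
    the non-cases) and entered as indicator terms in a covariate-adjusted
    logistic model with the bottom quintile as the fitting reference.
    Floated variances are derived from the estimated covariance matrix of
    the non-reference log-ORs (see :func:`float_variances`); each group's
    95% CI is log_or ± 1.96·sqrt(floated variance). Returns the group
    risks (reference group at log-OR 0) and the maximum relative error of
    the reconstructed contrast variances.
    """
    y = np.asarray(outcome, float)
    if reference_mask is None:
        reference_mask = y == 0  # cut-points defined among non-cases
    labels = assign_quintiles(score, reference_mask=reference_mask, n_groups=n_groups)
    dummies = pd.get_dummies(labels, prefix="q", drop_first=True).astype(float)
    X = dummies
    if covariates is not None:
        X = pd.concat([dummies.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    _check_rank(X)
    fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
    names = list(dummies.columns)
    b = fit.params[names].to_numpy()
    V = fit.cov_params().loc[names, names].to_numpy()
    lams, max_err = float_variances(V)
    groups = [FloatedGroupRisk(group=1, log_or=0.0, floated_variance=float(lams[0]))]
    for g, (bi, li) in enumerate(zip(b, lams[1:]), start=2):
        groups.append(FloatedGroupRisk(group=g, log_or=float(bi), floated_variance=float(li)))
    logger.info("floated-variance max relative contrast error: %.3g", max_err)
    return groups, float(max_err)


def adjusted_for_second_score(
    score: GeneticScore,
    adjust_score: GeneticScore,
    outcome: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    outcome_label: str = "outcome",
) -> AssocResult:
    """Logistic fit of the outcome on the primary score with a second score as covariate.

    Used to ask whether one interval's effect survives adjustment for a
    correlated interval's score (e.g., PR adjusted for P-wave duration).
    """
    r = np.corrcoef(score.values, adjust_score.values)[0, 1]
    if abs(r) > 0.99:
        raise ValueError(f"scores nearly collinear (|r| = {abs(r):.3f}); adjustment unidentified")
    extra = pd.DataFrame({"adjust_score": np.asarray(adjust_score.values, float)})
    cov = extra if covariates is None else pd.concat(
        [extra, covariates.reset_index(drop=True)], axis=1
    )
    return logistic_assoc(score, outcome, cov, outcome_label=outcome_label)


def wald_p_from_or_ci(or_: float, ci_low: float, ci_high: float) -> float:
    """Two-sided Wald p implied by a printed OR and its 95% CI.

    Inverts the Wald construction: se = (ln ci_high − ln ci_low)/(2·1.96),
    z = ln(or)/se. Used to check published OR/CI/p triplets for internal
    consistency.
    """
    if not (0.0 < ci_low <= or_ <= ci_high):
        raise ValueError("require 0 < ci_low <= or <= ci_high")
    if ci_low == ci_high:
        raise ValueError("degenerate CI")
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95)
    z = np.log(or_) / se
    return float(2.0 * stats.norm.sf(abs(z)))
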