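"""Weighted genetic scores and instrument-strength metrics.

A genetic score is the per-individual weighted sum of effect-allele
dosages, the weights being published per-allele effects on the ECG
interval in milliseconds, so the score itself is in ms. Instrument
strength is summarised by the variance explained (R²), the one-regressor
F statistic, and analytic power for a binary outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneticScore:
    """Per-individual weighted allele score in ms."""

    values: np.ndarray
    weights_used: dict[str, float]
    n_variants: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StrengthReport:
    """Instrument-strength summary: R², F, analytic power at an alternative."""

    r2: float
    f_stat: float
    power: float
    alpha: float
    n: int
    case_fraction: float
    or_alt: float

    def to_text(self) -> str:
        return (
            f"variance explained (R2): {self.r2:.4f}\n"
            f"F statistic: {self.f_stat:.1f}\n"
            f"power to detect OR {self.or_alt:.2f}/SD at alpha {self.alpha:.2g}: "
            f"{100 * self.power:.1f}%\n"
            f"n = {self.n}, case fraction = {self.case_fraction:.4f}"
        )


def build_score(
    genotypes: np.ndarray,
    weights: Mapping[str, float],
    variant_ids: Sequence[str],
    impute_missing: bool = True,
) -> GeneticScore:
    """Exact weighted sum of dosages, score_i = Σ_j w_j g_ij.

    ``variant_ids`` labels the columns of ``genotypes``; every weighted
    variant must be present. NaN dosages are mean-imputed per variant when
    ``impute_missing`` (preserves the score scale); otherwise they
    propagate.
    """
    id_to_col = {vid: j for j, vid in enumerate(variant_ids)}
    missing = [vid for vid in weights if vid not in id_to_col]
    if missing:
        raise KeyError(f"weights refer to variants absent from the genotype matrix: {missing}")
    cols = [id_to_col[vid] for vid in weights]
    w = np.array([weights[vid] for vid in weights], dtype=float)
    g = genotypes[:, cols].astype(float)
    if impute_missing and np.isnan(g).any():
        col_means = np.nanmean(g, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(g))
        g[nan_r, nan_c] = col_means[nan_c]
    return GeneticScore(values=g @ w, weights_used=dict(weights), n_variants=len(w))


def assign_quintiles(
    score: GeneticScore,
    reference_mask: Optional[np.ndarray] = None,
    n_groups: int = 5,
) -> np.ndarray:
    """Quantile-group labels 1..n_groups, cut-points defined in a reference subset.

    Cut-points are placed by rank within the reference subset (typically
    the non-case participants), giving reference group sizes equal to
    within one after ties, then applied to every individual: a score equal
    to a cut-point falls in the lower group. Ties spanning a cut-point are
    broken by stable input order within the reference and logged.
    """
    x = np.asarray(score.values, dtype=float)
    ref = np.ones(len(x), dtype=bool) if reference_mask is None else np.asarray(reference_mask, bool)
    xr = x[ref]
    if len(np.unique(xr)) < n_groups:
        raise ValueError(f"cannot form {n_groups} groups: fewer distinct reference scores")
    nr = len(xr)
    order = np.argsort(xr, kind="stable")
    ref_labels = np.empty(nr, dtype=int)
    bounds = [round(nr * k / n_groups) for k in range(n_groups + 1)]
    cuts = []
    for k in range(n_groups):
        ref_labels[order[bounds[k] : bounds[k + 1]]] = k + 1
        if k < n_groups - 1:
            cuts.append(xr[order[bounds[k + 1] - 1]])
    cuts_arr = np.array(cuts)
    # a score equal to a cut-point belongs to the group below it
    labels = np.searchsorted(cuts_arr, x, side="left") + 1
    labels[labels > n_groups] = n_groups
    # within the reference, rank-based labels are authoritative (stable tie-break)
    if np.any(labels[ref] != ref_labels):
        logger.info("ties span a quintile cut-point; broken by stable input order")
    labels[np.flatnonzero(ref)] = ref_labels
    return labels


def variance_explained(score: GeneticScore, phenotype: np.ndarray) -> float:
    """R² from the simple linear regression of phenotype on score.

    Equals the squared Pearson correlation between the two.
    """
    x = np.asarray(score.values, float)
    y = np.asarray(phenotype, float)
    if len(x) != len(y):
        raise ValueError("score and phenotype must be paired")
    if np.var(x) == 0.0:
        raise ValueError("zero-variance score: R2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def f_statistic(r2: float, n: int) -> float:
    """One-regressor instrument F: F = R²(n − 2)/(1 − R²).

    F > 10 is the conventional bound below which weak-instrument bias is a
    concern.
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 must lie in [0, 1]")
    if r2 == 1.0:
        logger.warning("r2 = 1: F statistic is infinite")
        return float("inf")
    return float(r2 * (n - 2) / (1.0 - r2))


def analytic_power(
    r2: float,
    n: int,
    case_fraction: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power for binary-outcome MR with a single allele-score instrument.

    Normal approximation for a two-sided Wald test of the score–outcome
    log-OR: with K the case fraction and b the alternative log-OR per SD of
    the exposure, the test statistic is approximately
    N(b·sqrt(n·R²·K(1−K)), 1), giving

        power = Φ(|b|·s − z₁₋α/₂) + Φ(−|b|·s − z₁₋α/₂),  s = sqrt(n R² K(1−K)).

    The second term makes the two-sided power exactly alpha at the null and
    is negligible (< 1e-5) at any practically detectable alternative.
    """
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must lie in (0, 1)")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    b = abs(np.log(or_alt))
    s = np.sqrt(n * r2 * case_fraction * (1.0 - case_fraction))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(b * s - z) + stats.norm.cdf(-b * s - z))


def strength_report(
    score: GeneticScore,
    phenotype: np.ndarray,
    n: int,
    case_fraction: float,
    or_alt: float = 1.15,
    alpha: float = 0.05,
) -> StrengthReport:
    """R², F and power in one record, as reported for each ECG score."""
    r2 = variance_explained(score, phenotype)
    return StrengthReport(
        r2=r2,
        f_stat=f_statistic(r2, len(score)),
        power=analytic_power(r2, n, case_fraction, or_alt, alpha),
        alpha=alpha,
        n=n,
        case_fraction=case_fraction,
        or_alt=or_alt,
    )
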