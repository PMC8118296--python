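"""Two-sample Mendelian-randomisation estimators on harmonised summary pairs.

Implements the estimator roster used for summary-data MR of ECG intervals
on AF: single-variant Wald ratios, fixed/random-effects inverse-variance
weighting, MR-Egger regression (directional-pleiotropy intercept),
weighted median and weighted mode (robust to invalid instruments),
MR-PRESSO outlier detection, fixed-effects meta-analysis, and the
bidirectional analysis obtained by swapping exposure and outcome roles.

All estimators use the standard summarised-data formulation: first-order
Wald-ratio SEs and outcome-SE weights (exposure-side uncertainty is
ignored in the point estimators, the NO-Measurement-Error convention, but
propagated in the parametric bootstrap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .instruments import SummaryPair

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class MREstimate:
    """A causal-effect estimate: log-OR of outcome per unit (ms) of exposure."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_variants: int
    scale: str = "per-ms"
    q_statistic: Optional[float] = None
    q_df: Optional[int] = None
    notes: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class PressoReport:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_flags: np.ndarray  # bool per variant
    outlier_p: np.ndarray  # Bonferroni-adjusted per-variant p
    distortion_p: Optional[float]
    corrected: Optional[MREstimate]
    original: MREstimate
    n_sim: int
    seed: int


def _wrap(method: str, beta: float, se: float, n_variants: int,
          p: Optional[float] = None, **extra) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        p=float(2.0 * stats.norm.sf(abs(z))) if p is None else float(p),
        n_variants=n_variants,
        **extra,
    )


def _arrays(pairs: Sequence[SummaryPair]):
    bx = np.array([p.beta_exposure for p in pairs], float)
    by = np.array([p.beta_outcome for p in pairs], float)
    sx = np.array([p.se_exposure for p in pairs], float)
    sy = np.array([p.se_outcome for p in pairs], float)
    if np.any(sy <= 0):
        raise ValueError("outcome SEs must be positive")
    return bx, by, sx, sy


def scale_mr_per_5ms(est: MREstimate) -> MREstimate:
    """Rescale a per-ms MR estimate to the per-5 ms reporting scale."""
    if est.scale != "per-ms":
        raise ValueError(f"estimate already on scale {est.scale!r}")
    return replace(
        est,
        beta=5.0 * est.beta,
        se=5.0 * est.se,
        ci_low=5.0 * est.beta - Z95 * 5.0 * est.se,
        ci_high=5.0 * est.beta + Z95 * 5.0 * est.se,
        scale="per-5ms",
    )


def wald_ratio(pair: SummaryPair) -> MREstimate:
    """Single-variant ratio estimate β_Y/β_X with first-order SE se_Y/|β_X|."""
    if pair.beta_exposure == 0:
        raise ValueError("Wald ratio undefined for a zero exposure effect")
    beta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return _wrap("wald_ratio", beta, se, 1)


def ivw(pairs: Sequence[SummaryPair], effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance weighted estimate: WLS of β_Y on β_X through the origin.

    beta = Σ w β_X β_Y / Σ w β_X² with w = 1/se_Y². The fixed-effects SE is
    (Σ w β_X²)^(-1/2); the multiplicative random-effects SE inflates it by
    sqrt(max(1, Q/(J−1))) where Q is Cochran's heterogeneity statistic.
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError("effects_model must be 'fixed' or 'random'")
    if len(pairs) < 2:
        raise ValueError("IVW requires at least 2 variants")
    bx, by, _, sy = _arrays(pairs)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValueError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = len(pairs) - 1
    if effects_model == "random":
        se = se_fixed * np.sqrt(max(1.0, q / df))
        method = "ivw_random"
    else:
        se = se_fixed
        method = "ivw_fixed"
    return _wrap(method, beta, se, len(pairs), q_statistic=q, q_df=df)


def mr_egger(
    pairs: Sequence[SummaryPair],
    fit_intercept: bool = True,
) -> tuple[MREstimate, Optional[MREstimate]]:
    """MR-Egger: weighted regression β_Y = β₀ + β·β_X with weights 1/se_Y².

    Requires all pairs coded to the exposure-increasing allele (β_X ≥ 0,
    the harmonisation contract). The slope estimates the causal effect
    under InSIDE; the intercept estimates average directional pleiotropy.
    SEs use the multiplicative random-effects scale max(1, RSS/(J−2)) and
    p-values the t distribution with the residual df, the standard
    summary-data Egger convention; CIs remain Wald ±1.96·se.

    With ``fit_intercept=False`` the regression runs through the origin
    and the slope point estimate coincides exactly with fixed-effects IVW
    (the intercept slot is None).
    """
    if len(pairs) < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    bx, by, _, sy = _arrays(pairs)
    if np.any(bx < 0):
        raise ValueError("MR-Egger requires harmonised pairs with beta_exposure >= 0")
    if np.ptp(bx) == 0:
        raise ValueError("no spread in exposure effects: Egger slope unidentified")
    w = 1.0 / sy**2
    sw = np.sqrt(w)
    if fit_intercept:
        X = np.column_stack([sw, sw * bx])  # weighted intercept and slope columns
    else:
        X = (sw * bx)[:, None]
    yw = sw * by
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ yw)
    resid = yw - X @ coef
    df = len(pairs) - X.shape[1]
    scale = max(1.0, float(resid @ resid) / df)
    cov = np.linalg.inv(xtx) * scale
    se = np.sqrt(np.diag(cov))
    if not fit_intercept:
        p1 = float(2.0 * stats.t.sf(abs(coef[0] / se[0]), df))
        return _wrap("egger_slope", coef[0], se[0], len(pairs), p=p1), None
    p0 = float(2.0 * stats.t.sf(abs(coef[0] / se[0]), df))
    p1 = float(2.0 * stats.t.sf(abs(coef[1] / se[1]), df))
    slope = _wrap("egger_slope", coef[1], se[1], len(pairs), p=p1)
    intercept = _wrap("egger_intercept", coef[0], se[0], len(pairs), p=p0)
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted empirical median with the standard mid-point interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    csum = np.cumsum(w) - 0.5 * w  # mid-point cumulative weight per ratio
    if 0.5 <= csum[0]:
        return float(r[0])
    if 0.5 >= csum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, csum, r))


def weighted_median(
    pairs: Sequence[SummaryPair],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    Consistent when at least 50% of the weight comes from valid
    instruments. Weights are β_X²/se_Y² (inverse ratio variance); the SE is
    a parametric bootstrap resampling β_X and β_Y from normal(β̂, se) with
    a fixed seed.
    """
    if len(pairs) < 2:
        raise ValueError("weighted median requires at least 2 variants")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap SE will be noisy", n_boot)
    bx, by, sx, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect: ratio undefined")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(_weighted_median_point, bx, by, sx, sy, n_boot, seed)
    return _wrap("weighted_median", beta, se, len(pairs))


def _silverman_bandwidth(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Modified Silverman rule on the ratio estimates (weighted moments)."""
    w = weights / weights.sum()
    mean = float(np.sum(w * ratios))
    sd = float(np.sqrt(np.sum(w * (ratios - mean) ** 2)))
    mad = float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))
    s = min(sd, mad) if mad > 0 else sd
    if s == 0:
        return 0.0
    return 0.9 * s * len(ratios) ** (-1.0 / 5.0)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         bandwidth_factor: float = 1.0) -> float:
    h = bandwidth_factor * _silverman_bandwidth(ratios, weights)
    if h == 0.0:
        return float(ratios[0])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    pairs: Sequence[SummaryPair],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_sweep: Sequence[float] = (0.5, 1.0, 2.0),
) -> MREstimate:
    """Mode of the kernel-smoothed weighted ratio density.

    Consistent when the largest homogeneous cluster of variants is valid,
    even if they are a minority. Gaussian kernel with bandwidth =
    bandwidth_factor × modified-Silverman rule; SE by parametric bootstrap.
    The estimate's sensitivity to bandwidth is reported in ``notes``.
    """
    if len(pairs) < 2:
        raise ValueError("weighted mode requires at least 2 variants")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    bx, by, sx, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect: ratio undefined")
    ratios = by / bx
    weights = bx**2 / sy**2
    if _silverman_bandwidth(ratios, weights) == 0.0 and np.ptp(ratios) > 0:
        raise ValueError("zero bandwidth with non-degenerate ratios")
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)
    se = _bootstrap_se(
        lambda r, w: _weighted_mode_point(r, w, bandwidth_factor),
        bx, by, sx, sy, n_boot, seed,
    )
    sweep = {
        f"bandwidth_factor={f:g}": _weighted_mode_point(ratios, weights, f)
        for f in bandwidth_sweep
    }
    return _wrap("weighted_mode", beta, se, len(pairs), notes={"bandwidth_sweep": sweep})


def _bootstrap_se(point_fn, bx, by, sx, sy, n_boot: int, seed: int) -> float:
    """Parametric bootstrap SE: resample betas from normal(β̂, se)."""
    rng = np.random.default_rng(seed)
    J = len(bx)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx_star[b]
        bxs = np.where(bxs == 0, 1e-12, bxs)
        est[b] = point_fn(by_star[b] / bxs, bxs**2 / sy**2)
    return float(est.std(ddof=1))


def _ivw_beta(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def mr_presso(
    pairs: Sequence[SummaryPair],
    n_sim: int = 1000,
    seed: int = 0,
    alpha_outlier: float = 0.05,
) -> PressoReport:
    """MR-PRESSO: simulation-based pleiotropy residual sum of squares and outlier test.

    The global test compares the observed leave-one-out weighted RSS with
    its null distribution obtained by regenerating outcome betas from the
    leave-one-out IVW fit at the observed SEs. Each variant's own residual
    against its leave-one-out prediction gives a per-variant outlier p
    (Bonferroni-corrected across variants); the corrected estimate is the
    IVW fit on the non-flagged variants; the distortion test compares the
    observed estimate shift after exclusion against shifts from removing
    the same number of randomly chosen variants.
    """
    J = len(pairs)
    if J < 4:
        raise ValueError("MR-PRESSO requires at least 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim too small for a meaningful simulated null")
    if J / (n_sim + 1) >= alpha_outlier:
        logger.warning(
            "n_sim=%d cannot resolve a Bonferroni outlier p below %.3g with %d "
            "variants; increase n_sim above %d", n_sim, alpha_outlier, J,
            int(np.ceil(J / alpha_outlier)),
        )
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = _arrays(pairs)
    w = 1.0 / sy**2

    # leave-one-out IVW slopes
    sw_xy = np.sum(w * bx * by)
    sw_xx = np.sum(w * bx**2)
    beta_loo = (sw_xy - w * bx * by) / (sw_xx - w * bx**2)
    obs_res = w * (by - beta_loo * bx) ** 2
    obs_rss = float(obs_res.sum())

    # simulated null: regenerate betas around the leave-one-out fit
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, J))
    sw_xy_s = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sw_xx_s = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    beta_loo_s = (sw_xy_s - w * bx_sim * by_sim) / (sw_xx_s - w * bx_sim**2)
    sim_res = w * (by_sim - beta_loo_s * bx_sim) ** 2
    sim_rss = sim_res.sum(axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    per_variant_p = (np.sum(sim_res >= obs_res, axis=0) + 1) / (n_sim + 1)
    outlier_p = np.minimum(per_variant_p * J, 1.0)  # Bonferroni
    flags = outlier_p < alpha_outlier

    original = ivw(pairs, "fixed")
    corrected: Optional[MREstimate] = None
    distortion_p: Optional[float] = None
    if flags.all():
        raise ValueError("all variants flagged as outliers; no corrected estimate possible")
    if flags.any():
        keep = [p for p, f in zip(pairs, flags) if not f]
        corrected = ivw(keep, "fixed")
        corrected = replace(corrected, method="presso_corrected")
        n_out = int(flags.sum())
        obs_shift = abs(corrected.beta - original.beta)
        n_draw = min(n_sim, 1000)
        shifts = np.empty(n_draw)
        for d in range(n_draw):
            drop = rng.choice(J, size=n_out, replace=False)
            mask = np.ones(J, bool)
            mask[drop] = False
            shifts[d] = abs(_ivw_beta(bx[mask], by[mask], w[mask]) - original.beta)
        distortion_p = float((np.sum(shifts >= obs_shift) + 1) / (n_draw + 1))
    return PressoReport(
        global_rss=obs_rss,
        global_p=global_p,
        outlier_flags=flags,
        outlier_p=outlier_p,
        distortion_p=distortion_p,
        corrected=corrected,
        original=original,
        n_sim=n_sim,
        seed=seed,
    )


def meta_fixed(estimates: Sequence[MREstimate]) -> MREstimate:
    """Fixed-effects inverse-variance meta-analysis of MR estimates.

    Used to pool the individual-level (UK-Biobank-style) and summary-data
    (AFGen-style) estimates; all inputs must share a reporting scale.
    """
    if len(estimates) < 2:
        raise ValueError("meta-analysis requires at least 2 estimates")
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"estimates on mixed scales {scales}; rescale first")
    b = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - beta) ** 2))
    return _wrap(
        "meta_fixed", beta, se, sum(e.n_variants for e in estimates),
        scale=estimates[0].scale, q_statistic=q, q_df=len(estimates) - 1,
    )


def bidirectional_mr(
    outcome_score_pairs: Sequence[SummaryPair],
    forward_estimate: Optional[MREstimate] = None,
    effects_model: str = "fixed",
) -> MREstimate:
    """Reverse-direction MR: disease liability as exposure, ECG interval as outcome.

    ``outcome_score_pairs`` must be harmonised with the AF-liability score
    variants as exposure and the ECG interval as outcome; the same IVW
    estimator then applies with roles swapped. When the forward estimate
    is supplied, the reverse/forward effect-size ratio (on the common
    scale) is reported in ``notes``.
    """
    est = ivw(outcome_score_pairs, effects_model)
    est = replace(est, method=f"bidirectional_{est.method}")
    if forward_estimate is not None:
        if forward_estimate.scale != est.scale:
            raise ValueError("forward and reverse estimates on different scales")
        if forward_estimate.beta != 0:
            est.notes["reverse_to_forward_ratio"] = est.beta / forward_estimate.beta
    return est


def funnel_table(pairs: Sequence[SummaryPair]) -> "np.ndarray":
    """Per-variant ratio estimate vs precision, the funnel-plot coordinates.

    Returns a structured array with fields (variant_id, ratio, precision);
    asymmetry of ratio about the pooled estimate at low precision suggests
    directional pleiotropy.
    """
    rows = []
    for p in pairs:
        est = wald_ratio(p)
        rows.append((p.variant.id, est.beta, 1.0 / est.se))
    return np.array(rows, dtype=[("variant_id", "U32"), ("ratio", "f8"), ("precision", "f8")])
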