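"""Independent reference implementations used as oracles in tests.

Each function is a deliberately naive, direct transcription of a
definition — loops, enumeration, closed forms — kept free of any code
from the package modules it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def naive_weighted_score(genotypes, weights_by_col):
    """Allele score by explicit double loop."""
    n, m = genotypes.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(m):
            out[i] += weights_by_col[j] * genotypes[i, j]
    return out


def copula_dosage_correlation(f1: float, f2: float, rho: float) -> float:
    """Implied dosage correlation of the Gaussian-copula haplotype model.

    Each haplotype's allele indicators are 1{z < Φ⁻¹(f)} with latent
    correlation rho, so P(both alleles) is the bivariate normal orthant
    probability and the allelic (= dosage) correlation follows from the
    Bernoulli moments.
    """
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    p11 = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    return (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))


def irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-12):
    """Plain iteratively-reweighted least squares for a logistic GLM.

    Returns (coefficients, standard errors) from the Fisher information.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        step = np.linalg.solve(info, X.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def ivw_via_normal_equations(bx, by, sy):
    """Weighted least squares of by on bx through the origin, weights 1/sy²."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    w = 1.0 / sy**2
    beta = (w * bx * by).sum() / (w * bx**2).sum()
    se = (w * bx**2).sum() ** -0.5
    return float(beta), float(se)


def weighted_median_walk(ratios, weights):
    """Weighted median by an explicit cumulative-weight walk with interpolation."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    csum = 0.0
    mid = []
    for wi in w:
        mid.append(csum + wi / 2.0)
        csum += wi
    mid = np.array(mid)
    if 0.5 <= mid[0]:
        return float(r[0])
    if 0.5 >= mid[-1]:
        return float(r[-1])
    k = int(np.searchsorted(mid, 0.5))
    frac = (0.5 - mid[k - 1]) / (mid[k] - mid[k - 1])
    return float(r[k - 1] + frac * (r[k] - r[k - 1]))


def greedy_clump_reference(records, r2_lookup, r2_threshold, window_bp):
    """Direct restatement of greedy p-ascending clumping on index tuples.

    ``records`` is a list of (id, chrom, pos, p); ``r2_lookup`` maps
    frozenset({id_a, id_b}) to r². Returns the retained ids in input order.
    """
    order = sorted(range(len(records)), key=lambda i: (records[i][3], i))
    chosen = []
    for i in order:
        rid, chrom, pos, _ = records[i]
        ok = True
        for j in chosen:
            jid, jchrom, jpos, _ = records[j]
            if jchrom == chrom and abs(jpos - pos) <= window_bp:
                r2 = r2_lookup.get(frozenset((rid, jid)), 0.0)
                if r2 >= r2_threshold:
                    ok = False
                    break
        if ok:
            chosen.append(i)
    return [records[i][0] for i in sorted(chosen)]


def truncated_normal_quintile_means():
    """E[Z | quintile] for a standard normal split at its quintiles."""
    qs = stats.norm.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    means = []
    for lo, hi in zip(qs[:-1], qs[1:]):
        lo_pdf = 0.0 if np.isinf(lo) else stats.norm.pdf(lo)
        hi_pdf = 0.0 if np.isinf(hi) else stats.norm.pdf(hi)
        means.append((lo_pdf - hi_pdf) / 0.2)
    return np.array(means)
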