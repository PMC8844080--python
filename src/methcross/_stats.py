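"""Shared statistical primitives: beta-binomial likelihood and rank tests.

The beta-binomial parameterisation used throughout is (p, rho): mean
proportion p and intra-class correlation rho in (0, 1), with classical
shape parameters a = p * t, b = (1 - p) * t where t = (1 - rho) / rho.
rho -> 0 recovers the binomial.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

_EPS_P = 1e-6


def betabinom_loglik(k, n, p: float, rho: float) -> float:
    """Log-likelihood of counts k out of n under BetaBinomial(p, rho).

    k, n are arrays (replicates); the binomial coefficient term is omitted
    (constant in p, rho), so values are comparable across parameters only.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = min(max(p, _EPS_P), 1.0 - _EPS_P)
    rho = min(max(rho, 1e-8), 1.0 - 1e-8)
    t = (1.0 - rho) / rho
    a = p * t
    b = (1.0 - p) * t
    return float(
        np.sum(
            special.gammaln(k + a)
            + special.gammaln(n - k + b)
            - special.gammaln(n + a + b)
            + special.gammaln(a + b)
            - special.gammaln(a)
            - special.gammaln(b)
        )
    )


def betabinom_mle_p(k, n, rho: float) -> tuple[float, float]:
    """Profile MLE of the mean proportion p at fixed dispersion rho.

    Returns (p_hat, loglik). Seeds the bounded search at the pooled
    proportion, which is the exact MLE in the binomial limit.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    tot = n.sum()
    if tot <= 0:
        return float("nan"), 0.0
    p0 = float(np.clip(k.sum() / tot, _EPS_P, 1 - _EPS_P))
    if rho < 1e-6 or len(k) == 1:
        return p0, betabinom_loglik(k, n, p0, max(rho, 1e-8))
    res = optimize.minimize_scalar(
        lambda p: -betabinom_loglik(k, n, p, rho),
        bounds=(_EPS_P, 1 - _EPS_P),
        method="bounded",
        options={"xatol": 1e-7},
    )
    p_hat = float(res.x)
    ll = -float(res.fun)
    ll0 = betabinom_loglik(k, n, p0, rho)
    if ll0 > ll:  # bounded search can stall on flat likelihoods
        return p0, ll0
    return p_hat, ll


def mom_icc(k, n, groups) -> float:
    """Method-of-moments intra-class correlation from replicate scatter.

    Pools the within-group binomial chi-square over both groups and solves
    E[X2] = df * (1 + (n_eff - 1) * rho) for rho. Returns 0 when there is no
    replication to estimate from, or when scatter is sub-binomial.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    groups = np.asarray(groups)
    x2 = 0.0
    df = 0
    wsum = 0.0
    n_contrib = 0
    for g in np.unique(groups):
        sel = groups == g
        kg, ng = k[sel], n[sel]
        ok = ng > 0
        kg, ng = kg[ok], ng[ok]
        if len(ng) < 2:
            continue
        p = kg.sum() / ng.sum()
        if p <= 0 or p >= 1:
            continue
        x2 += float(np.sum((kg - ng * p) ** 2 / (ng * p * (1 - p))))
        df += len(ng) - 1
        wsum += float(np.sum(ng)) / len(ng)  # mean replicate depth
        n_contrib += 1
    if df == 0 or wsum == 0:
        return 0.0
    n_eff = wsum / n_contrib
    if n_eff <= 1:
        return 0.0
    rho = (x2 / df - 1.0) / (n_eff - 1.0)
    return float(np.clip(rho, 0.0, 0.5))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def ranksum_test(x, y, min_n: int = 1):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution for small samples, normal approximation with
    continuity correction otherwise (scipy's automatic switch). Returns
    (statistic, p) or (nan, nan) if either sample is smaller than *min_n*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < min_n or len(y) < min_n:
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x, y):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's convention); returns (nan, 1.0)
    when every pair is tied — identical inputs are evidence for the null,
    not an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    d = d[d != 0]
    if len(d) == 0:
        return float("nan"), 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)
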