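"""Statistical battery for condition comparisons.

Linear quantities (per-animal correlogram peaks, Fourier amplitudes,
signal values) are compared between well-fed and starved cohorts with
the Brunner-Munzel rank test, which estimates the relative effect
p = P(A < B) + 0.5 P(A = B) without assuming normality or equal
variances.  Circular quantities (per-animal weighted mean phase
directions) use the V test (modified Rayleigh: uniformity against a
unimodal alternative at a pre-specified direction), Watson's U^2
goodness-of-fit check for the von Mises assumption the V test needs,
and the Mardia-Watson-Wheeler uniform-scores test for two-sample
homogeneity.  Family-wise error is controlled by Bonferroni division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sstats

from .errors import DegenerateSignalError, ParameterError


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    estimate: float | None = None   # relative effect (BM) / resultant length (circular)
    ci_low: float | None = None
    ci_high: float | None = None
    df: float | None = None
    alpha: float | None = None
    reject: bool | None = None
    critical_value: float | None = None
    tie_warning: bool = False


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * np.asarray(a, dtype=float)))


def circular_mean_resultant(
    angles: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """(mean direction, mean resultant length) of a circular sample."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    z = np.sum(weights * np.exp(1j * angles))
    total = np.sum(weights)
    return float(np.angle(z)), float(np.abs(z) / total)


def brunner_munzel(a, b, alpha: float = 0.05) -> TestResult:
    """Brunner-Munzel test of the relative effect P(A < B) + 0.5 P(A = B).

    Mid-rank estimator, studentized with Satterthwaite-type degrees of
    freedom, two-sided p from the t distribution, and a Wald confidence
    interval for the relative effect at level 1 - ``alpha``.
    Complete separation gives estimate 0 or 1 with an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 4:
        raise ParameterError(f"need n >= 4 per sample, got {n1}, {n2}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateSignalError("all values identical across both samples")
    n = n1 + n2
    r = sstats.rankdata(pooled)          # pooled mid-ranks
    r1, r2 = r[:n1], r[n1:]
    ri1 = sstats.rankdata(a)             # within-sample mid-ranks
    ri2 = sstats.rankdata(b)
    m1, m2 = float(np.mean(r1)), float(np.mean(r2))
    p_hat = (m2 - (n2 + 1) / 2.0) / n1
    v1 = np.sum((r1 - ri1 - m1 + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    v2 = np.sum((r2 - ri2 - m2 + (n2 + 1) / 2.0) ** 2) / (n2 - 1)
    denom = np.sqrt(n1 * v1 + n2 * v2)
    if denom == 0.0:
        stat = np.inf * np.sign(m2 - m1) if m2 != m1 else 0.0
        p = 0.0 if m2 != m1 else 1.0
        return TestResult(
            "brunner_munzel", float(stat), float(p), n1, n2,
            estimate=float(p_hat), ci_low=float(p_hat), ci_high=float(p_hat),
            df=float("nan"), alpha=alpha,
        )
    stat = n1 * n2 * (m2 - m1) / (n * denom)
    df = (n1 * v1 + n2 * v2) ** 2 / (
        (n1 * v1) ** 2 / (n1 - 1) + (n2 * v2) ** 2 / (n2 - 1)
    )
    p = 2.0 * sstats.t.sf(abs(stat), df)
    se = np.sqrt(v1 / (n1 * n2**2) + v2 / (n2 * n1**2))
    tq = sstats.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(
        "brunner_munzel", float(stat), float(p), n1, n2,
        estimate=float(p_hat),
        ci_low=float(p_hat - tq * se), ci_high=float(p_hat + tq * se),
        df=float(df), alpha=alpha,
    )


def v_test(angles, mu0: float) -> TestResult:
    """V test (modified Rayleigh) for uniformity against a unimodal
    alternative concentrated at the pre-specified direction ``mu0``.

    V = Rbar * cos(thetabar - mu0); u = V * sqrt(2n); one-sided p from
    the standard normal upper tail.
    """
    angles = _wrap(angles)
    n = angles.size
    if n < 5:
        raise ParameterError(f"V test needs n >= 5, got {n}")
    theta_bar, r_bar = circular_mean_resultant(angles)
    V = r_bar * np.cos(theta_bar - mu0)
    u = V * np.sqrt(2.0 * n)
    p = float(sstats.norm.sf(u))
    return TestResult("v_test", float(V), p, n, estimate=float(r_bar))


def _kappa_mle(r_bar: float, n: int) -> float:
    """Maximum-likelihood concentration of a von Mises sample from Rbar."""
    if r_bar >= 1.0 - 1e-12:
        return 1e6
    if r_bar <= 1e-12:
        return 0.0

    def a1_diff(k: float) -> float:
        return special.i1(k) / special.i0(k) - r_bar

    # A1 is increasing in kappa; bracket then solve
    hi = 1.0
    while a1_diff(hi) < 0 and hi < 1e6:
        hi *= 2.0
    from scipy.optimize import brentq

    return float(brentq(a1_diff, 1e-12, hi))


# Upper percentage points of Watson's U^2 for a von Mises null with both
# parameters estimated (Lockhart & Stephens); rows indexed by kappa.
_WATSON_KAPPA = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 4.0, np.inf])
_WATSON_ALPHAS = (0.10, 0.05, 0.01)
_WATSON_CRIT = np.array(
    [
        [0.052, 0.061, 0.081],
        [0.056, 0.066, 0.090],
        [0.066, 0.079, 0.110],
        [0.077, 0.092, 0.128],
        [0.084, 0.101, 0.142],
        [0.093, 0.113, 0.158],
        [0.096, 0.117, 0.164],
    ]
)


def watson_vonmises_gof(angles, alpha: float = 0.05) -> TestResult:
    """Watson's U^2 goodness-of-fit test for a von Mises distribution with
    parameters estimated from the sample.

    The statistic is compared with the published critical value at
    ``alpha`` (0.10, 0.05 or 0.01), selected/interpolated by the
    estimated concentration kappa.
    """
    angles = _wrap(angles)
    n = angles.size
    if n < 10:
        raise ParameterError(f"Watson GOF needs n >= 10, got {n}")
    if alpha not in _WATSON_ALPHAS:
        raise ParameterError(f"alpha must be one of {_WATSON_ALPHAS}")
    mu_hat, r_bar = circular_mean_resultant(angles)
    kappa_hat = _kappa_mle(r_bar, n)
    centered = _wrap(angles - mu_hat)
    z = np.sort(sstats.vonmises.cdf(centered, kappa_hat))
    i = np.arange(1, n + 1)
    u2 = float(np.sum((z - (2 * i - 1) / (2 * n)) ** 2)
               + 1.0 / (12 * n) - n * (np.mean(z) - 0.5) ** 2)
    col = _WATSON_ALPHAS.index(alpha)
    k_clip = min(kappa_hat, _WATSON_KAPPA[-2] * 2)  # beyond 2*4 use the Inf row
    if kappa_hat > _WATSON_KAPPA[-2]:
        crit = float(_WATSON_CRIT[-1, col])
    else:
        crit = float(np.interp(k_clip, _WATSON_KAPPA[:-1], _WATSON_CRIT[:-1, col]))
    return TestResult(
        "watson_vonmises_gof", u2, float("nan"), n,
        estimate=float(kappa_hat), alpha=alpha, reject=bool(u2 > crit),
        critical_value=crit,
    )


def mardia_watson_wheeler(
    a, b, n_perm: int = 9999, seed: int | None = None
) -> TestResult:
    """Mardia-Watson-Wheeler uniform-scores test for two-sample homogeneity
    of circular data (difference in mean direction and/or dispersion).

    Pooled mid-ranks are mapped to uniform scores beta = 2*pi*rank/N and
    W = 2 (R1^2/n1 + R2^2/n2) is formed from the group resultants of the
    scores.  p comes from chi^2 with 2 df when both groups have n >= 10,
    otherwise from a seeded permutation reference of size ``n_perm``.
    A tie fraction above 20% of the pooled sample sets ``tie_warning``.
    """
    a = _wrap(a)
    b = _wrap(b)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 5:
        raise ParameterError(f"need n >= 5 per sample, got {n1}, {n2}")
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_warning = bool(np.sum(counts[counts > 1]) > 0.2 * n)
    ranks = sstats.rankdata(pooled)
    beta = 2.0 * np.pi * ranks / n

    def w_stat(labels: np.ndarray) -> float:
        z1 = np.sum(np.exp(1j * beta[labels]))
        z2 = np.sum(np.exp(1j * beta[~labels]))
        return float(2.0 * (np.abs(z1) ** 2 / n1 + np.abs(z2) ** 2 / n2))

    labels = np.zeros(n, dtype=bool)
    labels[:n1] = True
    W = w_stat(labels)
    if min(n1, n2) >= 10:
        p = float(sstats.chi2.sf(W, df=2))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            count += w_stat(labels[perm]) >= W
        p = (count + 1) / (n_perm + 1)
    return TestResult(
        "mardia_watson_wheeler", W, float(p), n1, n2, df=2.0,
        tie_warning=tie_warning,
    )


def bonferroni_alpha(family_alpha: float, k: int) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if not 0.0 < family_alpha < 1.0:
        raise ParameterError(f"family alpha must be in (0, 1), got {family_alpha}")
    if k < 1:
        raise ParameterError(f"number of tests must be >= 1, got {k}")
    return family_alpha / k
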