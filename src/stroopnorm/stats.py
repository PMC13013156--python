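"""Statistical utilities for study design and task comparisons.

Covers the self-contained pieces of the norming study's inferential
machinery: the Cohen's-f2 a-priori power analysis for the multiple-regression
F-test, the Greenhouse-Geisser sphericity-correction factor, paired Cohen's
d, and Holm-Bonferroni step-down adjustment.  (Full repeated-measures ANOVA F
computation is deliberately out of scope; these utilities support effect-size
and multiplicity reporting around it.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerSpec",
    "PowerResult",
    "f2_power",
    "required_n_f2",
    "gg_epsilon",
    "cohens_d_paired",
    "holm_adjust",
]


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power analysis for testing u regressors at effect size f2."""

    u: int
    f2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if not self.f2 > 0:
            raise ValueError("f2 must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Power-analysis solution with both reporting conventions exposed.

    The R convention (pwr.f2.test) reports the solved denominator df ``v``
    itself as the suggested sample size, while the total regression n is
    ``u + v + 1``; both are returned so either convention is inspectable.
    """

    v: float            # denominator df solving the power equation
    n_suggested: int    # round(v): the pwr.f2.test-style reported size
    n_total_exact: float  # u + v + 1
    n_total: int        # round(u + v + 1)


def f2_power(u: int, v: float, f2: float, alpha: float = 0.05) -> float:
    """Power of the F-test of u regressors with noncentrality f2*(u+v+1)."""
    lam = f2 * (u + v + 1)
    fcrit = stats.f.isf(alpha, u, v)
    return float(stats.ncf.sf(fcrit, u, v, lam))


def required_n_f2(spec: PowerSpec) -> PowerResult:
    """Solve the a-priori sample size for the multiple-regression F-test.

    Finds the denominator df v at which the noncentral-F power function
    (noncentrality lambda = f2 * (u + v + 1)) attains the requested power.
    Power is monotone increasing in v, so the root is unique; it is located
    by bracketed root-finding.  At (u=3, f2=0.03, alpha=0.05, power=0.80)
    this gives v = 363.35, i.e. a suggested size of 363 under the
    pwr.f2.test reporting convention (367 as total round(u + v + 1)).
    """
    u, f2, alpha, power = spec.u, spec.f2, spec.alpha, spec.power

    def gap(v):
        return f2_power(u, v, f2, alpha) - power

    lo, hi = 1.0, 16.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e9:
            raise ValueError("requested power unattainable at this effect size")
    if gap(lo) >= 0:
        v = lo
    else:
        v = optimize.brentq(gap, lo, hi, xtol=1e-10)
    n_exact = u + v + 1
    return PowerResult(v=float(v), n_suggested=int(round(v)),
                       n_total_exact=float(n_exact), n_total=int(round(n_exact)))


def gg_epsilon(condition_covariance) -> float:
    """Greenhouse-Geisser epsilon from a k x k condition covariance matrix.

    Uses the trace form on the double-centred covariance A = C S C with
    C = I - J/k:  epsilon = tr(A)^2 / ((k-1) tr(A^2)), clipped to the
    theoretical range (1/(k-1), 1].  Requires a symmetric PSD input; k = 2
    designs are always spherical (epsilon = 1).
    """
    S = np.asarray(condition_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("condition covariance must be square")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least two repeated conditions")
    if not np.allclose(S, S.T, rtol=1e-8, atol=1e-10):
        raise ValueError("condition covariance must be symmetric")
    C = np.eye(k) - np.ones((k, k)) / k
    A = C @ S @ C
    denom = (k - 1) * np.trace(A @ A)
    if denom <= 0:
        return 1.0  # degenerate (e.g. zero between-condition variance)
    eps = float(np.trace(A) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d: mean(x - y) / SD(x - y), sample SD (ddof = 1).

    A zero-SD difference with nonzero mean is an infinite effect and is
    reported as signed infinity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    m = float(np.mean(d))
    if sd == 0:
        return 0.0 if m == 0 else math.copysign(math.inf, m)
    return m / sd


def holm_adjust(p) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values (order-preserving).

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) on the ascending
    ordering; monotonicity is enforced, output follows the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-d")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()
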