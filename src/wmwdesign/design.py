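"""Sample-size formula, optimal allocation rate, and balance diagnostics.

With effect estimates (p, sigma0, sigma1, sigma2) fixed by the synthetic
data, the total sample size needed to detect p != 1/2 with a two-sided
asymptotic rank test at level alpha and power 1 - beta, when a fraction
t = n1/N is allocated to the reference group, is

    N(t) = [ sigma0 * u_{1-a/2} + u_{1-b} * sqrt(t*s2^2 + (1-t)*s1^2) ]^2
           / [ t (1-t) (p - 1/2)^2 ],

with u_c the standard normal quantile.  The allocation rate t0 minimizing
N is unique on (0, 1); it equals 1/2 exactly when sigma1 = sigma2, and is
below (above) 1/2 exactly when sigma1 < sigma2 (sigma1 > sigma2).  A
closed-form bracketing interval for t0, built from kappa = sigma2/sigma1
and the design quantiles, is provided alongside the numeric minimizer; the
numeric minimizer is authoritative.

Noether's classical formula — which replaces the variance under the
alternative by the null variance 1/12 of continuous tie-free data — is
included as a comparator; it can grossly oversize a study when the data
are tied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .ranks import EffectEstimates, effect_and_variances, integral_oracle, normalized_ecdf

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "AllocationInterval",
    "BalanceReport",
    "sample_size_exact",
    "sample_size_at_t",
    "noether_sample_size",
    "optimize_allocation",
    "allocation_interval",
    "balance_diagnostics",
]

_T_DOMAIN = (1e-3, 1.0 - 1e-3)
_KAPPA_EQ_RTOL = 1e-12


@dataclass(frozen=True)
class DesignSpec:
    """Type-I error rate, target power, and allocation request."""

    alpha: float = 0.05
    power: float = 0.80
    t: float | str = 0.5  # rate in (0,1), or "balanced" / "optimize"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if isinstance(self.t, str):
            if self.t not in ("balanced", "optimize"):
                raise ValueError("t must be a rate in (0,1), 'balanced' or 'optimize'")
        elif not 0.0 < self.t < 1.0:
            raise ValueError("t must be in (0, 1)")
        if self.power <= 0.5:
            warnings.warn("power <= 0.5: the allocation-interval theory "
                          "assumes 1 - beta > 1/2", stacklevel=2)

    @property
    def u_alpha(self) -> float:
        return float(norm.ppf(1.0 - self.alpha / 2.0))

    @property
    def u_beta(self) -> float:
        return float(norm.ppf(self.power))


@dataclass(frozen=True)
class SampleSizeResult:
    """A rounded two-group design.

    n1 and n2 are each rounded up from the exact real-valued solution, so
    N = n1 + n2 >= N_exact always.
    """

    t_used: float
    N_exact: float
    n1: int
    n2: int
    method: str = "proposed"

    @property
    def N(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class AllocationInterval:
    """Closed-form bounds bracketing the optimal allocation rate t0."""

    lower: float
    upper: float
    t0: float
    kappa_branch: str


@dataclass(frozen=True)
class BalanceReport:
    """Diagnostics for whether a balanced design is optimal.

    `integral_lhs` and `integral_rhs` are the two sides of the balance
    characterization  integral F1^2 dF2 = integral (1-F2)^2 dF1,  which
    holds iff sigma1 = sigma2 iff t0 = 1/2.  `mirror` reports whether an
    `a` exists with F1(a + x) = 1 - F2(a - x) on the whole support — a
    sufficient (not necessary) condition for balance; F1 = F2 with a
    non-symmetric shape satisfies the integral equation but not the mirror
    condition.
    """

    sigma1_sq: float
    sigma2_sq: float
    sigma_diff: float
    integral_lhs: float
    integral_rhs: float
    mirror: bool
    mirror_a: float | None


def _check_effects(effects: EffectEstimates) -> None:
    if effects.sigma0_sq <= 0.0:
        raise ValueError("degenerate synthetic data (all values tied)")
    if abs(effects.p - 0.5) < 1e-12:
        raise ValueError("no effect to detect (p = 1/2)")


def sample_size_exact(effects: EffectEstimates, design: DesignSpec, t: float) -> float:
    """Exact (real-valued) total sample size N(t) at allocation rate t."""
    if not 0.0 < t < 1.0:
        raise ValueError("t must be in (0, 1)")
    _check_effects(effects)
    num = (effects.sigma0 * design.u_alpha
           + design.u_beta * math.sqrt(t * effects.sigma2_sq
                                       + (1.0 - t) * effects.sigma1_sq)) ** 2
    return num / (t * (1.0 - t) * (effects.p - 0.5) ** 2)


def _round_design(N_exact: float, t: float, method: str) -> SampleSizeResult:
    # per-group ceiling; tiny slack so that exact integers are not bumped up
    eps = 1e-9
    n1 = int(math.ceil(t * N_exact - eps))
    n2 = int(math.ceil((1.0 - t) * N_exact - eps))
    return SampleSizeResult(t_used=t, N_exact=N_exact, n1=n1, n2=n2, method=method)


def sample_size_at_t(effects: EffectEstimates, design: DesignSpec,
                     t: float | None = None) -> SampleSizeResult:
    """Rounded design at a fixed allocation rate (default: the spec's t)."""
    if t is None:
        t = 0.5 if isinstance(design.t, str) else design.t
    return _round_design(sample_size_exact(effects, design, t), t, "proposed")


def noether_sample_size(p: float, design: DesignSpec, t: float = 0.5) -> SampleSizeResult:
    """Noether's approximation: null variance 1/12 in place of the
    alternative-hypothesis variance.

    N = (u_{1-a/2} + u_{1-b})^2 / (12 t (1-t) (p - 1/2)^2).  Exact only for
    continuous tie-free data; with ties it can dramatically overshoot.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("t must be in (0, 1)")
    if abs(p - 0.5) < 1e-12:
        raise ValueError("no effect to detect (p = 1/2)")
    N_exact = (design.u_alpha + design.u_beta) ** 2 / (
        12.0 * t * (1.0 - t) * (p - 0.5) ** 2)
    return _round_design(N_exact, t, "noether")


def optimize_allocation(effects: EffectEstimates,
                        design: DesignSpec) -> tuple[float, SampleSizeResult]:
    """Numerically locate t0 = argmin N(t) and the rounded design there.

    Derivative-free bounded minimization on [1e-3, 1 - 1e-3] to absolute
    tolerance 1e-6; the minimizer is unique.  Ties within 1e-9 of the
    balanced sample size break toward t = 1/2.
    """
    _check_effects(effects)
    res = minimize_scalar(lambda t: sample_size_exact(effects, design, t),
                          bounds=_T_DOMAIN, method="bounded",
                          options={"xatol": 1e-6})
    t0 = float(res.x)
    n_half = sample_size_exact(effects, design, 0.5)
    if n_half <= res.fun + 1e-9 * max(1.0, n_half):
        t0 = 0.5
    return t0, _round_design(sample_size_exact(effects, design, t0), t0, "proposed")


def _sigmas_equal(s1: float, s2: float) -> bool:
    return abs(s1 - s2) <= _KAPPA_EQ_RTOL * max(s1, s2, 1e-300)


def _interval_below_half(s1: float, s2: float, sigma0: float,
                         ua: float, ub: float) -> tuple[float, float]:
    """Closed-form bounds for t0 when s1 < s2 (so t0 < 1/2).

    At the minimizer of N(t), w = 1 - 2*t satisfies the stationarity
    relation  w = C(s) * (1 - w^2) / 4  with

        C(s) = u_{1-b} (s2^2 - s1^2) / ( s * (u_{1-a/2} sigma0 + u_{1-b} s) ),
        s(t) = sqrt(t s2^2 + (1-t) s1^2),

    whose positive root is w = C / (2 + sqrt(4 + C^2)), increasing in C.
    Because s is increasing in t and t0 < 1/2, s(t0) never exceeds
    s(1/2) = sqrt((s1^2 + s2^2)/2); plugging that into C yields a valid
    upper bound for t0.  The lower bound is the variance-ratio allocation
    I1 = s1/(s1 + s2) = 1/(kappa + 1), the exact limit of t0 as the power
    approaches 1; when s1 = 0 it degenerates and is replaced by

        I1_0 = (u_{1-a/2} sigma0 / 2) / (u_{1-a/2} sigma0 + u_{1-b} s2),

    which follows from the same stationarity relation via t0 = 1/(2 + r),
    r = u_{1-b} s2 sqrt(t0) / (u_{1-a/2} sigma0) and sqrt(t0) < 1/sqrt(2).
    """
    def upper_from(s: float) -> float:
        c = ub * (s2**2 - s1**2) / (s * (ua * sigma0 + ub * s))
        w = c / (2.0 + math.sqrt(4.0 + c * c))
        return (1.0 - w) / 2.0

    s_half = math.sqrt((s1**2 + s2**2) / 2.0)
    upper = upper_from(s_half)
    if s1 == 0.0:
        lower = (ua * sigma0 / 2.0) / (ua * sigma0 + ub * s2)
    else:
        lower = s1 / (s1 + s2)
    return lower, upper


def allocation_interval(effects: EffectEstimates, design: DesignSpec) -> AllocationInterval:
    """Closed-form interval bracketing the optimal allocation rate t0.

    The sign of t0 - 1/2 is governed by kappa = sigma2/sigma1: the interval
    lies entirely below 1/2 when sigma1 < sigma2, entirely above when
    sigma1 > sigma2, and collapses to the point 1/2 when sigma1 = sigma2.
    See :func:`_interval_below_half` for the bound construction; larger
    alpha or larger power pushes the bound farther from 1/2, and as power
    tends to 1 the interval shrinks toward the variance-ratio allocation
    1/(kappa + 1).  The interval is advisory: the numeric minimizer is
    always computed, and a bracketing failure raises rather than passing
    silently.
    """
    if design.power <= 0.5:
        raise ValueError("interval theory requires 1 - beta > 0.5")
    _check_effects(effects)
    s1, s2 = effects.sigma1, effects.sigma2
    if s1 == 0.0 and s2 == 0.0:
        raise ValueError("sigma1 and sigma2 are both zero")
    ua, ub = design.u_alpha, design.u_beta

    t0, _ = optimize_allocation(effects, design)

    if _sigmas_equal(s1, s2):
        branch = "sigma1=sigma2"
        lower = upper = 0.5
    elif s1 < s2:
        branch = "sigma1=0" if s1 == 0.0 else "sigma1<sigma2"
        lower, upper = _interval_below_half(s1, s2, effects.sigma0, ua, ub)
    else:
        branch = "sigma2=0" if s2 == 0.0 else "sigma1>sigma2"
        lo, hi = _interval_below_half(s2, s1, effects.sigma0, ua, ub)
        lower, upper = 1.0 - hi, 1.0 - lo

    if not (lower - 1e-6 <= t0 <= upper + 1e-6):
        raise RuntimeError(
            f"allocation interval [{lower:.6f}, {upper:.6f}] fails to bracket "
            f"the numeric minimizer t0 = {t0:.6f}; closed form invalid here")
    return AllocationInterval(lower=lower, upper=upper, t0=t0, kappa_branch=branch)


def _mirror_condition(x1: np.ndarray, x2: np.ndarray, tol: float = 1e-9):
    """Search for `a` with F1(a+x) = 1 - F2(a-x) at all support points.

    Equivalent to: the distribution of 2a - X2 equals F1.  The only
    candidate aligning the supports is a = (min x1 + max x2)/2.
    """
    a = 0.5 * (x1.min() + x2.max())
    mirrored = 2.0 * a - x2
    support = np.unique(np.concatenate([x1, mirrored]))
    f1 = normalized_ecdf(x1, support)
    fm = normalized_ecdf(mirrored, support)
    ok = bool(np.all(np.abs(f1 - fm) <= tol))
    return ok, (float(a) if ok else None)


def balance_diagnostics(sample1, sample2) -> BalanceReport:
    """Is a balanced design optimal for this synthetic-data pair?"""
    est = effect_and_variances(sample1, sample2)
    x1 = np.asarray(sample1, dtype=float).ravel()
    x2 = np.asarray(sample2, dtype=float).ravel()
    lhs = float(np.mean(normalized_ecdf(x1, x2) ** 2))       # int F1^2 dF2
    rhs = float(np.mean((1.0 - normalized_ecdf(x2, x1)) ** 2))  # int (1-F2)^2 dF1
    mirror, a = _mirror_condition(x1, x2)
    return BalanceReport(sigma1_sq=est.sigma1_sq, sigma2_sq=est.sigma2_sq,
                         sigma_diff=est.sigma1_sq - est.sigma2_sq,
                         integral_lhs=lhs, integral_rhs=rhs,
                         mirror=mirror, mirror_a=a)
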