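"""Midranks, placements, and nonparametric effect/variance estimation.

The nonparametric relative effect

    p = P(X1 < X2) + 0.5 * P(X1 = X2) = integral of F1 dF2,

with all cdfs taken in normalized form F = (F+ + F-)/2, is the effect
measure underlying the Wilcoxon-Mann-Whitney test.  When the two samples
are treated as *fixed* theoretical distributions ("synthetic data": a
prior-information sample for the reference group and an artificially
generated sample for the relevant alternative), the effect and every
variance component that enters the sample-size formula can be computed
exactly from midranks and placements.  Because the samples play the role
of populations, all variances use population divisors (N, n_i), never
N - 1 or n_i - 1.

Two independent computational routes are provided:

* :func:`effect_and_variances` — the rank/placement identities
  (fast, O(N log N)).
* :func:`integral_oracle` — direct evaluation of the defining integrals
  over the normalized empirical cdfs (slower, used for cross-validation).

Both return the same :class:`EffectEstimates` up to floating point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "FrequencyTable",
    "RankSummary",
    "EffectEstimates",
    "midranks",
    "pooled_ranking",
    "effect_and_variances",
    "effect_from_frequency_table",
    "integral_oracle",
]


def as_observations(values, name: str = "values") -> np.ndarray:
    """Validate and coerce a sample to a 1-d float array.

    Ordering of entries carries no meaning; every statistic downstream is
    permutation invariant.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name}: no observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: all values must be finite")
    return arr


@dataclass(frozen=True)
class FrequencyTable:
    """Ordered-categorical data for two groups.

    Categories are taken in the given order as the ordinal order; labels are
    never re-sorted.  Weights may be counts or probabilities — only the
    normalized per-group relative frequencies matter.
    """

    categories: tuple
    weights1: np.ndarray
    weights2: np.ndarray

    def __post_init__(self):
        w1 = np.asarray(self.weights1, dtype=float).ravel()
        w2 = np.asarray(self.weights2, dtype=float).ravel()
        cats = tuple(self.categories)
        if len(cats) < 2:
            raise ValueError("need >= 2 categories")
        if w1.size != len(cats) or w2.size != len(cats):
            raise ValueError("weights must have one entry per category")
        for name, w in (("group1", w1), ("group2", w2)):
            if np.any(w < 0):
                raise ValueError(f"{name}: negative weight")
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name}: non-finite weight")
            if w.sum() <= 0:
                raise ValueError(f"{name}: weights sum to zero")
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "weights1", w1)
        object.__setattr__(self, "weights2", w2)

    @property
    def m(self) -> int:
        return len(self.categories)

    def relative_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        return self.weights1 / self.weights1.sum(), self.weights2 / self.weights2.sum()


@dataclass(frozen=True)
class RankSummary:
    """Overall midranks, within-group midranks and placements for a pooled pair.

    The placement of an observation is the other group's size times the other
    group's normalized empirical cdf evaluated at that observation; it equals
    the overall midrank minus the within-group midrank.
    """

    overall_midranks: tuple[np.ndarray, np.ndarray]
    internal_midranks: tuple[np.ndarray, np.ndarray]
    placements: tuple[np.ndarray, np.ndarray]
    rank_means: tuple[float, float]
    placement_means: tuple[float, float]
    n1: int
    n2: int

    @property
    def N(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class EffectEstimates:
    """Relative effect and variance components of a synthetic-data pair.

    Attributes
    ----------
    p : float
        Relative effect in [0, 1].
    sigma0_sq : float
        Pooled null variance, integral of (F*)^2 dF* - 1/4, where F* is the
        normalized cdf of the combined synthetic sample.  Equals
        (N^2 - 1)/(12 N^2) for a tie-free pooled sample of size N; ties only
        reduce it.
    sigma1_sq, sigma2_sq : float
        Variance components under the alternative, Var(F2(X1)) and
        Var(F1(X2)); each lies in [0, 1/4].
    """

    p: float
    sigma0_sq: float
    sigma1_sq: float
    sigma2_sq: float

    @property
    def sigma0(self) -> float:
        return float(np.sqrt(self.sigma0_sq))

    @property
    def sigma1(self) -> float:
        return float(np.sqrt(self.sigma1_sq))

    @property
    def sigma2(self) -> float:
        return float(np.sqrt(self.sigma2_sq))

    @property
    def kappa_defined(self) -> bool:
        """False when sigma1 = 0, where the ratio sigma2/sigma1 diverges."""
        return self.sigma1_sq > 0.0

    @property
    def kappa(self) -> float:
        """Ratio sigma2/sigma1; +inf when sigma1 = 0 < sigma2, nan if both 0."""
        if self.sigma1_sq > 0.0:
            return self.sigma2 / self.sigma1
        return float("inf") if self.sigma2_sq > 0.0 else float("nan")

    @property
    def q(self) -> float:
        """p(1 - p), the Bernoulli-type bound on the alternative variances."""
        return self.p * (1.0 - self.p)


def midranks(values) -> np.ndarray:
    """Midranks of a sample: tied observations get the mean ordinal rank.

    Equivalent to n * F_hat(x) + 1/2 with F_hat the normalized empirical cdf.
    Ranks always sum to n(n+1)/2.
    """
    return rankdata(as_observations(values), method="average")


def pooled_ranking(sample1, sample2) -> RankSummary:
    """Overall/internal midranks and placements for two pooled samples."""
    x1 = as_observations(sample1, "sample1")
    x2 = as_observations(sample2, "sample2")
    n1, n2 = x1.size, x2.size
    overall = rankdata(np.concatenate([x1, x2]), method="average")
    r1, r2 = overall[:n1], overall[n1:]
    r1_int = rankdata(x1, method="average")
    r2_int = rankdata(x2, method="average")
    p1 = r1 - r1_int
    p2 = r2 - r2_int
    return RankSummary(
        overall_midranks=(r1, r2),
        internal_midranks=(r1_int, r2_int),
        placements=(p1, p2),
        rank_means=(float(r1.mean()), float(r2.mean())),
        placement_means=(float(p1.mean()), float(p2.mean())),
        n1=n1,
        n2=n2,
    )


def effect_and_variances(sample1, sample2, null_variance: str = "pooled") -> EffectEstimates:
    """Relative effect and variance components from rank/placement identities.

    Parameters
    ----------
    sample1, sample2 : array-like
        The reference (prior information) and alternative synthetic samples.
    null_variance : {"pooled", "reference"}
        "pooled" (default) computes sigma0_sq from the combined sample's
        midranks; "reference" uses only the first sample
        (integral of F1^2 dF1 - 1/4), the continuous-theory null variance.
    """
    rs = pooled_ranking(sample1, sample2)
    n1, n2, N = rs.n1, rs.n2, rs.N
    r_all = np.concatenate(rs.overall_midranks)
    p = (rs.rank_means[1] - rs.rank_means[0]) / N + 0.5
    if null_variance == "pooled":
        sigma0_sq = float(np.sum((r_all - (N + 1) / 2.0) ** 2) / N**3)
    elif null_variance == "reference":
        r1i = rs.internal_midranks[0]
        sigma0_sq = float(np.sum((r1i - (n1 + 1) / 2.0) ** 2) / n1**3)
    else:
        raise ValueError("null_variance must be 'pooled' or 'reference'")
    p1, p2 = rs.placements
    sigma1_sq = float(np.sum((p1 - p1.mean()) ** 2) / (n1 * n2**2))
    sigma2_sq = float(np.sum((p2 - p2.mean()) ** 2) / (n1**2 * n2))
    return EffectEstimates(p=float(p), sigma0_sq=sigma0_sq,
                           sigma1_sq=sigma1_sq, sigma2_sq=sigma2_sq)


def effect_from_frequency_table(table: FrequencyTable,
                                pool_weight: float = 0.5) -> EffectEstimates:
    """Effect and variances straight from an ordered-categorical table.

    Works on relative frequencies, so it is exact for any (possibly
    non-integer) weights and agrees with :func:`effect_and_variances` on any
    integer expansion of the table whose group sizes are in the ratio
    pool_weight : (1 - pool_weight).

    Parameters
    ----------
    pool_weight : float in (0, 1)
        Fraction of group 1 in the pooled synthetic sample; enters only the
        pooled null variance sigma0_sq.
    """
    if not 0.0 < pool_weight < 1.0:
        raise ValueError("pool_weight must be in (0, 1)")
    f1, f2 = table.relative_frequencies()
    # normalized-cdf value of each category: mass strictly below + half its own
    h1 = np.cumsum(f1) - f1 / 2.0
    h2 = np.cumsum(f2) - f2 / 2.0
    p = float(np.sum(f2 * h1))
    sigma2_sq = float(np.sum(f2 * h1**2) - p**2)
    sigma1_sq = float(np.sum(f1 * h2**2) - (1.0 - p) ** 2)
    w = pool_weight
    fs = w * f1 + (1.0 - w) * f2
    hs = np.cumsum(fs) - fs / 2.0
    sigma0_sq = float(np.sum(fs * hs**2) - 0.25)
    # variances are nonnegative up to rounding; clip the dust
    return EffectEstimates(p=p, sigma0_sq=max(sigma0_sq, 0.0),
                           sigma1_sq=max(sigma1_sq, 0.0),
                           sigma2_sq=max(sigma2_sq, 0.0))


def normalized_ecdf(sample, x) -> np.ndarray:
    """Normalized empirical cdf (F+ + F-)/2 of `sample` evaluated at `x`."""
    s = np.sort(as_observations(sample, "sample"))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    below = np.searchsorted(s, x, side="left")
    at_or_below = np.searchsorted(s, x, side="right")
    return (below + at_or_below) / (2.0 * s.size)


def integral_oracle(sample1, sample2, null_variance: str = "pooled") -> EffectEstimates:
    """Effect and variances by direct summation of the defining integrals.

    Evaluates integral F1 dF2, integral F2^2 dF1, integral F1^2 dF2 and
    integral (F*)^2 dF* over the pooled support using normalized empirical
    cdfs.  Independent of the rank identities; used to cross-validate
    :func:`effect_and_variances`.
    """
    x1 = as_observations(sample1, "sample1")
    x2 = as_observations(sample2, "sample2")
    p = float(np.mean(normalized_ecdf(x1, x2)))
    sigma1_sq = float(np.mean(normalized_ecdf(x2, x1) ** 2) - (1.0 - p) ** 2)
    sigma2_sq = float(np.mean(normalized_ecdf(x1, x2) ** 2) - p**2)
    if null_variance == "pooled":
        pooled = np.concatenate([x1, x2])
        sigma0_sq = float(np.mean(normalized_ecdf(pooled, pooled) ** 2) - 0.25)
    elif null_variance == "reference":
        sigma0_sq = float(np.mean(normalized_ecdf(x1, x1) ** 2) - 0.25)
    else:
        raise ValueError("null_variance must be 'pooled' or 'reference'")
    return EffectEstimates(p=p, sigma0_sq=max(sigma0_sq, 0.0),
                           sigma1_sq=max(sigma1_sq, 0.0),
                           sigma2_sq=max(sigma2_sq, 0.0))
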