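"""Asymptotic rank test and Monte-Carlo verification of computed designs.

The test is the tie-corrected normal-approximation Wilcoxon-Mann-Whitney
test: with p_hat estimated from midranks and the null variance estimated
from the pooled midranks (which automatically accounts for ties), the
standardized statistic

    T = sqrt(N) * (p_hat - 1/2) / sqrt(sigma0_hat^2 / (t_hat (1 - t_hat))),
    sigma0_hat^2 = sum_k (R_k - (N+1)/2)^2 / (N^2 (N - 1)),

is compared two-sided against the standard normal quantile.  The N - 1
divisor makes sigma0_hat^2 the exact permutation variance of the rank sum
given the observed tie pattern — the classical finite-sample form of the
tie-corrected test; the population divisor N is reserved for fixed
synthetic distributions in the planning step.  No continuity correction is
applied.

Power is verified by resampling: each replicate draws the planned group
sizes with replacement from the two synthetic distributions (or from a
parametric family) and applies the test; the rejection fraction estimates
the achieved power.  Each replicate owns a child random generator spawned
from the global seed, so enlarging nsim extends — never reshuffles — the
replicate stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .design import DesignSpec, optimize_allocation, sample_size_exact
from .ranks import FrequencyTable, as_observations, effect_and_variances

__all__ = [
    "TestResult",
    "PowerEstimate",
    "DistributionSpec",
    "wmw_asymptotic_test",
    "simulate_power",
    "allocation_curve",
]

_CHUNK = 512  # replicates ranked per vectorized batch


@dataclass(frozen=True)
class TestResult:
    p_hat: float
    statistic: float
    reject: bool


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection rate with its binomial standard error."""

    power: float
    nsim: int
    seed: int

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power * (1.0 - self.power) / self.nsim))


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution to draw replicates from.

    ``beta`` draws Beta(shape1, shape2) variates; ``empirical`` draws with
    replacement from a stored vector, optionally weighted (the multinomial
    equivalent of a frequency-table row).
    """

    family: str
    shape1: float | None = None
    shape2: float | None = None
    values: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.family == "beta":
            if not (self.shape1 and self.shape2 and self.shape1 > 0 and self.shape2 > 0):
                raise ValueError("beta family requires shape1, shape2 > 0")
        elif self.family == "empirical":
            vals = as_observations(self.values, "values")
            object.__setattr__(self, "values", vals)
            if self.weights is not None:
                w = np.asarray(self.weights, dtype=float).ravel()
                if w.size != vals.size or np.any(w < 0) or w.sum() <= 0:
                    raise ValueError("weights must be nonnegative, same length "
                                     "as values, positive total")
                object.__setattr__(self, "weights", w / w.sum())
        else:
            raise ValueError("family must be 'beta' or 'empirical'")

    @classmethod
    def from_sample(cls, values) -> "DistributionSpec":
        return cls(family="empirical", values=np.asarray(values, dtype=float))

    @classmethod
    def from_frequency_row(cls, categories, weights) -> "DistributionSpec":
        return cls(family="empirical", values=np.asarray(categories, dtype=float),
                   weights=np.asarray(weights, dtype=float))

    @classmethod
    def beta(cls, shape1: float, shape2: float) -> "DistributionSpec":
        return cls(family="beta", shape1=shape1, shape2=shape2)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.shape1, self.shape2, size=n)
        return rng.choice(self.values, size=n, replace=True, p=self.weights)


def _batch_statistics(data: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized p_hat and standardized statistic for rows of pooled data."""
    N = data.shape[1]
    n2 = N - n1
    ranks = rankdata(data, method="average", axis=1)
    p_hat = (ranks[:, n1:].mean(axis=1) - ranks[:, :n1].mean(axis=1)) / N + 0.5
    # exact permutation variance of the pooled ranks (N - 1 divisor)
    sigma0_sq = np.sum((ranks - (N + 1) / 2.0) ** 2, axis=1) / (N**2 * (N - 1))
    t_hat = n1 / N
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.sqrt(N) * (p_hat - 0.5) / np.sqrt(sigma0_sq / (t_hat * (1 - t_hat)))
    stat[sigma0_sq == 0.0] = 0.0
    return p_hat, stat


def wmw_asymptotic_test(x1, x2, alpha: float = 0.05) -> TestResult:
    """Two-sided tie-corrected asymptotic WMW test at level alpha."""
    x1 = as_observations(x1, "x1")
    x2 = as_observations(x2, "x2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    data = np.concatenate([x1, x2])[None, :]
    p_hat, stat = _batch_statistics(data, x1.size)
    crit = norm.ppf(1.0 - alpha / 2.0)
    return TestResult(p_hat=float(p_hat[0]), statistic=float(stat[0]),
                      reject=bool(abs(stat[0]) > crit))


def _replicate_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_power(f1: DistributionSpec, f2: DistributionSpec, n1: int, n2: int,
                   alpha: float = 0.05, nsim: int = 10_000,
                   seed: int = 0) -> PowerEstimate:
    """Monte-Carlo power of the asymptotic WMW test for a given design.

    Draws n1 values from f1 and n2 from f2 per replicate, with replacement
    for empirical families, and reports the rejection fraction.  Replicate k
    uses a generator spawned as child k of `seed`, so results for the first
    k replicates do not depend on nsim.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if nsim < 1:
        raise ValueError("need nsim >= 1")
    crit = norm.ppf(1.0 - alpha / 2.0)
    rejections = 0
    N = n1 + n2
    for start in range(0, nsim, _CHUNK):
        stop = min(start + _CHUNK, nsim)
        block = np.empty((stop - start, N))
        for i in range(start, stop):
            rng = _replicate_rng(seed, i)
            block[i - start, :n1] = f1.draw(rng, n1)
            block[i - start, n1:] = f2.draw(rng, n2)
        _, stat = _batch_statistics(block, n1)
        rejections += int(np.sum(np.abs(stat) > crit))
    return PowerEstimate(power=rejections / nsim, nsim=nsim, seed=seed)


def allocation_curve(f1: DistributionSpec, f2: DistributionSpec,
                     sweep: str, grid, alpha: float = 0.05, power: float = 0.80,
                     ndraw: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Optimal-allocation behaviour along a grid of alpha or power values.

    For each grid value, `ndraw` values per group are drawn as Monte-Carlo
    stand-ins for F1 and F2, the effect estimates are computed, and the
    optimal rate t0 together with the rounded totals N(t0) and N(1/2) is
    recorded.  Returns a DataFrame with columns
    ``sweep, value, t0, N_opt, N_balanced, p, kappa``.
    """
    if sweep not in ("alpha", "power"):
        raise ValueError("sweep must be 'alpha' or 'power'")
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty sweep grid")
    if ndraw < 1_000:
        raise ValueError("need ndraw >= 1000")
    rows = []
    for i, g in enumerate(grid):
        rng = _replicate_rng(seed, i)
        x1 = f1.draw(rng, ndraw)
        x2 = f2.draw(rng, ndraw)
        eff = effect_and_variances(x1, x2)
        a, pw = (g, power) if sweep == "alpha" else (alpha, g)
        design = DesignSpec(alpha=a, power=pw)
        t0, opt = optimize_allocation(eff, design)
        n_half = sample_size_exact(eff, design, 0.5)
        bal_n1 = int(np.ceil(0.5 * n_half - 1e-9))
        rows.append({"sweep": sweep, "value": g, "t0": t0, "N_opt": opt.N,
                     "N_balanced": 2 * bal_n1, "p": eff.p, "kappa": eff.kappa})
    return pd.DataFrame(rows)
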