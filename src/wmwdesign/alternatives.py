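"""Generating the synthetic alternative sample from prior information.

A relevant alternative is specified in interpretable terms — a relative
reduction for counts, a location shift for metric data, or a move of a
fraction of subjects to an adjacent category for ordinal data — and
translated into a synthetic sample or frequency-table row whose empirical
distribution IS the alternative distribution F2.  No parametric model
(location shift family, proportional odds, ...) is assumed anywhere
downstream; the alternative is just another fixed distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranks import as_observations

__all__ = [
    "EffectSpec",
    "scale_alternative",
    "shift_alternative",
    "category_shift_alternative",
    "expand_to_integer_counts",
]


@dataclass(frozen=True)
class EffectSpec:
    """Interpretable effect specification for generating an alternative.

    Exactly the fields of the chosen `kind` may be set:

    * ``scale``: multiply every value by `q` > 0 (e.g. q = 0.5 for a 50 %
      reduction of counts), optionally flooring to integers (`discretize`).
    * ``shift``: add `delta`, or `relative_fraction` times the mean of the
      reference sample; optionally round to `round_decimals` decimals.
    * ``category_shift``: move `fraction` of the mass of each affected
      category one step in `direction` (+1 = worse, -1 = better).
    """

    kind: str
    q: float | None = None
    discretize: bool = False
    delta: float | None = None
    relative_fraction: float | None = None
    round_decimals: int | None = None
    fraction: float | None = None
    direction: int = 1
    affected_categories: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("scale", "shift", "category_shift"):
            raise ValueError(f"unknown effect kind: {self.kind!r}")
        if self.kind == "scale" and (self.q is None or self.q <= 0):
            raise ValueError("scale effect requires q > 0")
        if self.kind == "shift" and (self.delta is None) == (self.relative_fraction is None):
            raise ValueError("shift effect requires exactly one of delta, relative_fraction")
        if self.kind == "category_shift":
            if self.fraction is None or not 0.0 <= self.fraction <= 1.0:
                raise ValueError("category_shift requires fraction in [0, 1]")
            if self.direction not in (1, -1):
                raise ValueError("direction must be +1 or -1")


def scale_alternative(values, q: float, discretize: bool = False) -> np.ndarray:
    """Alternative by multiplicative scaling: x -> q*x, or floor(q*x).

    The floor is toward -inf (only visible for negative inputs; count data
    are nonnegative).  With q < 1 on nonnegative data the result is
    stochastically smaller than the input, so the induced relative effect
    p(F1, F2) is at most 1/2.
    """
    x = as_observations(values)
    if q <= 0:
        raise ValueError("scale factor q must be > 0")
    y = q * x
    return np.floor(y) if discretize else y


def shift_alternative(values, delta: float | None = None,
                      relative_fraction: float | None = None,
                      round_decimals: int | None = None) -> np.ndarray:
    """Alternative by location shift: x -> x + delta.

    `delta` may be given directly or as `relative_fraction` of the mean of
    `values` (e.g. 0.05 for a shift of 5 % of the reference mean).  When
    `round_decimals` is set, the shifted values are rounded, matching how
    such targets are stated on a measurement scale of fixed precision.
    """
    x = as_observations(values)
    if (delta is None) == (relative_fraction is None):
        raise ValueError("give exactly one of delta, relative_fraction")
    if delta is None:
        delta = relative_fraction * float(x.mean())
    if not np.isfinite(delta):
        raise ValueError("shift delta must be finite")
    y = x + delta
    return np.round(y, round_decimals) if round_decimals is not None else y


def category_shift_alternative(weights, fraction: float, direction: int = 1,
                               affected=None) -> np.ndarray:
    """Alternative for ordinal data: move a fraction of each affected
    category's mass to the adjacent category.

    All moves are computed simultaneously from the ORIGINAL weights — mass
    moved into a category is never moved again.  Total mass is conserved
    exactly.

    Parameters
    ----------
    weights : array-like
        Nonnegative per-category counts or probabilities, in ordinal order.
    fraction : float in [0, 1]
        Proportion of each affected category's mass that moves.
    direction : {+1, -1}
        +1 shifts toward higher (worse) categories, -1 toward lower.
    affected : iterable of int, optional
        Indices of the categories whose mass moves; defaults to every
        category with a valid neighbour in `direction`.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    m = w.size
    if affected is None:
        affected = range(m - 1) if direction == 1 else range(1, m)
    affected = sorted(int(j) for j in set(affected))
    out = w.copy()
    for j in affected:
        if not 0 <= j < m:
            raise ValueError(f"affected category {j} outside the scale")
        tgt = j + direction
        if not 0 <= tgt < m:
            raise ValueError(
                f"shift from category {j} falls off the end of the scale")
        moved = fraction * w[j]
        out[j] -= moved
        out[tgt] += moved
    return out


def expand_to_integer_counts(weights, max_factor: int = 10_000,
                             tol: float = 1e-9) -> tuple[np.ndarray, int]:
    """Smallest multiplier k <= max_factor turning weights into integer counts.

    Useful to realize a frequency row as an explicit synthetic sample, e.g.
    probabilities (0.85, 0.10, 0.05) become counts (17, 2, 1) with k = 20.
    Raises if no such k exists, in which case the frequency-table route
    should be used directly instead of an expansion.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    for k in range(1, max_factor + 1):
        scaled = k * w
        if np.all(np.abs(scaled - np.round(scaled)) <= tol):
            return np.round(scaled).astype(int), k
    raise ValueError(
        f"no integer expansion with factor <= {max_factor}; "
        "compute from the frequency table directly")


def apply_effect(values_or_weights, spec: EffectSpec) -> np.ndarray:
    """Dispatch an :class:`EffectSpec` to the matching generator."""
    if spec.kind == "scale":
        return scale_alternative(values_or_weights, spec.q, spec.discretize)
    if spec.kind == "shift":
        return shift_alternative(values_or_weights, delta=spec.delta,
                                 relative_fraction=spec.relative_fraction,
                                 round_decimals=spec.round_decimals)
    return category_shift_alternative(values_or_weights, spec.fraction,
                                      spec.direction, spec.affected_categories)
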