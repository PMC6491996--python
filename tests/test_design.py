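"""Sample-size formula, optimal allocation, intervals, balance diagnostics."""

import warnings

import numpy as np
import pytest

from wmwdesign import (DesignSpec, allocation_interval, balance_diagnostics,
                       effect_and_variances, effect_from_frequency_table,
                       noether_sample_size, optimize_allocation,
                       sample_size_at_t, sample_size_exact)
from wmwdesign.ranks import EffectEstimates

from conftest import random_sample_pair


def quiet_design(alpha, power):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DesignSpec(alpha=alpha, power=power)


def test_epilepsy_balanced_design(epilepsy_pair, design_08):
    eff = effect_and_variances(*epilepsy_pair)
    res = sample_size_at_t(eff, design_08, 0.5)
    assert (res.n1, res.n2, res.N) == (24, 24, 48)
    assert res.N_exact <= res.N


def test_epilepsy_optimized_design(epilepsy_pair, design_08):
    eff = effect_and_variances(*epilepsy_pair)
    t0, res = optimize_allocation(eff, design_08)
    assert round(t0, 2) == 0.49
    assert (res.n1, res.n2, res.N) == (23, 24, 47)


def test_nasal_designs(nasal_table, design_08):
    eff = effect_from_frequency_table(nasal_table)
    bal = sample_size_at_t(eff, design_08, 0.5)
    assert (bal.n1, bal.n2) == (85, 85)
    t0, opt = optimize_allocation(eff, design_08)
    assert round(t0, 2) == 0.49
    assert (opt.n1, opt.n2, opt.N) == (83, 87, 170)
    assert eff.kappa > 1


def test_kidney_designs(kidney_pair, design_08):
    eff = effect_and_variances(*kidney_pair)
    assert round(eff.p, 2) == 0.70
    bal = sample_size_at_t(eff, design_08, 0.5)
    assert (bal.n1, bal.n2, bal.N) == (30, 30, 60)
    t0, opt = optimize_allocation(eff, design_08)
    assert round(t0, 2) == 0.51
    # rounding makes the optimized total exceed the balanced one here
    assert (opt.n1, opt.n2, opt.N) == (31, 30, 61)


def test_albumin_designs(albumin_table, design_09):
    eff = effect_from_frequency_table(albumin_table)
    bal = sample_size_at_t(eff, design_09, 0.5)
    assert (bal.n1, bal.n2, bal.N) == (877, 877, 1754)
    t0, opt = optimize_allocation(eff, design_09)
    assert round(t0, 2) == 0.52
    assert (opt.n1, opt.n2, opt.N) == (909, 842, 1751)


@pytest.mark.parametrize("fixture,power,expected", [
    ("epilepsy", 0.80, (26, 26, 52)),
    ("nasal", 0.80, (134, 134, 268)),
    ("kidney", 0.80, (32, 32, 64)),
    ("albumin", 0.90, (2667, 2667, 5334)),
])
def test_noether_comparator(request, fixture, power, expected):
    """Noether's null-variance formula on each study's relative effect."""
    from wmwdesign import load_fixture
    from wmwdesign.ranks import FrequencyTable
    payload = load_fixture(fixture)
    if isinstance(payload, FrequencyTable):
        eff = effect_from_frequency_table(payload)
    else:
        eff = effect_and_variances(*payload)
    res = noether_sample_size(eff.p, DesignSpec(alpha=0.05, power=power), 0.5)
    assert (res.n1, res.n2, res.N) == expected
    assert res.method == "noether"


def test_noether_diverges_as_effect_vanishes(design_08):
    sizes = [noether_sample_size(p, design_08, 0.5).N
             for p in (0.6, 0.55, 0.52, 0.51)]
    assert sizes == sorted(sizes)
    with pytest.raises(ValueError, match="no effect"):
        noether_sample_size(0.5, design_08)


def test_group_swap_symmetry(design_08):
    rng = np.random.default_rng(11)
    for _ in range(20):
        x1, x2 = random_sample_pair(rng)
        eff = effect_and_variances(x1, x2)
        if abs(eff.p - 0.5) < 1e-9 or eff.sigma0_sq <= 0:
            continue
        swapped = effect_and_variances(x2, x1)
        for t in (0.2, 0.35, 0.5, 0.7):
            assert sample_size_exact(eff, design_08, t) == pytest.approx(
                sample_size_exact(swapped, design_08, 1.0 - t), rel=1e-10)


def test_degenerate_inputs_rejected(design_08):
    no_effect = effect_and_variances([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="no effect"):
        sample_size_at_t(no_effect, design_08, 0.5)
    tied = effect_and_variances([2, 2], [2, 2, 2])
    with pytest.raises(ValueError, match="degenerate"):
        sample_size_at_t(tied, design_08, 0.5)
    eff = effect_and_variances([1, 2], [3, 4])
    with pytest.raises(ValueError, match="t must be"):
        sample_size_exact(eff, design_08, 1.5)


def test_design_spec_validation():
    with pytest.raises(ValueError):
        DesignSpec(alpha=0.0)
    with pytest.raises(ValueError):
        DesignSpec(power=1.0)
    with pytest.warns(UserWarning, match="power <= 0.5"):
        DesignSpec(power=0.4)


def test_equal_variances_give_balanced_optimum(design_08):
    eff = EffectEstimates(p=0.65, sigma0_sq=1 / 12, sigma1_sq=0.04, sigma2_sq=0.04)
    t0, _ = optimize_allocation(eff, design_08)
    assert t0 == 0.5
    iv = allocation_interval(eff, design_08)
    assert (iv.lower, iv.upper, iv.t0) == (0.5, 0.5, 0.5)
    assert iv.kappa_branch == "sigma1=sigma2"


def test_power_half_gives_balanced_optimum(epilepsy_pair):
    """With u_{1-beta} = 0 the alternative variances drop out of N(t)."""
    eff = effect_and_variances(*epilepsy_pair)
    t0, _ = optimize_allocation(eff, quiet_design(0.05, 0.5 + 1e-12))
    assert t0 == pytest.approx(0.5, abs=1e-6)


def test_sign_equivalence_and_bracketing_on_random_pairs():
    """t0 < 1/2 iff sigma1 < sigma2, and the closed-form interval always
    brackets the numeric minimizer."""
    rng = np.random.default_rng(23)
    checked = 0
    for _ in range(60):
        x1, x2 = random_sample_pair(rng)
        eff = effect_and_variances(x1, x2)
        if (abs(eff.p - 0.5) < 1e-9 or eff.sigma0_sq <= 0
                or (eff.sigma1_sq == 0 and eff.sigma2_sq == 0)):
            continue
        design = quiet_design(float(rng.uniform(0.01, 0.1)),
                              float(rng.uniform(0.55, 0.95)))
        iv = allocation_interval(eff, design)  # raises on bracketing failure
        assert iv.lower - 1e-6 <= iv.t0 <= iv.upper + 1e-6
        if abs(eff.sigma1 - eff.sigma2) > 1e-12:
            if eff.sigma1 < eff.sigma2:
                assert iv.t0 < 0.5 + 1e-6
            else:
                assert iv.t0 > 0.5 - 1e-6
        checked += 1
    assert checked > 30


def test_interval_on_fixtures(epilepsy_pair, nasal_table, design_08):
    eff = effect_and_variances(*epilepsy_pair)
    iv = allocation_interval(eff, design_08)
    assert iv.kappa_branch == "sigma1<sigma2"
    assert iv.lower == pytest.approx(1.0 / (eff.kappa + 1.0))
    assert iv.lower <= iv.t0 <= iv.upper < 0.5
    eff = effect_from_frequency_table(nasal_table)
    iv = allocation_interval(eff, design_08)
    assert iv.upper < 0.5 and round(iv.t0, 2) == 0.49


def test_interval_handles_degenerate_sigma1(design_08):
    eff = effect_and_variances([5, 5, 5], [1, 1, 9])
    iv = allocation_interval(eff, design_08)
    assert iv.kappa_branch == "sigma1=0"
    assert 0.0 < iv.lower <= iv.t0 <= iv.upper < 0.5
    mirrored = effect_and_variances([1, 1, 9], [5, 5, 5])
    iv2 = allocation_interval(mirrored, design_08)
    assert iv2.kappa_branch == "sigma2=0"
    assert iv2.lower == pytest.approx(1.0 - iv.upper, abs=1e-9)
    with pytest.raises(ValueError, match="1 - beta > 0.5"):
        allocation_interval(eff, quiet_design(0.05, 0.4))


def test_interval_tightens_with_power(epilepsy_pair):
    """Raising the power drives the interval toward the variance-ratio
    allocation 1/(kappa+1)."""
    eff = effect_and_variances(*epilepsy_pair)
    widths, uppers, t0s = [], [], []
    i1 = 1.0 / (eff.kappa + 1.0)
    for power in (0.6, 0.75, 0.9, 0.99, 0.999):
        iv = allocation_interval(eff, DesignSpec(alpha=0.05, power=power))
        widths.append(iv.upper - iv.lower)
        uppers.append(iv.upper)
        t0s.append(iv.t0)
        assert iv.lower == pytest.approx(i1)
    assert all(a >= b for a, b in zip(widths, widths[1:]))
    assert all(a >= b for a, b in zip(uppers, uppers[1:]))
    assert all(a >= b >= i1 - 1e-9 for a, b in zip(t0s, t0s[1:]))
    # in the limit the alpha term is negligible against u_{1-beta}*sigma_i
    # and the optimum collapses onto the variance-ratio allocation itself;
    # emulate it by shrinking the null-variance term
    tiny = EffectEstimates(p=eff.p, sigma0_sq=1e-12,
                           sigma1_sq=eff.sigma1_sq, sigma2_sq=eff.sigma2_sq)
    iv = allocation_interval(tiny, DesignSpec(alpha=0.05, power=0.9))
    assert iv.t0 == pytest.approx(i1, abs=1e-4)
    assert iv.upper - iv.lower < 1e-3


def test_minimizer_unique_on_grid(epilepsy_pair, design_08):
    eff = effect_and_variances(*epilepsy_pair)
    ts = np.arange(1e-3, 1.0, 1e-3)
    ns = np.array([sample_size_exact(eff, design_08, t) for t in ts])
    interior_minima = np.flatnonzero(
        (ns[1:-1] < ns[:-2]) & (ns[1:-1] < ns[2:]))
    assert interior_minima.size == 1


def test_alpha_pushes_t0_away_from_half(epilepsy_pair, kidney_pair):
    for pair in (epilepsy_pair, kidney_pair):
        eff = effect_and_variances(*pair)
        devs = []
        for alpha in np.arange(0.01, 0.11, 0.01):
            t0, _ = optimize_allocation(eff, DesignSpec(alpha=float(alpha), power=0.8))
            devs.append(abs(t0 - 0.5))
        assert all(b >= a - 1e-9 for a, b in zip(devs, devs[1:]))


def test_mirror_construction_implies_balance(design_08):
    rng = np.random.default_rng(5)
    x1 = rng.integers(0, 8, 25).astype(float)
    x2 = 7.0 - x1  # mirror image about a = 3.5
    rep = balance_diagnostics(x1, x2)
    assert rep.mirror and rep.mirror_a == pytest.approx(3.5)
    assert rep.sigma1_sq == pytest.approx(rep.sigma2_sq, abs=1e-12)
    t0, _ = optimize_allocation(effect_and_variances(x1, x2), design_08)
    assert t0 == pytest.approx(0.5, abs=1e-6)


def test_identical_nonsymmetric_samples_balance_without_mirror():
    x = np.array([0.0, 0.0, 1.0, 5.0, 20.0])  # skewed
    rep = balance_diagnostics(x, x)
    assert rep.integral_lhs == pytest.approx(rep.integral_rhs, abs=1e-12)
    assert not rep.mirror


def test_balance_diagnostics_sign_matches_optimum(epilepsy_pair, design_08):
    rep = balance_diagnostics(*epilepsy_pair)
    assert rep.sigma_diff < 0  # sigma1 < sigma2
    assert rep.integral_lhs > rep.integral_rhs
    t0, _ = optimize_allocation(effect_and_variances(*epilepsy_pair), design_08)
    assert t0 < 0.5
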