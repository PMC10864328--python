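import numpy as np
import pytest
import scipy.integrate
from hypothesis import given, settings, strategies as st

import spinscape as sp
from spinscape.correlation import CorrelationFunction


def _cf(times, values, label="t"):
    return CorrelationFunction(label, times, values, len(times), 1.0)


# ---------------------------------------------------------------------------
# grids


def test_build_grid_three_point_decades():
    g = sp.build_grid(3, 1.0, 100.0)
    np.testing.assert_allclose(g.taus, [1.0, 10.0, 100.0], rtol=1e-12)


def test_nh_preset_matches_definition():
    g = sp.build_grid(preset="NH")
    assert g.n == 100
    assert g.tau_min == pytest.approx(1.0)
    assert g.tau_max == pytest.approx(1.0e5)
    ratios = g.taus[1:] / g.taus[:-1]
    np.testing.assert_allclose(ratios, 10.0 ** (5.0 / 99.0), rtol=1e-9)


def test_ch_preset_matches_definition():
    g = sp.build_grid(preset="CH")
    assert g.n == 500
    assert g.tau_min == pytest.approx(1.0e-3)   # 1 fs
    assert g.tau_max == pytest.approx(1.0e6)    # 1 us


def test_two_point_grid_is_endpoints():
    g = sp.build_grid(2, 3.0, 7.0)
    np.testing.assert_allclose(g.taus, [3.0, 7.0])


def test_grid_rejects_bad_bounds():
    with pytest.raises(ValueError):
        sp.build_grid(5, -1.0, 10.0)
    with pytest.raises(ValueError):
        sp.build_grid(5, 10.0, 1.0)
    with pytest.raises(ValueError):
        sp.build_grid(1, 1.0, 10.0)


# ---------------------------------------------------------------------------
# NNLS fitting


def test_mono_exponential_self_consistency():
    t = np.arange(0.0, 201.0)
    g = sp.build_grid(5, 0.1, 1000.0)  # contains tau = 10 ps exactly
    assert np.any(np.isclose(g.taus, 10.0))
    fit = sp.fit_exponentials(_cf(t, np.exp(-t / 10.0)), g)
    rms = np.sqrt(np.mean((fit.reconstruct(t) - np.exp(-t / 10.0)) ** 2))
    assert rms < 1e-6
    near = np.abs(np.log(g.taus / 10.0)) <= np.log(g.taus[1] / g.taus[0]) + 1e-9
    assert fit.weights[near].sum() >= 0.95 * fit.total_weight


def test_two_exponential_recovery_on_nh_grid(nh_grid):
    t = np.arange(0.0, 20001.0, 10.0)
    c = 0.5 * np.exp(-t / 1.0e3) + 0.5 * np.exp(-t / 1.0e5)
    fit = sp.fit_exponentials(_cf(t, c), nh_grid)
    taus = nh_grid.taus
    for center in (1.0e3, 1.0e5):
        cluster = (taus >= center / np.sqrt(10)) & (taus <= center * np.sqrt(10))
        assert fit.weights[cluster].sum() == pytest.approx(0.5, abs=0.02)


def test_constant_correlation_loads_slowest_timescale(nh_grid):
    t = np.arange(0.0, 200.0)
    fit = sp.fit_exponentials(_cf(t, np.ones_like(t)), nh_grid)
    assert fit.weights[-1] >= 0.99 * fit.total_weight


def test_fit_rejects_degenerate_input(nh_grid):
    t = np.arange(0.0, 100.0)
    with pytest.raises(ValueError, match="zero"):
        sp.fit_exponentials(_cf(t, np.zeros_like(t)), nh_grid)
    bad = np.ones_like(t)
    bad[3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        sp.fit_exponentials(_cf(t, bad), nh_grid)
    with pytest.raises(ValueError, match="lag"):
        sp.fit_exponentials(_cf(np.arange(5.0), np.ones(5)), nh_grid)


def test_fit_never_worse_than_best_single_exponential(nh_grid):
    t = np.arange(0.0, 2000.0, 2.0)
    c = 0.3 * np.exp(-t / 50.0) + 0.6 * np.exp(-t / 2000.0) + 0.1
    fit = sp.fit_exponentials(_cf(t, c), nh_grid)
    multi_rms = np.sqrt(np.mean((fit.reconstruct(t) - c) ** 2))
    best_single = np.inf
    for tau in nh_grid.taus:
        a = np.exp(-t / tau)
        alpha = max(0.0, float(a @ c) / float(a @ a))
        best_single = min(best_single, np.sqrt(np.mean((alpha * a - c) ** 2)))
    assert multi_rms <= best_single + 1e-12


# ---------------------------------------------------------------------------
# artificial slow-timescale filter


def _fit_with_slow_weight(nh_grid, w_slow):
    weights = np.zeros(nh_grid.n)
    weights[50] = 1.0 - w_slow
    weights[-1] = w_slow
    return sp.ExponentialFit("s", nh_grid, weights, residual=0.0)


def test_small_slow_weight_is_zeroed_and_flagged(nh_grid):
    out = sp.filter_artificial_slow(_fit_with_slow_weight(nh_grid, 0.005))
    assert out.weights[-1] == 0.0
    assert out.flags[-1]
    assert out.weights[50] == pytest.approx(0.995)  # no renormalization


def test_zero_slow_weight_returns_fit_unchanged(nh_grid):
    fit = _fit_with_slow_weight(nh_grid, 0.0)
    assert sp.filter_artificial_slow(fit) is fit


def test_large_slow_weight_kept_with_warning(nh_grid):
    fit = _fit_with_slow_weight(nh_grid, 0.2)
    with pytest.warns(UserWarning, match="exceeds"):
        out = sp.filter_artificial_slow(fit)
    np.testing.assert_array_equal(out.weights, fit.weights)


# ---------------------------------------------------------------------------
# spectral density and effective correlation time


def test_spectral_density_at_zero_is_twice_tau():
    grid = sp.TimescaleGrid(np.array([5000.0, 50000.0]))
    fit = sp.ExponentialFit("s", grid, np.array([1.0, 0.0]), 0.0)
    assert sp.spectral_density(fit, 0.0) == pytest.approx(10000.0)  # 10 ns in ps


def test_spectral_density_monotone_decay_single_term():
    grid = sp.TimescaleGrid(np.array([100.0, 1000.0]))
    fit = sp.ExponentialFit("s", grid, np.array([0.0, 1.0]), 0.0)
    omegas = np.geomspace(1e-6, 10.0, 50)
    J = sp.spectral_density(fit, omegas)
    assert np.all(np.diff(J) < 0)


def test_spectral_density_hand_evaluation():
    # alpha = {0.5 @ 1 ns, 0.5 @ 10 ns} at the 15N Larmor frequency of an
    # 850 MHz spectrometer (|omega_N|/2pi = 0.0862 GHz)
    grid = sp.TimescaleGrid(np.array([1000.0, 10000.0]))
    fit = sp.ExponentialFit("s", grid, np.array([0.5, 0.5]), 0.0)
    omega = 2.0 * np.pi * 0.0862e-3  # rad/ps
    expected = sum(2.0 * 0.5 * tau / (1.0 + (omega * tau) ** 2)
                   for tau in (1000.0, 10000.0))
    assert sp.spectral_density(fit, omega) == pytest.approx(expected, rel=1e-12)


def test_effective_correlation_time_values():
    grid = sp.TimescaleGrid(np.array([1000.0, 10000.0]))
    mono = sp.ExponentialFit("s", sp.TimescaleGrid(np.array([5000.0, 50000.0])),
                             np.array([1.0, 0.0]), 0.0)
    assert sp.effective_correlation_time(mono) == pytest.approx(5000.0)
    two = sp.ExponentialFit("s", grid, np.array([0.5, 0.5]), 0.0)
    assert sp.effective_correlation_time(two) == pytest.approx(5500.0)


def test_effective_correlation_time_matches_quadrature(nh_grid):
    rng = np.random.default_rng(23)
    weights = rng.random(nh_grid.n)
    weights[weights < 0.9] = 0.0
    weights /= weights.sum()
    fit = sp.ExponentialFit("s", nh_grid, weights, 0.0)
    quad, _ = scipy.integrate.quad(
        lambda t: float(fit.reconstruct(np.array([t]))[0]),
        0.0, 1000.0 * nh_grid.tau_max, limit=500)
    assert sp.effective_correlation_time(fit) == pytest.approx(quad, rel=1e-3)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 9999))
def test_tau_eff_is_half_of_j_zero(seed, nh_grid):
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.ones(nh_grid.n) * 0.1)
    fit = sp.ExponentialFit("s", nh_grid, weights, 0.0)
    assert sp.effective_correlation_time(fit) == sp.spectral_density(fit, 0.0) / 2.0
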