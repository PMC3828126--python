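"""Tuning curves, rate model, and analytic derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticode import (
    PopulationSpec,
    Stimulus,
    build_population,
    mean_rates,
    rate_derivative,
    roex_response,
    sharpness_from_q,
)

# Independently computed root of (1 + x) exp(-x) = 1/2 (bisection oracle
# frozen): the roex reaches half height at alpha*g = x*.
X_HALF = 1.6783469900166605


def _bisect_half():
    lo, hi = 0.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1.0 + mid) * np.exp(-mid) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_half_height_root_oracle():
    assert _bisect_half() == pytest.approx(X_HALF, abs=1e-12)


@pytest.mark.parametrize(
    "q, expected_alpha",
    [(12.0, 24 * X_HALF), (3.7, 7.4 * X_HALF)],  # ~40.28 and ~12.42
)
def test_sharpness_from_q(q, expected_alpha):
    assert sharpness_from_q(q) == pytest.approx(expected_alpha, rel=1e-9)


def test_sharpness_rejects_nonpositive_q():
    with pytest.raises(ValueError):
        sharpness_from_q(0.0)


@pytest.mark.parametrize("q", [3.7, 12.0])
def test_half_height_bandwidth_recovers_q(q):
    """Grid search on the constructed curve recovers Q within 0.1%."""
    bf = 1000.0
    alpha = sharpness_from_q(q)
    f = np.linspace(500.0, 1500.0, 2_000_001)
    h = roex_response(f, bf, alpha)
    above = f[h >= 0.5]
    width = above[-1] - above[0]
    assert bf / width == pytest.approx(q, rel=1e-3)


def test_roex_peak_half_and_tail():
    q = 12.0
    alpha = sharpness_from_q(q)
    assert roex_response(1000.0, 1000.0, alpha) == 1.0
    assert roex_response(1000.0 * (1 + 1 / (2 * q)), 1000.0, alpha) == pytest.approx(
        0.5, rel=1e-12
    )
    assert roex_response(5000.0, 1000.0, alpha) < 1e-30


@given(
    bf=st.floats(200.0, 5000.0),
    rel_dev=st.floats(-0.5, 0.5),
    alpha=st.floats(5.0, 80.0),
)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_roex_symmetric_and_bounded(bf, rel_dev, alpha):
    """h depends only on |f - bf|/bf and lies in (0, 1]."""
    f_up = bf * (1 + rel_dev)
    f_dn = bf * (1 - rel_dev)
    h_up = roex_response(f_up, bf, alpha)
    # mirror frequency with the same normalised deviation g
    assert h_up == pytest.approx(roex_response(f_dn, bf, alpha), rel=1e-12)
    assert 0.0 < h_up <= 1.0


def test_build_population_density_and_endpoints():
    pop = build_population(n=1700)
    assert pop.bf_grid[0] == pytest.approx(500.0)
    assert pop.bf_grid[-1] == pytest.approx(2000.0)
    assert pop.octaves == pytest.approx(2.0)
    assert pop.density_per_octave == pytest.approx(850.0)
    assert build_population(n=600).density_per_octave == pytest.approx(300.0)

    two = build_population(n=2, f_low_hz=440.0, f_high_hz=880.0)
    np.testing.assert_allclose(two.bf_grid, [440.0, 880.0])

    with pytest.raises(ValueError):
        build_population(n=1)
    with pytest.raises(ValueError):
        build_population(n=10, f_low_hz=2000.0, f_high_hz=500.0)


def test_population_spec_invariants():
    with pytest.raises(ValueError):
        PopulationSpec(bf_grid=np.array([1000.0, 900.0]), q=12.0)
    with pytest.raises(ValueError):
        PopulationSpec(bf_grid=np.array([-1.0, 1000.0]), q=12.0)
    with pytest.raises(ValueError):
        PopulationSpec(bf_grid=np.array([500.0, 1000.0]), q=12.0, r_e_ref=0.0)


def test_mean_rates_peak_tail_and_bounds():
    pop = PopulationSpec(bf_grid=np.array([500.0, 1000.0, 4000.0]), q=12.0)
    rv = mean_rates(pop, Stimulus(1000.0, 50.0))
    # unit at BF: r_s + r_e_ref = 0.1 + 15
    assert rv.rates[1] == pytest.approx(15.1)
    # unit far off-BF: spontaneous rate only
    assert rv.rates[2] == pytest.approx(0.1, abs=1e-6)
    assert np.all(rv.rates >= pop.r_s)
    assert np.all(rv.rates <= pop.r_s + pop.r_e_ref)
    # counts scale with duration
    rv2 = mean_rates(pop, Stimulus(1000.0, 50.0, duration_s=0.5))
    np.testing.assert_allclose(rv2.counts, 0.5 * rv2.rates)


def test_rate_level_model_and_validity_range():
    pop = build_population(n=10, intensity_slope=0.8)
    r60 = mean_rates(pop, Stimulus(1000.0, 60.0)).rates
    r50 = mean_rates(pop, Stimulus(1000.0, 50.0)).rates
    assert np.max(r60 - r50) == pytest.approx(
        8.0 * np.max(roex_response(1000.0, pop.bf_grid, pop.alpha)), rel=1e-12
    )
    with pytest.raises(ValueError):
        mean_rates(pop, Stimulus(1000.0, 30.0))  # evoked rate would be negative


def test_frequency_derivative_zero_at_bf_and_intensity_sign():
    pop = build_population(n=11, intensity_slope=0.8)
    stim = Stimulus(float(pop.bf_grid[5]), 50.0)
    dr = rate_derivative(pop, stim, "frequency")
    assert dr[5] == 0.0
    dl = rate_derivative(pop, stim, "intensity")
    assert np.all(dl >= 0.0)
    np.testing.assert_allclose(
        dl, 0.8 * roex_response(stim.frequency_hz, pop.bf_grid, pop.alpha)
    )
    with pytest.raises(ValueError):
        rate_derivative(pop, stim, "loudness")


@given(f=st.floats(600.0, 1900.0))
@settings(derandomize=True, max_examples=100, deadline=None)
def test_frequency_derivative_matches_finite_difference(f):
    """Analytic d(rate)/df vs central difference, 1e-6 relative on the vector scale."""
    pop = build_population(n=40)
    h = 1e-4  # Hz
    dr = rate_derivative(pop, Stimulus(f, 50.0), "frequency")
    fd = (
        mean_rates(pop, Stimulus(f + h, 50.0)).rates
        - mean_rates(pop, Stimulus(f - h, 50.0)).rates
    ) / (2 * h)
    scale = np.max(np.abs(dr)) + 1e-12
    assert np.max(np.abs(dr - fd)) / scale < 1e-6


def test_intensity_derivative_matches_finite_difference():
    pop = build_population(n=40, intensity_slope=0.8)
    h = 1e-5
    dl = rate_derivative(pop, Stimulus(1234.0, 50.0), "intensity")
    fd = (
        mean_rates(pop, Stimulus(1234.0, 50.0 + h)).rates
        - mean_rates(pop, Stimulus(1234.0, 50.0 - h)).rates
    ) / (2 * h)
    assert np.max(np.abs(dl - fd)) / (np.max(np.abs(dl)) + 1e-12) < 1e-6
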