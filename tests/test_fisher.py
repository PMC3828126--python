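"""Fisher information, d', per-unit decomposition, SNR, and the 2I2AFC map."""

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.stats import multivariate_normal

from corticode import (
    dprime,
    dprime_from_percent_correct,
    fisher_information,
    fisher_information_terms,
    per_unit_dprime,
    percent_correct_2i2afc,
    pooled_dprime_independent,
    single_unit_snr,
)


def quadrature_fisher(mu0, dmu, S0, dS, h=1e-4, order=80):
    """Numeric Fisher information of the explicit Gaussian likelihood.

    I(x) = E[(d/dx log p(y; x))^2] at x = 0 for mu(x) = mu0 + x*dmu,
    S(x) = S0 + x*dS, via Gauss-Hermite quadrature under p(y; 0) and a
    central finite difference of the log likelihood in x.  Independent
    of the closed-form route it checks.
    """
    z, w = hermgauss(order)
    L = np.linalg.cholesky(S0)
    Z = np.stack(np.meshgrid(z, z, indexing="ij"), axis=-1).reshape(-1, 2)
    Y = mu0 + np.sqrt(2.0) * Z @ L.T
    W = np.outer(w, w).ravel() / np.pi

    def logp(x):
        return multivariate_normal(mu0 + x * dmu, S0 + x * dS).logpdf(Y)

    score = (logp(h) - logp(-h)) / (2 * h)
    return float(np.sum(W * score**2))


def test_fisher_matches_gaussian_quadrature_oracle():
    mu0 = np.array([10.0, 12.0])
    dmu = np.array([0.6, -0.4])
    S0 = np.array([[4.0, 1.0], [1.0, 3.0]])
    dS = np.array([[0.3, 0.1], [0.1, -0.2]])
    closed = fisher_information(dmu, S0, dS)
    assert closed == pytest.approx(quadrature_fisher(mu0, dmu, S0, dS), rel=1e-4)
    # mean term only
    closed_mean = fisher_information(dmu, S0, None)
    assert closed_mean == pytest.approx(
        quadrature_fisher(mu0, dmu, S0, np.zeros((2, 2))), rel=1e-4
    )


def test_fisher_trivial_and_diagonal_cases():
    V = np.diag([4.0, 9.0])
    assert fisher_information(np.zeros(2), V, np.zeros((2, 2))) == 0.0
    dr = np.array([2.0, 3.0])
    assert fisher_information(dr, V) == pytest.approx(4 / 4 + 9 / 9)
    with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
        fisher_information(dr, np.zeros((2, 2)))


def test_dprime_linearity_and_validation():
    assert dprime(0.0, 5.0) == 0.0
    assert dprime(2.0, 4.0) == pytest.approx(2 * dprime(1.0, 4.0))
    with pytest.raises(ValueError):
        dprime(1.0, -1.0)


def test_per_unit_decomposition_conserves_total():
    rng = np.random.default_rng(11)
    n = 25
    A = rng.normal(size=(n, n))
    V = A @ A.T + n * np.eye(n)
    dr = rng.normal(size=n)
    dS = rng.normal(size=(n, n))
    dS = dS + dS.T
    terms = fisher_information_terms(dr, V, dS)
    assert terms.sum() == pytest.approx(fisher_information(dr, V, dS), rel=1e-12)
    dpu = per_unit_dprime(dr, V, dS, delta_x=0.7)
    total = dprime(0.7, float(np.clip(terms, 0, None).sum()))
    assert np.sqrt(np.sum(dpu**2)) == pytest.approx(total, rel=1e-9)


def test_per_unit_negative_terms_warn_and_clip():
    # A crafted instance where one row-wise term is materially negative.
    V = np.array([[1.0, 0.9], [0.9, 1.0]])
    dS = np.array([[0.0, 1.0], [1.0, 0.0]])
    dr = np.array([1.0, -1.0])
    terms = fisher_information_terms(dr, V, dS)
    if np.any(terms < 0):
        with pytest.warns(UserWarning, match="clipped"):
            dpu = per_unit_dprime(dr, V, dS, 1.0)
        assert np.all(dpu >= 0)


def test_single_unit_snr():
    ref = np.array([16.0, 9.0])
    alt = np.array([20.0, 9.0])
    np.testing.assert_allclose(single_unit_snr(ref, alt), [1.0, 0.0])
    np.testing.assert_allclose(single_unit_snr(ref, ref), 0.0)
    with pytest.raises(ValueError):
        single_unit_snr(np.array([0.0]), np.array([1.0]))


@pytest.mark.parametrize(
    "d, expected, tol",
    [(0.0, 50.0, 1e-9), (0.12, 53.0, 0.5), (1.0, 76.0, 0.5)],
)
def test_percent_correct_2i2afc(d, expected, tol):
    assert percent_correct_2i2afc(d) == pytest.approx(expected, abs=tol)


def test_percent_correct_round_trip():
    for d in (0.05, 0.5, 1.3, 2.7):
        assert dprime_from_percent_correct(percent_correct_2i2afc(d)) == pytest.approx(
            d, rel=1e-12
        )


def test_pooled_dprime_independent():
    assert pooled_dprime_independent([0.5, 0.5, 0.5, 0.5]) == pytest.approx(1.0)
    assert pooled_dprime_independent([0.37]) == pytest.approx(0.37)
    assert pooled_dprime_independent(np.full(70, 0.12)) == pytest.approx(
        np.sqrt(70) * 0.12
    )


def test_opposed_sign_beats_same_sign_under_positive_correlation():
    """Two-unit geometry: with shared positive noise, an opposed-sign rate
    change (frequency-like) is easier to see than a same-sign one
    (intensity-like): Δr^T V^-1 Δr differs by 4*c*d^2/det(V)."""
    v1, v2, c, d = 10.0, 14.0, 5.0, 0.8
    V = np.array([[v1, c], [c, v2]])
    opposed = fisher_information(np.array([-d, d]), V)
    same = fisher_information(np.array([d, d]), V)
    det = v1 * v2 - c**2
    assert opposed - same == pytest.approx(4 * c * d**2 / det, rel=1e-12)
    assert opposed > same
    # without correlation the geometry is symmetric
    V0 = np.diag([v1, v2])
    assert fisher_information(np.array([-d, d]), V0) == pytest.approx(
        fisher_information(np.array([d, d]), V0), rel=1e-12
    )
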