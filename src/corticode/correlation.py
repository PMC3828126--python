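"""Spike-count correlation and covariance structure of the population.

Noise correlations (covariation of two units' spike counts across repeated
presentations of the same stimulus) are tied to receptive-field overlap:
the correlation between units i and j is proportional to the cosine
similarity of their tuning-curve vectors sampled on the BF grid, scaled so
the most-overlapping pair approaches the maximal coefficient ``rho``:

    C = I + rho * (G - I),   G_ij = <h_i, h_j> / (||h_i|| ||h_j||)

where h_i is unit i's roex tuning curve evaluated at every BF on the grid.
C is therefore stimulus-independent, symmetric, unit-diagonal and positive
semidefinite by construction (a convex combination of the identity and a
normalised Gram matrix), and C_ij decays towards zero as the BF separation
grows.

Spike-count variance is Poisson-like (variance equal to the mean count),
so the covariance matrix for a stimulus with expected counts c is

    V_ij = C_ij * sqrt(c_i * c_j)

i.e. the correlation coefficient times the geometric mean of the counts,
with diag(V) = c exactly.  V inherits the stimulus dependence through c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .population import PopulationSpec, roex_response

__all__ = [
    "NoiseModel",
    "overlap_matrix",
    "correlation_matrix",
    "covariance_matrix",
    "covariance_derivative",
    "ensure_psd",
]

# Eigenvalue tolerances for PSD validation: violations above _PSD_TOL are
# numerical noise and accepted; between the two, projected; below
# _PSD_REJECT, rejected as structurally non-PSD.
_PSD_TOL = 1e-10
_PSD_REJECT = -1e-6


@dataclass(frozen=True)
class NoiseModel:
    """Correlation matrix C, covariance matrix V (counts^2), and rho."""

    C: np.ndarray
    V: np.ndarray
    rho: float


def overlap_matrix(pop: PopulationSpec) -> np.ndarray:
    """Receptive-field overlap G: cosine similarity of tuning vectors.

    Row i of H is unit i's tuning curve evaluated at all BFs; G is the
    normalised Gram matrix H H^T with unit diagonal.
    """
    bf = pop.bf_grid
    # H[i, j] = h_i(phi_j)
    H = roex_response(bf[np.newaxis, :], bf[:, np.newaxis], pop.alpha[:, np.newaxis])
    G = H @ H.T
    norms = np.sqrt(np.diag(G))
    G /= np.outer(norms, norms)
    np.fill_diagonal(G, 1.0)
    return G


def correlation_matrix(pop: PopulationSpec, rho: float) -> np.ndarray:
    """Spike-count correlation matrix C = I + rho * (G - I).

    rho = 0 gives the identity (statistically independent units); for
    rho > 0 the off-diagonal entries approach rho for the most
    overlapping pair and decay with BF separation.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0.0:
        return np.eye(pop.n)
    G = overlap_matrix(pop)
    C = rho * G
    np.fill_diagonal(C, 1.0)
    return C


def covariance_matrix(C: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Spike-count covariance V_ij = C_ij * sqrt(c_i c_j); diag(V) = counts."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("expected counts must be non-negative")
    s = np.sqrt(counts)
    V = C * np.outer(s, s)
    # sqrt(c)^2 is off by an ulp; the diagonal is the counts by definition
    np.fill_diagonal(V, counts)
    return V


def covariance_derivative(
    C: np.ndarray, counts: np.ndarray, dcounts_dx: np.ndarray
) -> np.ndarray:
    """Derivative of the covariance matrix along a stimulus dimension.

    dV_ij/dx = C_ij * (c_i' c_j + c_i c_j') / (2 sqrt(c_i c_j)); the
    diagonal reduces to c_i' since V_ii = c_i.
    """
    counts = np.asarray(counts, dtype=float)
    dcounts_dx = np.asarray(dcounts_dx, dtype=float)
    if np.any(counts <= 0):
        raise ValueError(
            "covariance derivative needs strictly positive counts; "
            "a population with r_s > 0 guarantees this"
        )
    s = np.sqrt(counts)
    a = dcounts_dx / (2.0 * s)
    return C * (np.outer(a, s) + np.outer(s, a))


def ensure_psd(C: np.ndarray) -> np.ndarray:
    """Validate that a symmetric correlation matrix is positive semidefinite.

    Violations at numerical-noise scale (min eigenvalue in
    [-1e-6, -1e-10)) are repaired by projecting onto the nearest
    correlation matrix (eigenvalue clipping plus diagonal renormalisation)
    with a warning; larger violations raise.
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    # Fast path: a Cholesky of C + tol*I certifies min eigenvalue >= -tol
    # without the O(n^3) eigendecomposition (which only runs on failure).
    try:
        np.linalg.cholesky(C + _PSD_TOL * np.eye(C.shape[0]))
        return C
    except np.linalg.LinAlgError:
        pass
    eigvals = np.linalg.eigvalsh(C)
    lam_min = float(eigvals[0])
    if lam_min >= -_PSD_TOL:
        return C
    if lam_min < _PSD_REJECT:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {lam_min:.3e})"
        )
    warnings.warn(
        f"correlation matrix min eigenvalue {lam_min:.3e}; projecting onto "
        "the nearest correlation matrix",
        stacklevel=2,
    )
    lam, U = np.linalg.eigh(C)
    lam = np.clip(lam, 0.0, None)
    C_psd = (U * lam) @ U.T
    d = np.sqrt(np.diag(C_psd))
    C_psd /= np.outer(d, d)
    np.fill_diagonal(C_psd, 1.0)
    return C_psd
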