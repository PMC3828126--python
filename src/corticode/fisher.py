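"""Fisher information, d', per-unit d', single-unit SNR, and 2I2AFC mapping.

For a multivariate Gaussian response with stimulus-dependent mean counts
c(x) and covariance V(x), the Fisher information about the stimulus
dimension x (frequency in Hz or intensity in dB) is

    I(x) = c'(x)^T V^-1 c'(x) + 1/2 Tr[(V^-1 V'(x))^2]

the first ("mean") term measuring how fast the mean response moves
relative to the noise, the second ("covariance") term the information
carried by the stimulus dependence of the noise itself.  Via the
Cramer-Rao bound, the best achievable sensitivity for discriminating two
stimuli Δx apart is d' = Δx * sqrt(I(x)), and percent correct in a
two-interval two-alternative forced choice (2I2AFC) task is
P = Φ(d'/√2), with chance at 50%.

The per-unit decomposition splits both terms row-wise:

    I_i = [c']_i [V^-1 c']_i + 1/2 Diag_i[(V^-1 V')^2]

which sums to I exactly, so the root-sum-square of the per-unit
d'_i = Δx sqrt(I_i) reconstructs the population d'.  Individual I_i can
in principle be negative (the decomposition is not a variance); such
values are clipped at zero with a warning rather than silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import ndtr, ndtri

__all__ = [
    "DiscriminationResult",
    "fisher_information",
    "fisher_information_terms",
    "clip_negative_terms",
    "dprime",
    "per_unit_dprime",
    "single_unit_snr",
    "percent_correct_2i2afc",
    "dprime_from_percent_correct",
    "pooled_dprime_independent",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e10


def _cho(V: np.ndarray):
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        lam_min = float(np.linalg.eigvalsh(V)[0])
        raise np.linalg.LinAlgError(
            f"covariance matrix is singular or indefinite "
            f"(min eigenvalue {lam_min:.3e})"
        ) from exc
    # Cheap condition estimate from the Cholesky diagonal (lower bound on
    # the true 2-norm condition number; adequate for a warning).
    d = np.diag(cho[0])
    cond_est = float((d.max() / d.min()) ** 2)
    if cond_est > _COND_WARN:
        logger.warning("covariance condition number estimate %.2e", cond_est)
    else:
        logger.debug("covariance condition number estimate %.2e", cond_est)
    return cho


def fisher_information_terms(
    dr_dx: np.ndarray,
    V: np.ndarray,
    dV_dx: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-unit Fisher-information terms I_i; ``sum`` gives the total.

    Parameters are the derivative of the mean-count vector, the count
    covariance, and optionally the covariance derivative (omit for a
    stimulus-independent noise model).
    """
    dr_dx = np.asarray(dr_dx, dtype=float)
    cho = _cho(np.asarray(V, dtype=float))
    terms = dr_dx * cho_solve(cho, dr_dx)
    if dV_dx is not None:
        M = cho_solve(cho, np.asarray(dV_dx, dtype=float))
        terms = terms + 0.5 * np.einsum("ij,ji->i", M, M)
    return terms


def fisher_information(
    dr_dx: np.ndarray,
    V: np.ndarray,
    dV_dx: Optional[np.ndarray] = None,
) -> float:
    """Total Gaussian Fisher information, (units of x)^-2."""
    return float(fisher_information_terms(dr_dx, V, dV_dx).sum())


def dprime(delta_x: float, info: float) -> float:
    """Sensitivity d' = Δx * sqrt(I); exactly linear in Δx."""
    if info < 0:
        raise ValueError(f"Fisher information must be non-negative, got {info}")
    return float(abs(delta_x) * np.sqrt(info))


def per_unit_dprime(
    dr_dx: np.ndarray,
    V: np.ndarray,
    dV_dx: Optional[np.ndarray],
    delta_x: float,
) -> np.ndarray:
    """Per-unit d'_i = Δx sqrt(I_i); root-sum-square equals the total d'.

    Negative decomposition terms (possible in principle, never observed
    for this model's parameter ranges) are clipped at zero with a
    warning.
    """
    terms = clip_negative_terms(fisher_information_terms(dr_dx, V, dV_dx))
    return abs(delta_x) * np.sqrt(terms)


def clip_negative_terms(terms: np.ndarray) -> np.ndarray:
    """Clip negative per-unit Fisher terms at zero.

    The row-wise split of the trace term, diag((V^-1 V')^2), is not
    sign-definite, so uninformative units can carry tiny negative terms
    (cancellation-scale, < 1e-4 of the total information for this model's
    parameter ranges); those are clipped silently.  Materially negative
    values are reported via a warning before clipping.
    """
    noise_floor = -1e-4 * max(float(terms.sum()), np.finfo(float).tiny)
    if np.any(terms < noise_floor):
        n_neg = int(np.sum(terms < noise_floor))
        warnings.warn(
            f"{n_neg} negative per-unit Fisher terms (most negative "
            f"{terms.min():.3e}) clipped to zero",
            stacklevel=2,
        )
    return np.clip(terms, 0.0, None)


def single_unit_snr(counts_ref: np.ndarray, counts_alt: np.ndarray) -> np.ndarray:
    """Signed single-unit SNR: count change over sqrt(reference count)."""
    counts_ref = np.asarray(counts_ref, dtype=float)
    counts_alt = np.asarray(counts_alt, dtype=float)
    if np.any(counts_ref <= 0):
        raise ValueError("reference counts must be strictly positive")
    return (counts_alt - counts_ref) / np.sqrt(counts_ref)


def percent_correct_2i2afc(d: float) -> float:
    """Percent correct in 2I2AFC: 100 * Φ(d'/√2); 50% at d' = 0."""
    if d < 0:
        raise ValueError(f"d' must be non-negative, got {d}")
    return float(100.0 * ndtr(d / np.sqrt(2.0)))


def dprime_from_percent_correct(pct: float) -> float:
    """Inverse of the 2I2AFC map: d' = √2 Φ^-1(P/100)."""
    if not 0.0 < pct < 100.0:
        raise ValueError(f"percent correct must be in (0, 100), got {pct}")
    return float(np.sqrt(2.0) * ndtri(pct / 100.0))


def pooled_dprime_independent(snr: np.ndarray) -> float:
    """d' = sqrt(Σ SNR_i^2): independent units, constant covariance."""
    snr = np.asarray(snr, dtype=float)
    return float(np.sqrt(np.sum(snr**2)))


@dataclass(frozen=True)
class DiscriminationResult:
    """Fisher-information analysis of one discrimination task.

    Produced by :meth:`corticode.model.PopulationRateModel.fit`.  Holds
    the total and per-unit sensitivities together with the population
    profile used to compute them.
    """

    task: str  # "frequency" or "intensity"
    delta_x: float  # stimulus difference, Hz or dB
    fisher_info: float  # (units of x)^-2
    dprime: float
    dprime_per_unit: np.ndarray
    snr_per_unit: np.ndarray
    bf_grid: np.ndarray
    rates_ref: np.ndarray
    rates_alt: np.ndarray
    rho: float
    n: int

    @property
    def pct_correct_2i2afc(self) -> float:
        return percent_correct_2i2afc(self.dprime)

    @property
    def max_snr(self) -> float:
        return float(np.max(np.abs(self.snr_per_unit)))

    @property
    def max_rate_change(self) -> float:
        """Largest across-units change in mean spike rate, spikes/s."""
        return float(np.max(np.abs(self.rates_alt - self.rates_ref)))

    def to_frame(self) -> pd.DataFrame:
        """Per-unit table: BF, rates for both stimuli, SNR, d'/unit."""
        return pd.DataFrame(
            {
                "bf_hz": self.bf_grid,
                "rate_ref": self.rates_ref,
                "rate_alt": self.rates_alt,
                "snr": self.snr_per_unit,
                "dprime_per_unit": self.dprime_per_unit,
            }
        )

    def summary(self) -> str:
        unit = "Hz" if self.task == "frequency" else "dB"
        lines = [
            f"Discrimination analysis: {self.task} task",
            "=" * 44,
            f"units (n)                 {self.n:12d}",
            f"max pairwise correlation  {self.rho:12.3f}",
            f"stimulus difference       {self.delta_x:12.4g} {unit}",
            f"Fisher information        {self.fisher_info:12.6g} {unit}^-2",
            f"d'                        {self.dprime:12.4f}",
            f"2I2AFC percent correct    {self.pct_correct_2i2afc:12.1f} %",
            f"max single-unit |SNR|     {self.max_snr:12.4f}",
            f"max |rate change|         {self.max_rate_change:12.4f} spikes/s",
        ]
        return "\n".join(lines)
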