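"""Model/Results interface tying the population, noise and Fisher machinery together.

:class:`PopulationRateModel` is built from a :class:`~corticode.population.PopulationSpec`
plus the noise configuration (maximal spike-count correlation ``rho`` and
stimulus duration).  Its :meth:`~PopulationRateModel.fit` evaluates the
Fisher-information analysis for one discrimination task and returns a
:class:`~corticode.fisher.DiscriminationResult` with the estimates, per-unit
profiles and a ``summary()`` table; the inverse problems (population size for
a target d', discriminable stimulus step, intensity-slope calibration) are
exposed as ``fit_*`` solvers, and trial-level simulation hangs off
:meth:`~PopulationRateModel.simulate_2i2afc`.
"""

from __future__ import annotations

from typing import Mapping, Optional, Union

import numpy as np

from . import io as _io
from .correlation import (
    NoiseModel,
    correlation_matrix,
    covariance_derivative,
    covariance_matrix,
    ensure_psd,
)
from .fisher import (
    DiscriminationResult,
    clip_negative_terms,
    fisher_information_terms,
    single_unit_snr,
)
from .population import (
    PopulationSpec,
    RateVector,
    Stimulus,
    build_population,
    mean_rates,
    rate_derivative,
)

__all__ = ["PopulationRateModel", "DEFAULT_REFERENCE"]

#: Reference stimulus of the standard analyses: 1 kHz, 50 dB SPL, 1 s.
DEFAULT_REFERENCE = Stimulus(frequency_hz=1000.0, intensity_db=50.0, duration_s=1.0)


class PopulationRateModel:
    """Virtual cortical population with overlap-based spike-count correlations.

    Parameters
    ----------
    population : PopulationSpec
        The neuron array (BF grid, sharpness, rate parameters).
    rho : float
        Maximal pairwise spike-count correlation in [0, 1).
    duration_s : float
        Stimulus duration; expected counts are rates times duration.
    """

    def __init__(
        self,
        population: PopulationSpec,
        rho: float = 0.25,
        duration_s: float = 1.0,
    ) -> None:
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {rho}")
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        self.population = population
        self.rho = float(rho)
        self.duration_s = float(duration_s)
        self._C: Optional[np.ndarray] = None

    # ------------------------------------------------------------------ build
    @classmethod
    def from_config(cls, source: Union[str, Mapping]) -> "PopulationRateModel":
        """Build from a flat key-value config file or mapping.

        Recognised keys (all optional, with the standard defaults):
        ``n, f_low_hz, f_high_hz, q, rho, r_s, r_e_ref, k, duration_s``.
        """
        cfg = dict(_io.DEFAULT_CONFIG)
        cfg.update(_io.read_config(source) if isinstance(source, str) else source)
        pop = build_population(
            n=int(cfg["n"]),
            f_low_hz=float(cfg["f_low_hz"]),
            f_high_hz=float(cfg["f_high_hz"]),
            q=float(cfg["q"]),
            r_s=float(cfg["r_s"]),
            r_e_ref=float(cfg["r_e_ref"]),
            intensity_slope=float(cfg["k"]),
        )
        return cls(pop, rho=float(cfg["rho"]), duration_s=float(cfg["duration_s"]))

    def with_population(self, population: PopulationSpec) -> "PopulationRateModel":
        """Same noise configuration, different neuron array."""
        return PopulationRateModel(population, rho=self.rho, duration_s=self.duration_s)

    def with_rho(self, rho: float) -> "PopulationRateModel":
        return PopulationRateModel(self.population, rho=rho, duration_s=self.duration_s)

    # -------------------------------------------------------------- responses
    @property
    def n(self) -> int:
        return self.population.n

    @property
    def correlation(self) -> np.ndarray:
        """Stimulus-independent spike-count correlation matrix (validated PSD)."""
        if self._C is None:
            self._C = ensure_psd(correlation_matrix(self.population, self.rho))
        return self._C

    def _stim(self, stim: Stimulus) -> Stimulus:
        if stim.duration_s != self.duration_s:
            stim = Stimulus(stim.frequency_hz, stim.intensity_db, self.duration_s)
        return stim

    def rate_vector(self, stim: Stimulus) -> RateVector:
        return mean_rates(self.population, self._stim(stim))

    def count_derivative(self, stim: Stimulus, wrt: str) -> np.ndarray:
        """Derivative of expected counts along ``wrt`` (counts/Hz or counts/dB)."""
        return rate_derivative(self.population, self._stim(stim), wrt) * self.duration_s

    def noise_model(self, stim: Stimulus) -> NoiseModel:
        """Correlation and count-covariance matrices at one stimulus."""
        counts = self.rate_vector(stim).counts
        return NoiseModel(
            C=self.correlation,
            V=covariance_matrix(self.correlation, counts),
            rho=self.rho,
        )

    # ---------------------------------------------------------------- fitting
    def fit(
        self,
        task: str = "frequency",
        delta_x: float = 1.68,
        reference: Stimulus = DEFAULT_REFERENCE,
        include_covariance_term: bool = True,
    ) -> DiscriminationResult:
        """Fisher-information analysis of one two-stimulus discrimination task.

        The information is evaluated at the reference stimulus (the form
        d' = Δx sqrt(I(x)) is local); ``include_covariance_term=False``
        drops the stimulus dependence of the covariance (mean-term-only
        diagnostic).
        """
        if task not in ("frequency", "intensity"):
            raise ValueError(f"task must be 'frequency' or 'intensity', got {task!r}")
        reference = self._stim(reference)
        if task == "frequency":
            alt = Stimulus(
                reference.frequency_hz + delta_x,
                reference.intensity_db,
                self.duration_s,
            )
        else:
            alt = Stimulus(
                reference.frequency_hz,
                reference.intensity_db + delta_x,
                self.duration_s,
            )
        rv_ref = self.rate_vector(reference)
        rv_alt = self.rate_vector(alt)
        counts = rv_ref.counts
        C = self.correlation
        V = covariance_matrix(C, counts)
        dc = self.count_derivative(reference, wrt=task)
        dV = covariance_derivative(C, counts, dc) if include_covariance_term else None
        terms = clip_negative_terms(fisher_information_terms(dc, V, dV))
        info = float(terms.sum())
        return DiscriminationResult(
            task=task,
            delta_x=float(delta_x),
            fisher_info=info,
            dprime=float(abs(delta_x) * np.sqrt(info)),
            dprime_per_unit=abs(delta_x) * np.sqrt(terms),
            snr_per_unit=single_unit_snr(counts, rv_alt.counts),
            bf_grid=self.population.bf_grid,
            rates_ref=rv_ref.rates,
            rates_alt=rv_alt.rates,
            rho=self.rho,
            n=self.n,
        )

    def fit_population_size(self, *args, **kwargs):
        """Smallest population size reaching a target d'; see
        :func:`corticode.thresholds.units_for_target`."""
        from .thresholds import units_for_target

        return units_for_target(self, *args, **kwargs)

    def fit_threshold(self, *args, **kwargs):
        """Stimulus step giving a target d'; see
        :func:`corticode.thresholds.delta_for_target`."""
        from .thresholds import delta_for_target

        return delta_for_target(self, *args, **kwargs)

    def fit_intensity_slope(self, *args, **kwargs):
        """Calibrate the dB-linear evoked-rate slope; see
        :func:`corticode.thresholds.calibrate_intensity_slope`."""
        from .thresholds import calibrate_intensity_slope

        return calibrate_intensity_slope(self, *args, **kwargs)

    # ------------------------------------------------------------- simulation
    def simulate_counts(self, stim: Stimulus, n_trials: int, seed, integer: bool = True):
        """Integer spike-count trials for one stimulus; see
        :func:`corticode.simulate.draw_spike_counts`."""
        from .simulate import draw_spike_counts

        stim = self._stim(stim)
        nm = self.noise_model(stim)
        return draw_spike_counts(
            self.rate_vector(stim).counts,
            nm.V,
            n_trials,
            seed,
            stimulus=stim,
            integer=integer,
        )

    def simulate_2i2afc(self, *args, **kwargs):
        """Paired-interval trials; see :func:`corticode.simulate.simulate_2i2afc`."""
        from .simulate import simulate_2i2afc

        return simulate_2i2afc(self, *args, **kwargs)
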