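"""Inverse problems: population size, discriminable step, and slope calibration.

Three solvers invert the d' = Δx sqrt(I(x)) relationship:

* :func:`units_for_target` — smallest population size n (BFs re-spread
  over the same fixed BF range, so unit density changes with n) whose
  Fisher-information d' reaches a target.  d' is not guaranteed monotone
  in n for correlated populations, so monotonicity is verified on the
  evaluated ladder and reported rather than assumed.
* :func:`delta_for_target` — the stimulus difference Δx at which the
  population reaches a target d'; closed form by linearity of d' in Δx.
* :func:`calibrate_intensity_slope` — the dB-linear evoked-rate slope k
  (spikes/s/dB) for which the intensity task reaches a target d' at a
  given intensity step; 1-D root finding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .fisher import DiscriminationResult
from .population import PopulationSpec, Stimulus, build_population

__all__ = [
    "PopulationSizeResult",
    "SlopeCalibration",
    "TaskComparison",
    "units_for_target",
    "delta_for_target",
    "calibrate_intensity_slope",
    "task_comparison",
    "dprime_ratio",
]


@dataclass(frozen=True)
class PopulationSizeResult:
    """Outcome of the population-size search."""

    n: int
    dprime_at_n: float
    target_dprime: float
    density_per_octave: float
    ladder: List[Tuple[int, float]] = field(repr=False)
    monotone: bool = True

    def summary(self) -> str:
        lines = [
            "Population-size search",
            "=" * 40,
            f"target d'             {self.target_dprime:10.3f}",
            f"units required (n)    {self.n:10d}",
            f"d' at n               {self.dprime_at_n:10.4f}",
            f"density (units/oct)   {self.density_per_octave:10.1f}",
            f"d' monotone in n      {str(self.monotone):>10}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class SlopeCalibration:
    """Calibrated rate-level slope and its implied rate changes."""

    k: float  # spikes/s per dB
    delta_l_db: float
    target_dprime: float
    max_rate_change: float  # spikes/s at the threshold step
    rate_change_per_20db: float  # spikes/s per 20 dB at BF
    result: DiscriminationResult = field(repr=False)

    def summary(self) -> str:
        lines = [
            "Intensity-slope calibration",
            "=" * 40,
            f"intensity step         {self.delta_l_db:9.3f} dB",
            f"target d'              {self.target_dprime:9.3f}",
            f"slope k                {self.k:9.4f} spikes/s/dB",
            f"max rate change        {self.max_rate_change:9.4f} spikes/s",
            f"rate change per 20 dB  {self.rate_change_per_20db:9.2f} spikes/s",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class TaskComparison:
    """Threshold-level comparison of two discrimination tasks."""

    max_rate_change_ratio: float  # second task / first task
    dprime_ratio: float  # first / second


def _rebuilt(model, n: int):
    """Same model configuration with n BFs re-spread over the same range."""
    pop = model.population
    new_pop = build_population(
        n=n,
        f_low_hz=float(pop.bf_grid[0]),
        f_high_hz=float(pop.bf_grid[-1]),
        q=pop.q,
        r_s=pop.r_s,
        r_e_ref=pop.r_e_ref,
        intensity_slope=pop.intensity_slope,
    )
    return model.with_population(new_pop)


def units_for_target(
    model,
    task: str = "frequency",
    delta_x: float = 1.68,
    target_dprime: float = 1.0,
    reference: Optional[Stimulus] = None,
    n_min: int = 16,
    n_max: int = 32768,
    rel_tol: float = 0.01,
) -> PopulationSizeResult:
    """Smallest n on an integer grid with d'(n) >= ``target_dprime``.

    Doubles n from ``n_min`` until the target is bracketed, then bisects to
    relative width ``rel_tol``.  BFs are re-spread evenly over the model's
    fixed BF range at every n (density framing).  Raises if the target is
    not reached by ``n_max``.
    """
    if target_dprime < 0:
        raise ValueError("target d' must be non-negative")
    ref = reference if reference is not None else _default_reference(model)
    ladder: List[Tuple[int, float]] = []

    def dp(n: int) -> float:
        d = _rebuilt(model, n).fit(task=task, delta_x=delta_x, reference=ref).dprime
        ladder.append((n, d))
        return d

    if target_dprime == 0.0:
        return PopulationSizeResult(
            n=n_min,
            dprime_at_n=dp(n_min),
            target_dprime=0.0,
            density_per_octave=n_min / model.population.octaves,
            ladder=ladder,
        )

    lo, hi = n_min, n_min
    d_hi = dp(n_min)
    while d_hi < target_dprime:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(
                f"target d' {target_dprime} not reached by n = {n_max} "
                f"(d' = {d_hi:.4f} at n = {lo})"
            )
        d_hi = dp(hi)
    while hi - lo > max(1, int(rel_tol * hi)):
        mid = (lo + hi) // 2
        if dp(mid) >= target_dprime:
            hi, d_hi = mid, ladder[-1][1]
        else:
            lo = mid
    ladder_sorted = sorted(ladder)
    d_seq = [d for _, d in ladder_sorted]
    monotone = all(b >= a for a, b in zip(d_seq, d_seq[1:]))
    if not monotone:
        warnings.warn(
            "d' was not monotone in n over the evaluated ladder; the returned "
            "n is the smallest bracketed crossing",
            stacklevel=2,
        )
    return PopulationSizeResult(
        n=hi,
        dprime_at_n=d_hi,
        target_dprime=target_dprime,
        density_per_octave=hi / model.population.octaves,
        ladder=ladder_sorted,
        monotone=monotone,
    )


def delta_for_target(
    model,
    task: str = "frequency",
    target_dprime: float = 1.0,
    reference: Optional[Stimulus] = None,
) -> float:
    """Stimulus step Δx with d' = target: Δx = target / sqrt(I(x)).

    Exact by the linearity of d' in Δx; no search involved.
    """
    if target_dprime < 0:
        raise ValueError("target d' must be non-negative")
    ref = reference if reference is not None else _default_reference(model)
    info = model.fit(task=task, delta_x=1.0, reference=ref).fisher_info
    if info <= 0:
        raise ValueError(f"Fisher information is {info}; no finite threshold exists")
    return float(target_dprime / np.sqrt(info))


def calibrate_intensity_slope(
    model,
    delta_l_db: float = 1.22,
    target_dprime: float = 1.0,
    reference: Optional[Stimulus] = None,
    k_max: float = 1e3,
) -> SlopeCalibration:
    """Rate-level slope k with intensity-task d'(Δl) = ``target_dprime``.

    At the reference intensity the covariance does not depend on k while
    both Fisher terms scale as k^2, so d' is exactly linear in k; the
    root is still found by bracketed 1-D root finding on d'(k) - target,
    which stays correct if the model is extended.
    """
    if delta_l_db <= 0:
        raise ValueError("intensity step must be positive")
    if target_dprime < 0:
        raise ValueError("target d' must be non-negative")
    ref = reference if reference is not None else _default_reference(model)
    pop = model.population

    def with_k(k: float):
        new_pop = PopulationSpec(
            bf_grid=pop.bf_grid,
            q=pop.q,
            alpha=pop.alpha,
            r_s=pop.r_s,
            r_e_ref=pop.r_e_ref,
            intensity_slope=k,
        )
        return model.with_population(new_pop)

    def objective(k: float) -> float:
        return (
            with_k(k).fit(task="intensity", delta_x=delta_l_db, reference=ref).dprime
            - target_dprime
        )

    if target_dprime == 0.0:
        k = 0.0
    else:
        k_hi = 1.0
        while objective(k_hi) < 0:
            k_hi *= 4.0
            if k_hi > k_max:
                raise ValueError(f"no slope below {k_max} spikes/s/dB reaches the target")
        k = float(brentq(objective, 0.0, k_hi, xtol=1e-10, rtol=1e-12))

    result = with_k(k).fit(task="intensity", delta_x=delta_l_db, reference=ref)
    return SlopeCalibration(
        k=k,
        delta_l_db=delta_l_db,
        target_dprime=target_dprime,
        max_rate_change=result.max_rate_change,
        rate_change_per_20db=20.0 * k,
        result=result,
    )


def task_comparison(
    first: DiscriminationResult, second: DiscriminationResult
) -> TaskComparison:
    """Compare two tasks at their thresholds.

    ``max_rate_change_ratio`` is the second task's maximal across-units
    rate change over the first's (intensity/frequency in the standard
    analysis); ``dprime_ratio`` is first/second (used to quantify the
    correlation cost when the two results differ only in rho).
    """
    return TaskComparison(
        max_rate_change_ratio=second.max_rate_change / first.max_rate_change,
        dprime_ratio=first.dprime / second.dprime,
    )


def dprime_ratio(a: DiscriminationResult, b: DiscriminationResult) -> float:
    """d'(a) / d'(b): e.g. the cost of correlations with a at rho=0."""
    return a.dprime / b.dprime


def _default_reference(model) -> Stimulus:
    from .model import DEFAULT_REFERENCE

    return DEFAULT_REFERENCE
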