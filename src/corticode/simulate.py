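"""Synthetic spike-count trials from the multivariate Gaussian count model.

Trials are drawn from a multivariate Gaussian with mean equal to the
expected counts and covariance V, rounded to the nearest integer
(ties-to-even, platform-stable) and clamped at zero.  Spike counts are
non-negative by definition, so negative rounded draws — possible for
units near the spontaneous rate — are clamped; for the standard
parameters this touches only a small fraction of near-spontaneous
entries and perturbs the moments negligibly (measured in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Stimulus

__all__ = ["TrialSet", "PairedTrialSet", "draw_spike_counts", "simulate_2i2afc",
           "write_trials", "read_trials"]


@dataclass(frozen=True)
class TrialSet:
    """trials x n spike-count matrix for one stimulus."""

    counts: np.ndarray
    stimulus: Stimulus
    seed: int
    integer: bool = True

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PairedTrialSet:
    """Two-interval trials: count vectors per interval plus the answer key.

    ``labels[t] = 1`` when the second interval of trial t contained the
    higher-valued stimulus (reference + Δx), 0 when it came first.
    """

    first: np.ndarray
    second: np.ndarray
    labels: np.ndarray
    task: str
    delta_x: float
    seed: int

    @property
    def n_trials(self) -> int:
        return self.labels.size


def _draw(rng, mean, V, n_trials, integer):
    x = rng.multivariate_normal(mean, V, size=n_trials, method="eigh")
    if integer:
        x = np.clip(np.rint(x), 0.0, None)
    return x


def draw_spike_counts(
    counts_mean: np.ndarray,
    V: np.ndarray,
    n_trials: int,
    seed: int,
    stimulus: Stimulus = None,
    integer: bool = True,
) -> TrialSet:
    """Seeded integer spike-count draws with mean ``counts_mean`` and covariance V.

    ``integer=False`` skips rounding and clamping (used to measure the
    distortion the integer constraint introduces).
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    mean = np.asarray(counts_mean, dtype=float)
    V = np.asarray(V, dtype=float)
    lam_min = float(np.linalg.eigvalsh(V)[0])
    if lam_min < -1e-8 * max(1.0, float(np.abs(V).max())):
        raise ValueError(f"covariance is not PSD (min eigenvalue {lam_min:.3e})")
    rng = np.random.default_rng(seed)
    counts = _draw(rng, mean, V, n_trials, integer)
    return TrialSet(counts=counts, stimulus=stimulus, seed=seed, integer=integer)


def simulate_2i2afc(
    model,
    task: str = "frequency",
    delta_x: float = 1.68,
    n_trials: int = 1000,
    seed: int = 0,
    reference: Stimulus = None,
    integer: bool = True,
) -> PairedTrialSet:
    """Paired-interval trials: reference and reference+Δx in random order.

    Interval order is exactly balanced for even ``n_trials`` (one extra
    reference-first trial when odd), then shuffled.
    """
    from .model import DEFAULT_REFERENCE

    ref = reference if reference is not None else DEFAULT_REFERENCE
    ref = Stimulus(ref.frequency_hz, ref.intensity_db, model.duration_s)
    if task == "frequency":
        alt = Stimulus(ref.frequency_hz + delta_x, ref.intensity_db, model.duration_s)
    elif task == "intensity":
        alt = Stimulus(ref.frequency_hz, ref.intensity_db + delta_x, model.duration_s)
    else:
        raise ValueError(f"task must be 'frequency' or 'intensity', got {task!r}")

    rng = np.random.default_rng(seed)
    mean_ref = model.rate_vector(ref).counts
    mean_alt = model.rate_vector(alt).counts
    V_ref = model.noise_model(ref).V
    V_alt = model.noise_model(alt).V
    x_ref = _draw(rng, mean_ref, V_ref, n_trials, integer)
    x_alt = _draw(rng, mean_alt, V_alt, n_trials, integer)

    labels = np.zeros(n_trials, dtype=int)
    labels[: n_trials // 2] = 1
    rng.shuffle(labels)
    first = np.where(labels[:, None] == 1, x_ref, x_alt)
    second = np.where(labels[:, None] == 1, x_alt, x_ref)
    return PairedTrialSet(
        first=first,
        second=second,
        labels=labels,
        task=task,
        delta_x=delta_x,
        seed=seed,
    )


def write_trials(path: str, trials: TrialSet, rho: float = None) -> None:
    """Delimited text with a header line carrying the trial metadata."""
    stim = trials.stimulus
    meta = [f"seed={trials.seed}", f"n={trials.counts.shape[1]}"]
    if rho is not None:
        meta.append(f"rho={rho}")
    if stim is not None:
        meta += [
            f"frequency_hz={stim.frequency_hz}",
            f"intensity_db={stim.intensity_db}",
            f"duration_s={stim.duration_s}",
        ]
    np.savetxt(path, trials.counts, fmt="%g", delimiter="\t", header=" ".join(meta))


def read_trials(path: str) -> TrialSet:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    meta = dict(kv.split("=", 1) for kv in header)
    counts = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    stim = None
    if "frequency_hz" in meta:
        stim = Stimulus(
            float(meta["frequency_hz"]),
            float(meta.get("intensity_db", 50.0)),
            float(meta.get("duration_s", 1.0)),
        )
    return TrialSet(counts=counts, stimulus=stim, seed=int(meta.get("seed", 0)))
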