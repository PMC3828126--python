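"""Flat key-value config files and delimited-text writers.

Config files are plain ``key = value`` lines (``#`` comments allowed);
recognised keys and defaults are in :data:`DEFAULT_CONFIG`.  All array
output is tab-delimited text so results stay diff- and grep-able.
"""

from __future__ import annotations

from typing import Dict, Mapping, Union

import numpy as np

__all__ = [
    "DEFAULT_CONFIG",
    "read_config",
    "write_config",
    "write_rate_vector",
    "read_rate_vector",
    "write_matrix",
    "read_matrix",
]

#: Standard analysis configuration: 1700 sharply tuned units (Q = 12) over
#: the two octaves centred on 1 kHz, rho = 0.25, r_s = 0.1 spikes/s,
#: r_e = 15 spikes/s at 50 dB SPL, 1 s tones.  The rate-level slope ``k``
#: (spikes/s/dB) defaults to 0 and is set by calibration.
DEFAULT_CONFIG: Dict[str, float] = {
    "n": 1700,
    "f_low_hz": 500.0,
    "f_high_hz": 2000.0,
    "q": 12.0,
    "rho": 0.25,
    "r_s": 0.1,
    "r_e_ref": 15.0,
    "k": 0.0,
    "duration_s": 1.0,
}


def read_config(path: str) -> Dict[str, float]:
    """Parse a flat ``key = value`` config file; unknown keys raise."""
    out: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in DEFAULT_CONFIG:
                raise ValueError(
                    f"{path}:{lineno}: unknown config key {key!r} "
                    f"(known: {', '.join(sorted(DEFAULT_CONFIG))})"
                )
            out[key] = float(value)
    return out


def write_config(path: str, cfg: Mapping[str, Union[int, float]]) -> None:
    with open(path, "w") as fh:
        for key in DEFAULT_CONFIG:
            if key in cfg:
                fh.write(f"{key} = {cfg[key]}\n")


def write_rate_vector(path: str, bf_hz: np.ndarray, rates: np.ndarray) -> None:
    """Two-column delimited text: bf_hz, rate_spikes_per_s."""
    data = np.column_stack([bf_hz, rates])
    np.savetxt(
        path, data, fmt="%.8g", delimiter="\t", header="bf_hz\trate_spikes_per_s"
    )


def read_rate_vector(path: str):
    data = np.loadtxt(path, delimiter="\t")
    return data[:, 0], data[:, 1]


def write_matrix(path: str, M: np.ndarray) -> None:
    """Dense delimited-text matrix (correlation or covariance)."""
    np.savetxt(path, M, fmt="%.8g", delimiter="\t")


def read_matrix(path: str) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")
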