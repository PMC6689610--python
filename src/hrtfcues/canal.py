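"""Geometric model of interaural-canal destructive interference.

At one ear, the directly arriving wave is superposed with the wave that
entered the opposite ear and crossed the head through the interaural canal.
A path-length difference delta between the two produces a phase difference

    Phi = 2 * pi * f * delta / c,

and destructive interference wherever Phi is an odd multiple of pi, i.e. at

    f_ic = (2k + 1) * c / (2 * delta),  k = 0, 1, ...

Because delta grows with source azimuth (the external interaural path adds
to the fixed canal length), the predicted notch frequency falls toward the
grid edges, tracing the crescent-shaped low-pressure band seen in skull
HRTF maps; and because delta scales with head size, the whole interference
band shifts to lower frequency for larger heads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .signals import SessionGrid
from .simulate import HeadGeometry, external_path_difference

__all__ = [
    "CanalPrediction",
    "phase_difference",
    "destructive_frequencies",
    "default_delta_fn",
    "predict_crescent",
]


@dataclass(frozen=True)
class CanalPrediction:
    """Predicted interference frequencies along the azimuth grid."""

    azimuths: np.ndarray
    f_ic: np.ndarray          # Hz, fundamental c / (2 delta) per azimuth
    delta: np.ndarray         # metres per azimuth
    speed_of_sound: float
    harmonics: tuple = (1,)   # odd multipliers reported (fundamental first)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "azimuth_deg": self.azimuths,
            "f_ic_hz": self.f_ic,
            "delta_m": self.delta,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def phase_difference(f: float | np.ndarray, delta: float, c: float):
    """Phase difference Phi = 2 pi f delta / c between direct and canal waves."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or delta <= 0 or c <= 0:
        raise ValueError("frequency, delta and c must all be positive")
    out = 2.0 * np.pi * f * delta / c
    return float(out) if out.ndim == 0 else out


def destructive_frequencies(
    delta: float, c: float, band: tuple[float, float]
) -> np.ndarray:
    """All antiphase frequencies (2k+1) * c / (2 delta) within a band, ascending.

    The fundamental is c / (2 delta); higher entries follow from
    Phi = pi mod 2 pi.
    """
    if delta <= 0 or c <= 0:
        raise ValueError("delta and c must be positive")
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"empty frequency band {band}")
    fundamental = c / (2.0 * delta)
    k_max = int(np.floor((hi / fundamental - 1) / 2))
    freqs = fundamental * (2 * np.arange(0, k_max + 1) + 1)
    return freqs[(freqs >= lo) & (freqs <= hi)]


def default_delta_fn(geometry: HeadGeometry) -> Callable[[float], float]:
    """Default azimuth-dependent path difference.

    Fixed canal length plus the external (Woodworth) interaural path
    difference — a declared stand-in for the (unpublished) skull geometry,
    exposed as a pluggable function so alternatives can be substituted.
    """

    def delta(azimuth: float) -> float:
        return geometry.canal_delta + external_path_difference(geometry, azimuth)

    return delta


def predict_crescent(
    geometry: HeadGeometry,
    grid: SessionGrid,
    delta_fn: Callable[[float], float] | None = None,
) -> CanalPrediction:
    """Fundamental interference frequency f_ic(theta) = c / (2 delta(theta))
    over a session grid.

    With the default ``delta_fn`` the curve is crescent-shaped: delta grows
    with |theta|, so f_ic is highest at normal incidence and lowest at the
    grid edges.
    """
    if delta_fn is None:
        delta_fn = default_delta_fn(geometry)
    c = geometry.speed_of_sound
    deltas = np.empty(grid.n_azimuths)
    for i, az in enumerate(grid.azimuths):
        d = delta_fn(float(az))
        if d <= 0:
            raise ValueError(f"delta_fn returned non-positive delta at {az} deg")
        deltas[i] = d
    return CanalPrediction(
        azimuths=grid.azimuths.copy(),
        f_ic=c / (2.0 * deltas),
        delta=deltas,
        speed_of_sound=c,
    )
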