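"""Potential localization level (PLL): how strongly a cue map varies with azimuth.

For a cue map M(f, theta) in dB (an HRTF or an ILD map), the PLL at each
frequency is

    PLL(f) = 20 * log10( (1 / N_theta) * sum_theta |dM(f, theta) / dtheta| ),

the azimuth-averaged absolute azimuthal derivative, in dB.  A high PLL
means the cue changes rapidly with source direction and is therefore
potentially informative for localization.  The derivative is taken per
degree on the measurement grid (central differences, one-sided at the grid
ends).  Because only the theta-derivative enters, the PLL is exactly
invariant to any azimuth-independent offset g(f) added to the map — in
particular to the normalization ambiguity left by microphone-position
compensation.

PLL curves grow roughly linearly with log-frequency on live-animal-like
maps; :func:`fit_slope` quantifies that as a dB/octave ordinary
least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cues import ILDMap
from .hrtf import TransferMap

__all__ = ["PLLCurve", "SlopeFit", "compute_pll", "fit_slope"]


@dataclass(frozen=True)
class PLLCurve:
    """PLL(f) in dB; entries where the map is azimuth-constant are undefined
    (held as -inf internally, serialized as an explicit marker)."""

    frequencies: np.ndarray
    values: np.ndarray  # dB; -inf marks undefined (log of a zero mean)
    source: str = "hrtf"  # hrtf | ild
    n_azimuths: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if f.shape != v.shape:
            raise ValueError("frequencies and values must have matching shapes")
        if np.any(np.isnan(v)) or np.any(v == np.inf):
            raise ValueError("PLL values must be finite or the -inf sentinel")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        vals = ["undefined" if not ok else float(v)
                for v, ok in zip(self.values, self.defined)]
        return pd.DataFrame({
            "frequency_hz": self.frequencies,
            "pll_db": vals,
            "source": self.source,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of PLL (dB) against log2(frequency)."""

    slope: float          # dB per octave
    intercept: float      # dB at 1 Hz (log2 f = 0)
    fit_band: tuple[float, float]
    residual_rms: float   # dB
    n_points: int
    n_excluded: int       # undefined (sentinel) points dropped from the band

    def to_dict(self) -> dict:
        return {
            "slope_db_per_octave": self.slope,
            "intercept_db": self.intercept,
            "fit_band_hz": list(self.fit_band),
            "residual_rms_db": self.residual_rms,
            "n_points": self.n_points,
            "n_excluded": self.n_excluded,
        }


def compute_pll(cue_map: Union[TransferMap, ILDMap]) -> PLLCurve:
    """PLL curve of a cue map in dB.

    Works on any frequency x azimuth dB grid with at least two azimuths.
    The azimuthal derivative uses central differences on the grid (one-sided
    at the ends), with theta in degrees, so values are on the same scale as
    maps sampled every 5 degrees.
    """
    az = np.asarray(cue_map.azimuths, dtype=float)
    if az.size < 2:
        raise ValueError("PLL needs at least two azimuth samples")
    deriv = np.gradient(cue_map.values, az, axis=1)  # dB per degree
    mean_abs = np.mean(np.abs(deriv), axis=1)
    with np.errstate(divide="ignore"):
        values = 20.0 * np.log10(mean_abs)
    source = "ild" if isinstance(cue_map, ILDMap) else "hrtf"
    return PLLCurve(np.asarray(cue_map.frequencies, dtype=float), values,
                    source=source, n_azimuths=int(az.size))


def fit_slope(
    curve: PLLCurve,
    band: tuple[float, float] = (200.0, 10_000.0),
    log_weighting: bool = True,
) -> SlopeFit:
    """Least-squares dB/octave slope of a PLL curve over a frequency band.

    Undefined (sentinel) points are excluded and counted.  With
    ``log_weighting`` (default) points are weighted by their local log2-
    frequency spacing, so a curve sampled on a linear FFT grid contributes
    uniformly per octave rather than being dominated by its dense high end.
    """
    in_band = (curve.frequencies >= band[0]) & (curve.frequencies <= band[1])
    finite = curve.defined
    keep = in_band & finite & (curve.frequencies > 0)
    n_excluded = int(np.sum(in_band & ~finite))
    if keep.sum() < 3:
        raise ValueError(
            f"need at least 3 finite PLL points in {band}, got {int(keep.sum())}"
        )
    x = np.log2(curve.frequencies[keep])
    y = curve.values[keep]
    if log_weighting and x.size > 2:
        w = np.gradient(x)
        w = np.maximum(w, 0.0) + 1e-15
    else:
        w = np.ones_like(x)
    sw = np.sqrt(w)
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    residual_rms = float(np.sqrt(np.average(resid**2, weights=w)))
    return SlopeFit(slope=slope, intercept=intercept, fit_band=band,
                    residual_rms=residual_rms, n_points=int(keep.sum()),
                    n_excluded=n_excluded)
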