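"""Binaural cue extraction: ILD maps from HRTFs, ITD curves from signals.

ILD is read directly off a symmetrized HRTF map under the head-symmetry
assumption, ILD(f, theta) = H(f, theta) - H(f, -theta).  ITD is the lag
maximizing the interchannel cross-correlation, refined to sub-sample
precision by a three-point parabolic fit around the integer peak (44.1 kHz
sampling alone quantizes lags to 22.7 us, too coarse for canal effects of a
few tens of microseconds).  Sign convention: positive ITD means the left
ear (ipsilateral for positive azimuth) leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .hrtf import TransferMap
from .signals import BinauralRecording, SessionGrid

__all__ = [
    "ILDMap",
    "ITDCurve",
    "compute_ild",
    "compute_itd",
    "itd_curve",
    "STANDARD_TONE_FREQS",
]

STANDARD_TONE_FREQS = (125.0, 250.0, 500.0, 1000.0)


@dataclass(frozen=True)
class ILDMap:
    """Interaural level differences on a frequency x (non-negative) azimuth grid."""

    frequencies: np.ndarray
    azimuths: np.ndarray  # theta >= 0 half-grid
    values: np.ndarray    # dB, (n_freq, n_az)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.azimuths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(a < 0):
            raise ValueError("ILD azimuths must be non-negative")
        if v.shape != (f.size, a.size):
            raise ValueError("ILD grid dimensions inconsistent")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "azimuths", a)
        object.__setattr__(self, "values", v)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, columns=self.azimuths)
        frame.insert(0, "frequency_hz", self.frequencies)
        frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ITDCurve:
    """Interaural time differences across azimuth for one stimulus."""

    azimuths: np.ndarray
    delays: np.ndarray  # seconds
    stimulus: str = "pulse"
    canal_state: str = "blocked"
    normalized: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.azimuths, dtype=float)
        d = np.asarray(self.delays, dtype=float)
        if a.shape != d.shape:
            raise ValueError("azimuths and delays must have matching shapes")
        object.__setattr__(self, "azimuths", a)
        object.__setattr__(self, "delays", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "azimuth_deg": self.azimuths,
            "itd_us": self.delays * 1e6,
            "stimulus": self.stimulus,
            "canal_state": self.canal_state,
        })


# ---------------------------------------------------------------------------
# ILD
# ---------------------------------------------------------------------------

def compute_ild(transfer_map: TransferMap) -> ILDMap:
    """ILD(f, theta) = H(f, theta) - H(f, -theta) on the half-grid theta >= 0.

    Requires every positive azimuth to have its mirror on the map; ILD at
    0 deg is identically zero by construction.
    """
    az = transfer_map.azimuths
    pos = az[az >= 0]
    cols = []
    for theta in pos:
        i = np.nonzero(np.isclose(az, theta))[0][0]
        j = np.nonzero(np.isclose(az, -theta))[0]
        if j.size == 0:
            raise ValueError(f"map lacks the mirror azimuth of {theta} deg")
        cols.append(transfer_map.values[:, i] - transfer_map.values[:, j[0]])
    return ILDMap(transfer_map.frequencies, pos, np.column_stack(cols),
                  metadata=dict(transfer_map.metadata))


# ---------------------------------------------------------------------------
# ITD
# ---------------------------------------------------------------------------

def _parabolic_refine(corr: np.ndarray, peak: int) -> float:
    """Sub-sample peak location via a 3-point parabola; returns the offset."""
    if peak <= 0 or peak >= corr.size - 1:
        return 0.0
    c_m, c_0, c_p = corr[peak - 1], corr[peak], corr[peak + 1]
    denom = c_m - 2.0 * c_0 + c_p
    if denom == 0:
        return 0.0
    return 0.5 * (c_m - c_p) / denom


def compute_itd(
    recording: BinauralRecording,
    max_lag: float = 0.002,
    search_center: float = 0.0,
) -> float:
    """Interaural delay of one recording, in seconds.

    The lag maximizing the cross-correlation between left and right
    channels is searched within ``search_center +/- max_lag`` and refined
    by parabolic interpolation.  Positive values mean the left ear leads.
    """
    left = recording.left.samples
    right = recording.right.samples
    if not np.any(left) or not np.any(right):
        raise ValueError("all-zero channel: cross-correlation is flat")
    rate = recording.rate
    n = left.size
    if max_lag <= 0 or max_lag >= n / rate:
        raise ValueError("max_lag must be positive and within the signal duration")
    # corr[k] overlaps left[i] with right[i - m], m = k - (n - 1); when the
    # left channel leads by D samples (right delayed), the peak sits at
    # m = -D, so tau = -m / rate is positive when the left ear leads.
    corr = fftconvolve(left, right[::-1], mode="full")
    taus = -np.arange(-(n - 1), n) / rate
    window = (taus >= search_center - max_lag) & (taus <= search_center + max_lag)
    if not np.any(window):
        raise ValueError("search window contains no integer lags")
    idx = np.nonzero(window)[0]
    peak = idx[np.argmax(corr[idx])]
    offset = _parabolic_refine(corr, peak)
    return float(taus[peak] - offset / rate)


def itd_curve(
    recordings: Sequence[BinauralRecording],
    grid: SessionGrid,
    stimulus: str = "pulse",
    tone_freq: float | None = None,
    normalize_to_zero: bool = True,
    canal_state: str = "blocked",
    max_itd_bound: float | None = None,
    seed_curve: "ITDCurve | None" = None,
    max_lag: float = 0.002,
) -> ITDCurve:
    """Per-azimuth ITD across a session, normalized to the 0 deg value.

    For pure tones the lag search is capped at half the tone period (and,
    when a broadband ``seed_curve`` from a pulse run is supplied, centred on
    its per-azimuth estimate) to avoid cycle ambiguity.  A tone whose half
    period is smaller than the physical ITD bound is rejected as ambiguous.
    """
    if len(recordings) != grid.n_azimuths:
        raise ValueError("one recording per grid azimuth required")
    if tone_freq is not None:
        half_period = 0.5 / tone_freq
        if max_itd_bound is not None and half_period < max_itd_bound:
            raise ValueError(
                f"tone at {tone_freq} Hz is cycle-ambiguous: half period "
                f"{half_period * 1e6:.0f} us < physical ITD bound "
                f"{max_itd_bound * 1e6:.0f} us"
            )
        max_lag = min(max_lag, half_period)
        label = f"tone_{tone_freq:g}Hz"
    else:
        label = stimulus

    delays = np.empty(grid.n_azimuths)
    for i, rec in enumerate(recordings):
        center = 0.0
        if seed_curve is not None:
            center = float(np.interp(rec.azimuth, seed_curve.azimuths,
                                     seed_curve.delays))
        delays[i] = compute_itd(rec, max_lag=max_lag, search_center=center)
    if normalize_to_zero:
        delays = delays - delays[grid.index_of(0.0)]
    return ITDCurve(grid.azimuths.copy(), delays, stimulus=label,
                    canal_state=canal_state, normalized=normalize_to_zero)
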