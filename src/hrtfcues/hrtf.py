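"""HRTF estimation: spectra, calibration, microphone normalization, smoothing.

The in-ear recording R(f, theta, x) factorizes as the product of the
calibration signal S(f) (equipment transfer function, measured with the
microphones at the virtual head centre), the head-related transfer function
H(f, theta) and a microphone-position colouration mu(f, x).  Dividing each
recording by S and by the session-averaged mu,

    mu(f, x) = (1 / (S(f) N)) * sum_i R_i(f, theta_i, x),
    H(f, theta) = R(f, theta, x) / (S(f) * mu(f, x)),

cancels both nuisance factors exactly.  A consequence of estimating mu from
the session itself is that the linear-domain azimuth average of each
estimated per-ear H is exactly 1: maps are identified only up to that
normalization, so comparisons against ground truth are made after removing
the azimuth mean on both sides.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import welch

from .signals import TimeSignal

__all__ = [
    "SpectrumEstimate",
    "TransferMap",
    "DB_FLOOR",
    "estimate_spectrum",
    "average_calibration",
    "compute_hrtf",
    "symmetrize",
    "frequency_kernel_width",
    "smooth_map",
    "remove_azimuth_mean",
]

DB_FLOOR = 1e-12  # linear magnitude floor before taking logs


@dataclass(frozen=True)
class SpectrumEstimate:
    """Magnitude spectrum on a fixed frequency grid (linear units)."""

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if f.shape != v.shape:
            raise ValueError("frequencies and values must have the same shape")
        if f.size and not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TransferMap:
    """A dB gain map on a frequency x azimuth grid (houses H(f, theta))."""

    frequencies: np.ndarray
    azimuths: np.ndarray
    values: np.ndarray  # (n_freq, n_az), dB
    smoothed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.azimuths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (f.size, a.size):
            raise ValueError(
                f"value grid {v.shape} inconsistent with "
                f"{f.size} frequencies x {a.size} azimuths"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("map values must be finite (dB)")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "azimuths", a)
        object.__setattr__(self, "values", v)

    def to_csv(self, path: str | Path) -> None:
        """Rows = frequency bins, columns = azimuths; metadata in # comments."""
        with open(path, "w") as fh:
            fh.write(f"# smoothed: {self.smoothed}\n")
            for key, val in self.metadata.items():
                fh.write(f"# {key}: {val}\n")
            frame = pd.DataFrame(self.values, columns=self.azimuths)
            frame.insert(0, "frequency_hz", self.frequencies)
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransferMap":
        meta: dict = {}
        smoothed = False
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            key, _, val = line[1:].partition(":")
            key, val = key.strip(), val.strip()
            if key == "smoothed":
                smoothed = val == "True"
            else:
                meta[key] = val
        frame = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        return cls(
            frequencies=frame["frequency_hz"].to_numpy(),
            azimuths=np.array([float(c) for c in frame.columns[1:]]),
            values=frame.iloc[:, 1:].to_numpy(),
            smoothed=smoothed,
            metadata=meta,
        )


# ---------------------------------------------------------------------------
# Spectrum estimation
# ---------------------------------------------------------------------------

def estimate_spectrum(
    signal: TimeSignal,
    band: tuple[float, float] | None = (20.0, 10_000.0),
    nfft: int | None = None,
    method: str = "fft",
    welch_nperseg: int = 8192,
) -> SpectrumEstimate:
    """Magnitude spectrum of a signal on a session-shared frequency grid.

    The default estimator is a single FFT of the whole (synchronized)
    signal, which gives maximal frequency resolution for sweep recordings;
    ``method='welch'`` averages periodogram segments instead (lower
    variance, coarser grid) for noisy inputs.  ``nfft`` fixes the grid so
    that every recording in a session lands on identical bins.
    """
    if signal.n_samples == 0:
        raise ValueError("empty signal")
    x = signal.samples
    if x.ndim != 1:
        raise ValueError("estimate_spectrum expects a single channel")
    nyquist = signal.rate / 2
    if band is not None and band[1] > nyquist:
        raise ValueError(f"band upper edge {band[1]} Hz above Nyquist {nyquist} Hz")
    if method == "fft":
        n = nfft or signal.n_samples
        freqs = rfftfreq(n, 1.0 / signal.rate)
        mags = np.abs(rfft(x, n))
    elif method == "welch":
        freqs, psd = welch(x, fs=signal.rate,
                           nperseg=min(welch_nperseg, signal.n_samples))
        mags = np.sqrt(psd)
    else:
        raise ValueError(f"unknown method {method!r}")
    if band is not None:
        keep = (freqs >= band[0]) & (freqs <= band[1])
        freqs, mags = freqs[keep], mags[keep]
    return SpectrumEstimate(freqs, mags)


def _check_common_grid(spectra: Sequence[SpectrumEstimate]) -> np.ndarray:
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != grid.shape or not np.allclose(
                s.frequencies, grid):
            raise ValueError("spectra do not share a common frequency grid")
    return grid


def average_calibration(spectra: Sequence[SpectrumEstimate]) -> SpectrumEstimate:
    """Mean magnitude spectrum across calibration repetitions (n = 10
    in the acquisition protocol); averaging reduces the noise variance by
    roughly the number of repetitions."""
    if len(spectra) == 0:
        raise ValueError("need at least one calibration spectrum")
    grid = _check_common_grid(spectra)
    return SpectrumEstimate(grid, np.mean([s.values for s in spectra], axis=0))


# ---------------------------------------------------------------------------
# HRTF computation
# ---------------------------------------------------------------------------

def compute_hrtf(
    spectra: Sequence[SpectrumEstimate],
    azimuths: Sequence[float],
    calibration: SpectrumEstimate,
    metadata: dict | None = None,
) -> TransferMap:
    """Per-ear HRTF map from one ear's session spectra and the calibration.

    Implements H = R / (S * mu) with mu estimated as the session average
    (1/(S N)) * sum_i R_i, which reduces algebraically to
    H_i = R_i * N / sum_i R_i: any fixed colouration multiplying every R_i
    (microphone position, equipment) cancels exactly, and the linear-domain
    azimuth mean of the returned map is exactly 1 (0 dB) at each frequency.
    """
    azimuths = np.asarray(azimuths, dtype=float)
    if len(spectra) != azimuths.size:
        raise ValueError("one spectrum per azimuth required")
    if len(spectra) < 1:
        raise ValueError("empty session")
    grid = _check_common_grid(list(spectra) + [calibration])
    if np.any(calibration.values == 0):
        fbad = grid[np.nonzero(calibration.values == 0)[0][0]]
        raise ValueError(f"calibration spectrum has a zero bin at {fbad} Hz")
    stack = np.stack([s.values for s in spectra], axis=1)  # (n_freq, n_az)
    mean_r = stack.mean(axis=1)
    if np.any(mean_r == 0):
        fbad = grid[np.nonzero(mean_r == 0)[0][0]]
        raise ValueError(f"session-average spectrum is zero at {fbad} Hz")
    h_lin = stack / mean_r[:, None]
    values = 20.0 * np.log10(np.maximum(h_lin, DB_FLOOR))
    return TransferMap(grid, azimuths, values, smoothed=False,
                       metadata=metadata or {})


def symmetrize(left_map: TransferMap, right_map: TransferMap) -> TransferMap:
    """Average the two ears under the head-symmetry assumption.

    output(f, theta) = mean of left(f, theta) and right(f, -theta), in the
    dB domain (a geometric mean in linear units).  Requires a symmetric
    azimuth grid shared by both maps.
    """
    if (left_map.frequencies.shape != right_map.frequencies.shape
            or not np.allclose(left_map.frequencies, right_map.frequencies)
            or not np.allclose(left_map.azimuths, right_map.azimuths)):
        raise ValueError("left/right maps must share frequency and azimuth grids")
    az = left_map.azimuths
    mirror = np.empty(az.size, dtype=int)
    for i, theta in enumerate(az):
        j = np.nonzero(np.isclose(az, -theta))[0]
        if j.size == 0:
            raise ValueError(f"azimuth grid lacks the mirror of {theta} deg")
        mirror[i] = j[0]
    values = 0.5 * (left_map.values + right_map.values[:, mirror])
    return TransferMap(left_map.frequencies, az, values,
                       smoothed=left_map.smoothed and right_map.smoothed,
                       metadata={**right_map.metadata, **left_map.metadata,
                                 "symmetrized": True})


# ---------------------------------------------------------------------------
# 2-D Gaussian smoothing with frequency-dependent bandwidth
# ---------------------------------------------------------------------------

_WIDTH_ANCHORS = ((20.0, 3.0), (10_000.0, 1_000.0))
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def frequency_kernel_width(f: float | np.ndarray) -> float | np.ndarray:
    """Smoothing kernel width (Hz) at frequency f.

    Power law through the two anchors: 3 Hz at 20 Hz and 1 kHz at 10 kHz,
    i.e. width(f) = 3 * (f / 20)**beta with beta = log(1000/3) / log(500).
    """
    (f1, w1), (f2, w2) = _WIDTH_ANCHORS
    beta = np.log(w2 / w1) / np.log(f2 / f1)
    return w1 * (np.asarray(f, dtype=float) / f1) ** beta


def _gaussian_weights(distance: np.ndarray, sigma: float) -> np.ndarray:
    w = np.exp(-0.5 * (distance / sigma) ** 2)
    return w / w.sum()


def smooth_map(
    transfer_map: TransferMap,
    azimuth_width_points: float = 5.0,
    truncate: float = 3.0,
) -> TransferMap:
    """Separable 2-D Gaussian smoothing of a dB map.

    The azimuth axis uses a fixed kernel of ``azimuth_width_points`` grid
    steps full width at half maximum; the frequency axis uses a kernel whose
    FWHM follows :func:`frequency_kernel_width`.  Kernels are truncated at
    ``truncate`` standard deviations and renormalized to unit sum at every
    location (including grid edges), so a constant map is left exactly
    unchanged and single-bin mass is conserved.
    """
    if transfer_map.smoothed:
        raise ValueError("map is already smoothed; refusing to smooth twice")
    az = transfer_map.azimuths
    freqs = transfer_map.frequencies
    values = transfer_map.values

    # azimuth axis: fixed-width kernel, small dense weight matrix
    if az.size > 1:
        step = float(np.median(np.diff(az)))
        sigma_az = azimuth_width_points * step * _FWHM_TO_SIGMA
        dist = np.abs(az[:, None] - az[None, :])
        weights = np.where(dist <= truncate * sigma_az,
                           np.exp(-0.5 * (dist / sigma_az) ** 2), 0.0)
        weights /= weights.sum(axis=1, keepdims=True)
        values = values @ weights.T
    # frequency axis: variable-width kernel, windowed per bin
    out = np.empty_like(values)
    sigmas = np.asarray(frequency_kernel_width(freqs)) * _FWHM_TO_SIGMA
    for i, (f0, sigma) in enumerate(zip(freqs, sigmas)):
        lo = np.searchsorted(freqs, f0 - truncate * sigma, side="left")
        hi = np.searchsorted(freqs, f0 + truncate * sigma, side="right")
        w = _gaussian_weights(freqs[lo:hi] - f0, sigma)
        out[i, :] = w @ values[lo:hi, :]
    return TransferMap(freqs, az, out, smoothed=True,
                       metadata=dict(transfer_map.metadata))


def remove_azimuth_mean(transfer_map: TransferMap) -> TransferMap:
    """Subtract, per frequency, the dB value of the linear-domain azimuth
    mean — the normalization the mu-based estimator imposes by construction;
    apply it to ground-truth maps before comparing with estimates."""
    lin = 10.0 ** (transfer_map.values / 20.0)
    mean_db = 20.0 * np.log10(np.maximum(lin.mean(axis=1), DB_FLOOR))
    return dataclasses.replace(
        transfer_map, values=transfer_map.values - mean_db[:, None]
    )
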