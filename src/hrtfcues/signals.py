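"""Time-domain containers, session I/O and acquisition pre-processing.

The measurement protocol records, for every source azimuth on a grid, the
pressure signals at in-ear microphones in both ears, plus calibration
recordings made with both microphones at the virtual centre of the head.
This module holds the time-domain containers (:class:`TimeSignal`,
:class:`BinauralRecording`, :class:`SessionGrid`), reads and writes whole
sessions as directories of stereo WAV files with a YAML descriptor, and
implements the standard pre-processing applied before spectral analysis:
time synchronization against the emitted stimulus, Hann onset/offset ramps,
and RMS normalization by the normal-incidence (0 deg) recording.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from scipy.signal import fftconvolve


__all__ = [
    "TimeSignal",
    "BinauralRecording",
    "SessionGrid",
    "read_session",
    "write_session",
    "synchronize",
    "apply_ramps",
    "rms_normalize",
]


@dataclass(frozen=True)
class TimeSignal:
    """A sampled pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Linear pressure amplitudes (arbitrary units).  Shape ``(n,)`` for a
        single channel or ``(n, n_channels)``.
    rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or 2-D (n, n_channels)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def scaled(self, factor: float) -> "TimeSignal":
        return TimeSignal(self.samples * factor, self.rate)


@dataclass(frozen=True)
class BinauralRecording:
    """Left/right in-ear signals recorded for one source azimuth."""

    left: TimeSignal
    right: TimeSignal
    azimuth: float
    condition: str = "free_field"
    stimulus: object | None = None

    def __post_init__(self) -> None:
        if self.left.rate != self.right.rate:
            raise ValueError(
                f"left/right rates differ: {self.left.rate} vs {self.right.rate}"
            )
        if self.left.n_samples != self.right.n_samples:
            raise ValueError(
                "left/right lengths differ: "
                f"{self.left.n_samples} vs {self.right.n_samples}"
            )

    @property
    def rate(self) -> float:
        return self.left.rate

    def as_stereo(self) -> np.ndarray:
        return np.column_stack([self.left.samples, self.right.samples])


def default_azimuths(step: float = 5.0, limit: float = 90.0) -> np.ndarray:
    """Canonical azimuth grid: -limit .. +limit inclusive, in `step` increments."""
    n = int(round(limit / step))
    return np.arange(-n, n + 1) * step


@dataclass(frozen=True)
class SessionGrid:
    """Azimuth grid of a measurement session (elevation fixed at 0 deg)."""

    azimuths: np.ndarray = field(default_factory=default_azimuths)
    elevation: float = 0.0
    source_distance: float = 1.0
    rate: float = 44100.0

    def __post_init__(self) -> None:
        az = np.asarray(self.azimuths, dtype=float)
        if az.size == 0:
            raise ValueError("azimuth grid is empty")
        if not np.all(np.diff(az) > 0):
            raise ValueError("azimuths must be sorted and pairwise distinct")
        if not np.allclose(az + az[::-1], 0.0):
            raise ValueError("azimuth grid must be symmetric about 0")
        object.__setattr__(self, "azimuths", az)

    @property
    def n_azimuths(self) -> int:
        """Number of azimuth positions (37 on the canonical -90..90 / 5 deg grid)."""
        return int(self.azimuths.size)

    def index_of(self, azimuth: float) -> int:
        idx = np.nonzero(np.isclose(self.azimuths, azimuth))[0]
        if idx.size == 0:
            raise KeyError(f"azimuth {azimuth} not on session grid")
        return int(idx[0])


# ---------------------------------------------------------------------------
# Session I/O: directory of stereo WAVs + YAML descriptor + ground-truth CSV
# ---------------------------------------------------------------------------

DESCRIPTOR_NAME = "session.yaml"
GROUND_TRUTH_NAME = "ground_truth.csv"


def _azimuth_filename(azimuth: float, condition: str) -> str:
    sign = "m" if azimuth < 0 else "p"
    return f"az_{sign}{abs(azimuth):05.1f}_{condition}.wav"


def _calibration_filename(index: int, condition: str) -> str:
    return f"calibration_{index:02d}_{condition}.wav"


def write_session(
    directory: str | Path,
    grid: SessionGrid,
    recordings: Sequence[BinauralRecording],
    calibrations: Sequence[BinauralRecording] = (),
    metadata: dict | None = None,
    ground_truth: pd.DataFrame | None = None,
) -> Path:
    """Write a session as one stereo float32 WAV per azimuth plus a descriptor.

    The descriptor (YAML) lists azimuths, condition, rate and any extra
    metadata so the session round-trips exactly through :func:`read_session`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(recordings) != grid.n_azimuths:
        raise ValueError(
            f"{len(recordings)} recordings for {grid.n_azimuths} grid azimuths"
        )
    condition = recordings[0].condition
    for rec in recordings:
        if rec.rate != grid.rate:
            raise ValueError(f"recording rate {rec.rate} != grid rate {grid.rate}")
        fname = _azimuth_filename(rec.azimuth, condition)
        wavfile.write(directory / fname, int(grid.rate),
                      rec.as_stereo().astype(np.float32))
    for i, cal in enumerate(calibrations):
        wavfile.write(directory / _calibration_filename(i, condition),
                      int(grid.rate), cal.as_stereo().astype(np.float32))
    descriptor = {
        "azimuths": [float(a) for a in grid.azimuths],
        "condition": condition,
        "rate": float(grid.rate),
        "source_distance": float(grid.source_distance),
        "elevation": float(grid.elevation),
        "n_calibrations": len(calibrations),
        "metadata": metadata or {},
    }
    with open(directory / DESCRIPTOR_NAME, "w") as fh:
        yaml.safe_dump(descriptor, fh, sort_keys=False)
    if ground_truth is not None:
        ground_truth.to_csv(directory / GROUND_TRUTH_NAME, index=False)
    return directory


def read_session(
    directory: str | Path,
) -> tuple[SessionGrid, list[BinauralRecording], list[BinauralRecording]]:
    """Read a session directory written by :func:`write_session`.

    Raises
    ------
    FileNotFoundError
        If the descriptor or any azimuth WAV named by it is missing.
    ValueError
        On a sampling-rate mismatch between a WAV file and the descriptor.
    """
    directory = Path(directory)
    desc_path = directory / DESCRIPTOR_NAME
    if not desc_path.exists():
        raise FileNotFoundError(f"missing session descriptor {desc_path}")
    with open(desc_path) as fh:
        desc = yaml.safe_load(fh)
    grid = SessionGrid(
        azimuths=np.asarray(desc["azimuths"], dtype=float),
        elevation=desc.get("elevation", 0.0),
        source_distance=desc.get("source_distance", 1.0),
        rate=desc["rate"],
    )
    condition = desc["condition"]

    def _load(path: Path, azimuth: float) -> BinauralRecording:
        if not path.exists():
            raise FileNotFoundError(
                f"descriptor lists azimuth {azimuth} but {path.name} is missing"
            )
        rate, data = wavfile.read(path)
        if rate != grid.rate:
            raise ValueError(
                f"{path.name}: rate {rate} Hz differs from session rate "
                f"{grid.rate} Hz"
            )
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"{path.name}: expected stereo WAV")
        if data.dtype.kind == "i":  # integer PCM -> scale to [-1, 1)
            data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
        else:
            data = data.astype(float)
        return BinauralRecording(
            left=TimeSignal(data[:, 0], rate),
            right=TimeSignal(data[:, 1], rate),
            azimuth=azimuth,
            condition=condition,
        )

    recordings = [
        _load(directory / _azimuth_filename(az, condition), az)
        for az in grid.azimuths
    ]
    calibrations = [
        _load(directory / _calibration_filename(i, condition), math.nan)
        for i in range(desc.get("n_calibrations", 0))
    ]
    return grid, recordings, calibrations


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def _best_lag(x: np.ndarray, ref: np.ndarray) -> int:
    """Integer lag maximizing the cross-correlation of x against ref.

    Positive lag means x is delayed relative to ref.
    """
    corr = fftconvolve(x, ref[::-1], mode="full")
    return int(np.argmax(corr)) - (len(ref) - 1)


def synchronize(
    reference: TimeSignal, recording: BinauralRecording
) -> BinauralRecording:
    """Align a binaural recording to the emitted stimulus.

    The lag maximizing the cross-correlation between the recording (channel
    sum) and the reference is removed by a common shift of both channels, so
    the interaural lag is preserved exactly.  Integer-sample resolution;
    sub-sample alignment is deferred to ITD estimation where it matters.
    """
    if reference.rate != recording.rate:
        raise ValueError("reference and recording rates differ")
    mix = recording.left.samples + recording.right.samples
    ref = np.asarray(reference.samples, dtype=float)
    if not np.any(mix) or not np.any(ref):
        raise ValueError("all-zero signal: no correlation peak to synchronize on")
    lag = _best_lag(mix, ref)

    def _shift(sig: TimeSignal) -> TimeSignal:
        out = np.zeros_like(sig.samples)
        if lag > 0:
            out[: sig.n_samples - lag] = sig.samples[lag:]
        elif lag < 0:
            out[-lag:] = sig.samples[: sig.n_samples + lag]
        else:
            out = sig.samples.copy()
        return TimeSignal(out, sig.rate)

    return dataclasses.replace(
        recording, left=_shift(recording.left), right=_shift(recording.right)
    )


def apply_ramps(signal: TimeSignal, ramp_points: int = 501) -> TimeSignal:
    """Apply Hann onset/offset ramps of ``ramp_points`` samples each.

    The first and last ``ramp_points`` samples are multiplied by the rising
    and falling half of a Hann window (a ``2*ramp_points - 1`` point window
    split at its peak); the interior is untouched.  ``ramp_points=0`` is the
    identity.
    """
    if ramp_points < 0:
        raise ValueError("ramp_points must be non-negative")
    if ramp_points == 0:
        return signal
    if signal.n_samples < 2 * ramp_points:
        raise ValueError(
            f"signal of {signal.n_samples} samples too short for "
            f"{ramp_points}-point ramps at both ends"
        )
    window = np.hanning(2 * ramp_points - 1)
    rise = window[:ramp_points]
    out = signal.samples.copy()
    shape = (-1,) + (1,) * (out.ndim - 1)
    out[:ramp_points] *= rise.reshape(shape)
    out[-ramp_points:] *= rise[::-1].reshape(shape)
    return TimeSignal(out, signal.rate)


def rms_normalize(
    recordings: Sequence[BinauralRecording], grid: SessionGrid
) -> list[BinauralRecording]:
    """Normalize every channel by the RMS of the 0 deg channel.

    Left channels are divided by the RMS of the normal-incidence left channel
    and right channels by the normal-incidence right RMS, independently.
    Idempotent, and invariant to a common rescaling of all inputs.
    """
    i0 = grid.index_of(0.0)
    rms_left = recordings[i0].left.rms()
    rms_right = recordings[i0].right.rms()
    if rms_left == 0 or rms_right == 0:
        raise ValueError("zero RMS in the 0 deg recording; cannot normalize")
    return [
        dataclasses.replace(
            rec,
            left=rec.left.scaled(1.0 / rms_left),
            right=rec.right.scaled(1.0 / rms_right),
        )
        for rec in recordings
    ]
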