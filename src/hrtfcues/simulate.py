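"""Forward acoustic model: synthetic binaural sessions with known cues.

The animal/skull recordings this pipeline is designed for are binaural
in-ear measurements on an azimuth grid.  This module generates such
sessions synthetically, with exact ground truth, from a simple physical
model:

* a spherical-head approximation of the external filter — Woodworth-type
  interaural delays (straight-line path on the facing side, creeping arc on
  the shadowed side) plus a first-order head-shadow magnitude response whose
  attenuation grows with frequency and with the angle between source and
  ear;
* an image-source ground/water reflection (reflection coefficient +1 for a
  perfectly reflective surface), which turns each ear's single direct path
  into a two-ray comb filter;
* an interaural canal coupling the two ears internally: each ear receives,
  on top of its external signal, a delayed and attenuated copy of the
  opposite ear's external signal, producing destructive interference at
  odd multiples of c/(2*delta) and shortening apparent interaural delays;
* microphone-position colouration (a smooth random spectral tilt per ear)
  and an equipment transfer function common to all recordings, both of
  which the estimation stage must cancel;
* additive white Gaussian measurement noise at a configurable level
  relative to the stimulus RMS.

The head-shadow filter is applied zero-phase (magnitude only): all
interaural delay is carried explicitly by the Woodworth term, so the
simulator's ITD ground truth is exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.signal import chirp

from .signals import BinauralRecording, SessionGrid, TimeSignal

__all__ = [
    "StimulusSpec",
    "HeadGeometry",
    "SceneConfig",
    "GroundTruth",
    "SimulatedSession",
    "preset_geometry",
    "make_stimulus",
    "woodworth_ear_delays",
    "woodworth_itd",
    "external_path_difference",
    "head_response",
    "PropagationPath",
    "direct_paths",
    "apply_surface_reflection",
    "apply_canal_coupling",
    "simulate_session",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Emitted stimulus description.

    Defaults mirror the acquisition protocol: a 20 Hz - 10 kHz logarithmic
    sine sweep of 5 s at 80 dB SPL, sampled at 44.1 kHz.  Pure tones default
    to 500 ms; the pulse is a single-sample unit impulse (band-limited only
    by the sampling itself, so broadband delay estimates are well defined).
    """

    kind: str = "log_sweep"  # log_sweep | tone | pulse
    f_start: float = 20.0
    f_end: float = 10_000.0
    duration: float = 5.0
    level: float = 80.0  # dB SPL, metadata (amplitude is unity)
    tone_freq: float | None = None
    rate: float = 44_100.0

    def __post_init__(self) -> None:
        if self.kind not in ("log_sweep", "tone", "pulse"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind == "log_sweep":
            if not self.f_start < self.f_end:
                raise ValueError(
                    f"sweep needs f_start < f_end, got {self.f_start} >= {self.f_end}"
                )
            if self.rate < 2 * self.f_end:
                raise ValueError("sweep f_end violates the Nyquist limit")
        if self.kind == "tone":
            if self.tone_freq is None or self.tone_freq <= 0:
                raise ValueError("tone stimulus requires a positive tone_freq")
            if self.rate < 2 * self.tone_freq:
                raise ValueError("tone_freq violates the Nyquist limit")

    @classmethod
    def tone(cls, freq: float, duration: float = 0.5,
             rate: float = 44_100.0) -> "StimulusSpec":
        return cls(kind="tone", tone_freq=freq, duration=duration, rate=rate,
                   f_start=freq, f_end=freq)

    @classmethod
    def pulse(cls, duration: float = 0.05, rate: float = 44_100.0) -> "StimulusSpec":
        return cls(kind="pulse", duration=duration, rate=rate,
                   f_start=0.0, f_end=rate / 2)

    def label(self) -> str:
        if self.kind == "tone":
            return f"tone_{self.tone_freq:g}Hz"
        return self.kind


@dataclass(frozen=True)
class HeadGeometry:
    """Head dimensions governing the external and internal acoustic paths.

    ``canal_delta`` is the internal path length through the interaural canal
    (metres); the total path difference seen at an ear also includes the
    external interaural path difference, which depends on azimuth.
    ``canal_transmission`` scales the internally coupled wave (must be in
    (0, 1]; 1.0 means lossless coupling).
    """

    interaural_distance: float = 0.047
    effective_radius: float | None = None
    canal_delta: float | None = None
    canal_state: str = "open"  # open | blocked
    canal_transmission: float = 0.5
    snout_length: float | None = None
    speed_of_sound: float = 343.0

    def __post_init__(self) -> None:
        if self.interaural_distance <= 0:
            raise ValueError("interaural_distance must be positive")
        if self.effective_radius is None:
            object.__setattr__(self, "effective_radius",
                               self.interaural_distance / 2.0)
        if self.effective_radius <= 0:
            raise ValueError("effective_radius must be positive")
        if self.canal_delta is None:
            object.__setattr__(self, "canal_delta", self.interaural_distance)
        if self.canal_delta <= 0:
            raise ValueError("canal_delta must be positive")
        if self.canal_state not in ("open", "blocked"):
            raise ValueError(f"unknown canal_state {self.canal_state!r}")
        if not (0.0 < self.canal_transmission <= 1.0):
            raise ValueError("canal_transmission must lie in (0, 1]")
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")

    def scaled(self, s: float) -> "HeadGeometry":
        """Uniformly scale every length by ``s`` (size-scaling studies)."""
        return dataclasses.replace(
            self,
            interaural_distance=self.interaural_distance * s,
            effective_radius=self.effective_radius * s,
            canal_delta=self.canal_delta * s,
            snout_length=None if self.snout_length is None
            else self.snout_length * s,
        )


_PRESETS = {
    # live animals: stated interaural distances
    "crocodile": dict(interaural_distance=0.047, snout_length=None),
    "caiman": dict(interaural_distance=0.039, snout_length=None),
    # skulls: interaural distance stated only for the juvenile (6.9 cm) skull;
    # larger skulls scale it by head length (16.5 and 22.7 cm)
    "skull_small": dict(interaural_distance=0.024, snout_length=0.069),
    "skull_medium": dict(interaural_distance=0.024 * 16.5 / 6.9,
                         snout_length=0.165),
    "skull_large": dict(interaural_distance=0.024 * 22.7 / 6.9,
                        snout_length=0.227),
}


def preset_geometry(name: str, **overrides) -> HeadGeometry:
    """Named head geometries for the studied animals and skulls."""
    if name not in _PRESETS:
        raise KeyError(f"unknown geometry preset {name!r}; "
                       f"choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return HeadGeometry(**params)


@dataclass(frozen=True)
class SceneConfig:
    """Acoustic scene: measurement condition, surface, source and noise.

    ``noise_level`` is in dB relative to the stimulus RMS (e.g. -60 matches
    a 20 dB SPL room floor under an 80 dB SPL stimulus); ``None`` disables
    noise.  ``ear_height`` is the height of ears, source and (for
    calibration) the virtual head centre above the reflective surface.
    """

    condition: str = "land"  # land | interface | free_field
    reflection_coefficient: float = 1.0
    source_distance: float = 1.0
    elevation: float = 0.0
    ear_height: float = 0.03
    noise_level: float | None = -60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("land", "interface", "free_field"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.source_distance <= 0:
            raise ValueError("source_distance must be positive")
        if self.elevation != 0.0:
            raise ValueError("elevation is fixed at 0 deg")
        if self.condition != "free_field" and self.ear_height <= 0:
            raise ValueError("ear height above the surface must be positive")

    @property
    def reflective(self) -> bool:
        return self.condition in ("land", "interface")


@dataclass(frozen=True)
class GroundTruth:
    """Exact cues used by the simulator (the test oracle container)."""

    azimuths: np.ndarray
    itd_by_azimuth: np.ndarray          # seconds, external (Woodworth) ITD
    frequencies: np.ndarray             # Hz, analysis band grid
    hrtf_left: np.ndarray               # dB, (n_freq, n_az)
    hrtf_right: np.ndarray              # dB, (n_freq, n_az)
    canal_notches: list                 # per azimuth: ndarray of Hz (may be empty)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "azimuth_deg": self.azimuths,
            "itd_s": self.itd_by_azimuth,
            "notch_hz": [";".join(f"{f:.1f}" for f in n)
                         for n in self.canal_notches],
        })


@dataclass(frozen=True)
class SimulatedSession:
    """A complete synthetic session: recordings, calibrations and truth."""

    grid: SessionGrid
    recordings: list
    calibrations: list
    ground_truth: GroundTruth
    stimulus: StimulusSpec
    stimulus_signal: TimeSignal
    geometry: HeadGeometry
    scene: SceneConfig


# ---------------------------------------------------------------------------
# Stimulus synthesis
# ---------------------------------------------------------------------------

def make_stimulus(spec: StimulusSpec) -> TimeSignal:
    """Synthesize the emitted stimulus as a single-channel signal."""
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    if spec.kind == "log_sweep":
        x = chirp(t, f0=spec.f_start, t1=spec.duration, f1=spec.f_end,
                  method="logarithmic", phi=-90)
    elif spec.kind == "tone":
        x = np.sin(2 * np.pi * spec.tone_freq * t)
    else:  # pulse
        x = np.zeros(n)
        x[0] = 1.0
    return TimeSignal(x, spec.rate)


# ---------------------------------------------------------------------------
# Spherical-head response
# ---------------------------------------------------------------------------

def _incidence_angles(azimuth: float) -> tuple[float, float]:
    """Angle (rad) between the source direction and each ear's axis.

    Positive azimuth is toward the left ear (at +90 deg); the right ear sits
    at -90 deg.
    """
    theta = np.deg2rad(azimuth)
    return abs(theta - np.pi / 2), abs(theta + np.pi / 2)


def _woodworth_term(phi: float, radius: float, c: float) -> float:
    """Per-ear delay relative to the head centre for incidence angle phi."""
    if phi <= np.pi / 2:
        return -(radius / c) * np.cos(phi)      # straight path, ear side
    return (radius / c) * (phi - np.pi / 2)     # creeping arc, shadow side


def woodworth_ear_delays(geometry: HeadGeometry,
                         azimuth: float) -> tuple[float, float]:
    """(left, right) delays in seconds relative to the head centre."""
    a, c = geometry.effective_radius, geometry.speed_of_sound
    phi_l, phi_r = _incidence_angles(azimuth)
    return _woodworth_term(phi_l, a, c), _woodworth_term(phi_r, a, c)


def woodworth_itd(geometry: HeadGeometry, azimuth: float) -> float:
    """External interaural delay; positive when the left ear leads.

    Equals (a/c)(sin|az| + |az|_rad) in magnitude: (a/c)(1 + pi/2) at 90 deg.
    """
    dl, dr = woodworth_ear_delays(geometry, azimuth)
    return dr - dl


def external_path_difference(geometry: HeadGeometry, azimuth: float) -> float:
    """Extra external path length (m) to the far ear: c * |ITD(azimuth)|."""
    return geometry.speed_of_sound * abs(woodworth_itd(geometry, azimuth))


def _shadow_alpha(phi: float) -> float:
    # alpha in [0.1, 2]: high-shelf boost facing the source, cut in shadow
    return 1.05 + 0.95 * np.cos(phi)


def _shadow_gain(frequencies: np.ndarray, phi: float,
                 geometry: HeadGeometry) -> np.ndarray:
    """Zero-phase magnitude of the first-order spherical shadow filter.

    |H(f)| = sqrt((alpha^2 w^2 + beta^2) / (w^2 + beta^2)), beta = 2c/a.
    Unity at DC for every angle; tends to alpha at high frequency, so the
    ipsi-contra level difference grows monotonically with frequency.
    """
    alpha = _shadow_alpha(phi)
    beta = 2.0 * geometry.speed_of_sound / geometry.effective_radius
    w = 2 * np.pi * np.asarray(frequencies, dtype=float)
    return np.sqrt((alpha**2 * w**2 + beta**2) / (w**2 + beta**2))


def head_response(
    geometry: HeadGeometry, azimuth: float, frequencies: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Per-ear head filtering for a source at the given azimuth.

    Returns ``(gain_left, gain_right, (delay_left, delay_right))`` where the
    gains are real (zero-phase) magnitude responses sampled at
    ``frequencies`` and the delays are the Woodworth terms relative to the
    head centre (seconds).
    """
    if abs(azimuth) > 90:
        raise ValueError(f"azimuth {azimuth} outside the +/-90 deg grid")
    phi_l, phi_r = _incidence_angles(azimuth)
    freqs = np.asarray(frequencies, dtype=float)
    return (
        _shadow_gain(freqs, phi_l, geometry),
        _shadow_gain(freqs, phi_r, geometry),
        woodworth_ear_delays(geometry, azimuth),
    )


# ---------------------------------------------------------------------------
# Propagation paths (direct + image-source reflection)
# ---------------------------------------------------------------------------

class PropagationPath(NamedTuple):
    """One ray from source to receiver: arrival delay and linear amplitude."""

    delay: float       # seconds (propagation + Woodworth ear term)
    amplitude: float   # 1/r spreading times any reflection coefficient


def _horizontal_positions(scene: SceneConfig, geometry: HeadGeometry,
                          azimuth: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(source, left ear, right ear) horizontal (x, y) coordinates, metres.

    x points toward the left ear; the source lies at ``source_distance``
    from the head centre at the given azimuth.
    """
    theta = np.deg2rad(azimuth)
    r = scene.source_distance
    src = np.array([r * np.sin(theta), r * np.cos(theta)])
    a = geometry.effective_radius
    return src, np.array([a, 0.0]), np.array([-a, 0.0])


def direct_paths(scene: SceneConfig, geometry: HeadGeometry,
                 azimuth: float) -> tuple[list, list]:
    """Direct source-to-ear paths: ([left paths], [right paths])."""
    src, ear_l, ear_r = _horizontal_positions(scene, geometry, azimuth)
    d_l, d_r = woodworth_ear_delays(geometry, azimuth)
    c = geometry.speed_of_sound
    r0 = scene.source_distance
    out = []
    for ear, wterm in ((ear_l, d_l), (ear_r, d_r)):
        # source and ears share the same height: horizontal distance only
        r = float(np.linalg.norm(src - ear))
        out.append([PropagationPath(delay=r0 / c + wterm, amplitude=1.0 / r)])
    return out[0], out[1]


def apply_surface_reflection(
    paths: tuple[list, list], scene: SceneConfig, geometry: HeadGeometry,
    azimuth: float,
) -> tuple[list, list]:
    """Append the image-source reflection off the ground/water surface.

    For land/interface conditions each ear gains one extra path reflected in
    the horizontal surface (reflection coefficient +1 for a perfectly
    reflective boundary); free_field returns the input unchanged.
    """
    if not scene.reflective:
        return paths
    if scene.ear_height <= 0:
        raise ValueError("ear height above the surface must be positive")
    src, ear_l, ear_r = _horizontal_positions(scene, geometry, azimuth)
    d_l, d_r = woodworth_ear_delays(geometry, azimuth)
    c = geometry.speed_of_sound
    h = scene.ear_height
    left, right = list(paths[0]), list(paths[1])
    for plist, ear, wterm in ((left, ear_l, d_l), (right, ear_r, d_r)):
        horiz = float(np.linalg.norm(src - ear))
        r_ref = float(np.hypot(horiz, 2 * h))  # via the image source at -h
        # the reflection lags the direct arrival at the same ear by the
        # per-ear extra path; the interaural timing stays with the
        # Woodworth term carried by the direct path
        extra = r_ref - horiz
        plist.append(PropagationPath(
            delay=plist[0].delay + extra / c,
            amplitude=scene.reflection_coefficient / r_ref,
        ))
    return left, right


def _paths_to_spectrum(paths: list, frequencies: np.ndarray,
                       shadow: np.ndarray) -> np.ndarray:
    """Complex transfer of a path set: sum of delayed, scaled rays."""
    w = 2j * np.pi * np.asarray(frequencies, dtype=float)
    total = np.zeros(len(frequencies), dtype=complex)
    for p in paths:
        total += p.amplitude * np.exp(-w * p.delay)
    return total * shadow


def _canal_mix(x_left: np.ndarray, x_right: np.ndarray,
               frequencies: np.ndarray,
               geometry: HeadGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain interaural coupling of the two external spectra."""
    k = geometry.canal_transmission
    tau = geometry.canal_delta / geometry.speed_of_sound
    phase = np.exp(-2j * np.pi * np.asarray(frequencies, dtype=float) * tau)
    return x_left + k * phase * x_right, x_right + k * phase * x_left


def apply_canal_coupling(
    left: TimeSignal, right: TimeSignal, geometry: HeadGeometry
) -> tuple[TimeSignal, TimeSignal]:
    """Add the internal canal path to a pair of external ear signals.

    Each ear's output is its external signal plus the opposite ear's
    external signal delayed by ``canal_delta / c`` and scaled by the canal
    transmission coefficient.  With the canal blocked this is the identity.
    The delay is applied at sub-sample precision in the frequency domain.
    """
    if geometry.canal_state == "blocked":
        return left, right
    if left.rate != right.rate or left.n_samples != right.n_samples:
        raise ValueError("left/right signals must share rate and length")
    n = left.n_samples
    margin = int(np.ceil(geometry.canal_delta / geometry.speed_of_sound
                         * left.rate)) + 8
    nfft = next_fast_len(n + margin)
    freqs = rfftfreq(nfft, 1.0 / left.rate)
    xl = rfft(left.samples, nfft)
    xr = rfft(right.samples, nfft)
    yl, yr = _canal_mix(xl, xr, freqs, geometry)
    return (
        TimeSignal(irfft(yl, nfft)[:n + margin], left.rate),
        TimeSignal(irfft(yr, nfft)[:n + margin], right.rate),
    )


# ---------------------------------------------------------------------------
# Random smooth spectral colourations (equipment + microphone position)
# ---------------------------------------------------------------------------

def _smooth_colouration(frequencies: np.ndarray, rng: np.random.Generator,
                        spread_db: float, n_knots: int = 8) -> np.ndarray:
    """A smooth random magnitude response: spline-free log-f interpolation
    of Gaussian control points, zero phase."""
    f = np.asarray(frequencies, dtype=float)
    fmin = max(f[1] if f[0] == 0 else f[0], 1.0)
    knots = np.linspace(np.log(fmin), np.log(f[-1]), n_knots)
    levels_db = rng.normal(0.0, spread_db, size=n_knots)
    logf = np.log(np.maximum(f, fmin))
    return 10.0 ** (np.interp(logf, knots, levels_db) / 20.0)


# ---------------------------------------------------------------------------
# End-to-end session synthesis
# ---------------------------------------------------------------------------

ANALYSIS_BAND = (20.0, 10_000.0)


def _ear_transfer(scene: SceneConfig, geometry: HeadGeometry, azimuth: float,
                  frequencies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total azimuth-dependent complex transfer at each ear (incl. canal)."""
    gain_l, gain_r, _ = head_response(geometry, azimuth, frequencies)
    paths = direct_paths(scene, geometry, azimuth)
    paths = apply_surface_reflection(paths, scene, geometry, azimuth)
    x_l = _paths_to_spectrum(paths[0], frequencies, gain_l)
    x_r = _paths_to_spectrum(paths[1], frequencies, gain_r)
    if geometry.canal_state == "open":
        x_l, x_r = _canal_mix(x_l, x_r, frequencies, geometry)
    return x_l, x_r


def _centre_transfer(scene: SceneConfig, geometry: HeadGeometry,
                     frequencies: np.ndarray) -> np.ndarray:
    """Transfer from source to the virtual head centre (no head filtering)."""
    c = geometry.speed_of_sound
    r0 = scene.source_distance
    paths = [PropagationPath(delay=r0 / c, amplitude=1.0 / r0)]
    if scene.reflective:
        if scene.ear_height <= 0:
            raise ValueError("ear height above the surface must be positive")
        r_ref = float(np.hypot(r0, 2 * scene.ear_height))
        paths.append(PropagationPath(
            delay=r_ref / c,
            amplitude=scene.reflection_coefficient / r_ref))
    return _paths_to_spectrum(paths, frequencies, np.ones_like(frequencies))


def _canal_notches(geometry: HeadGeometry, azimuth: float,
                   band: tuple[float, float]) -> np.ndarray:
    """Destructive-interference frequencies at the ipsilateral ear."""
    from .canal import destructive_frequencies

    if geometry.canal_state != "open":
        return np.array([])
    delta = geometry.canal_delta + external_path_difference(geometry, azimuth)
    return destructive_frequencies(delta, geometry.speed_of_sound, band)


def simulate_session(
    grid: SessionGrid,
    geometry: HeadGeometry,
    scene: SceneConfig,
    stimulus: StimulusSpec | None = None,
    seed: int | None = None,
    n_calibrations: int = 10,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> SimulatedSession:
    """Simulate one full acquisition session on an azimuth grid.

    One binaural recording per azimuth, plus ``n_calibrations`` repetitions
    of the calibration recording made with both microphones at the virtual
    head centre (no head filtering, but with microphone colouration, the
    equipment response and any surface reflection).  Identical ``seed``
    yields bit-identical output.  The returned :class:`GroundTruth` carries
    the exact per-ear transfer maps, external ITDs and predicted canal
    notches used in the synthesis.
    """
    if grid.n_azimuths == 0:
        raise ValueError("empty azimuth grid")
    if stimulus is None:
        stimulus = StimulusSpec(rate=grid.rate)
    if stimulus.rate != grid.rate:
        raise ValueError("stimulus rate differs from session grid rate")
    if seed is None:
        seed = scene.seed if scene.seed is not None else 0
    rng = np.random.default_rng(seed)

    stim = make_stimulus(stimulus)
    n = stim.n_samples
    # margin covers propagation, reflection and canal delays at 1 m; output
    # length equals the FFT length so analysis reuses the same frequency grid
    nfft = next_fast_len(n + 4096)
    freqs = rfftfreq(nfft, 1.0 / grid.rate)
    spectrum = rfft(stim.samples, nfft)

    equipment = _smooth_colouration(freqs, rng, spread_db=2.0)
    mic_left = _smooth_colouration(freqs, rng, spread_db=3.0)
    mic_right = _smooth_colouration(freqs, rng, spread_db=3.0)

    stim_rms = stim.rms()
    noise_sd = (0.0 if scene.noise_level is None
                else stim_rms * 10.0 ** (scene.noise_level / 20.0))

    n_out = nfft
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    truth_l = np.empty((int(band_mask.sum()), grid.n_azimuths))
    truth_r = np.empty_like(truth_l)

    def _record(x_l: np.ndarray, x_r: np.ndarray, azimuth: float,
                ) -> BinauralRecording:
        yl = irfft(spectrum * equipment * mic_left * x_l, nfft)[:n_out]
        yr = irfft(spectrum * equipment * mic_right * x_r, nfft)[:n_out]
        if noise_sd > 0:
            yl = yl + rng.normal(0.0, noise_sd, n_out)
            yr = yr + rng.normal(0.0, noise_sd, n_out)
        return BinauralRecording(
            left=TimeSignal(yl, grid.rate),
            right=TimeSignal(yr, grid.rate),
            azimuth=azimuth, condition=scene.condition, stimulus=stimulus,
        )

    recordings = []
    floor = 1e-12
    for j, az in enumerate(grid.azimuths):
        x_l, x_r = _ear_transfer(scene, geometry, az, freqs)
        recordings.append(_record(x_l, x_r, float(az)))
        truth_l[:, j] = 20 * np.log10(np.maximum(np.abs(x_l[band_mask]), floor))
        truth_r[:, j] = 20 * np.log10(np.maximum(np.abs(x_r[band_mask]), floor))

    x_c = _centre_transfer(scene, geometry, freqs)
    calibrations = [_record(x_c, x_c, float("nan"))
                    for _ in range(n_calibrations)]

    truth = GroundTruth(
        azimuths=grid.azimuths.copy(),
        itd_by_azimuth=np.array([woodworth_itd(geometry, az)
                                 for az in grid.azimuths]),
        frequencies=freqs[band_mask].copy(),
        hrtf_left=truth_l,
        hrtf_right=truth_r,
        canal_notches=[_canal_notches(geometry, az, band)
                       for az in grid.azimuths],
    )
    return SimulatedSession(
        grid=grid, recordings=recordings, calibrations=calibrations,
        ground_truth=truth, stimulus=stimulus, stimulus_signal=stim,
        geometry=geometry, scene=scene,
    )
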