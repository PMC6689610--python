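"""End-to-end orchestration: simulate -> preprocess -> HRTF -> cues -> PLL.

`analyze_session` runs the acquisition-side processing chain on a recorded
(or simulated) session: synchronization against the emitted stimulus, Hann
onset/offset ramps, RMS normalization by the normal-incidence recording,
spectrum estimation on a shared grid, calibration averaging, per-ear HRTF
maps, ear symmetrization and optional smoothing.  `run_pipeline` drives a
complete synthetic study (HRTF maps, ILD, ITD with the canal open and
blocked, PLL curves and slopes, canal-interference prediction) and writes a
checksummed manifest; `make_fixtures` emits small deterministic sessions
for tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .canal import predict_crescent
from .cues import STANDARD_TONE_FREQS, compute_ild, itd_curve
from .hrtf import (SpectrumEstimate, TransferMap, average_calibration,
                   compute_hrtf, estimate_spectrum, smooth_map, symmetrize)
from .pll import compute_pll, fit_slope
from .signals import (BinauralRecording, SessionGrid, apply_ramps,
                      default_azimuths, rms_normalize, synchronize)
from .simulate import (ANALYSIS_BAND, HeadGeometry, SceneConfig,
                       SimulatedSession, StimulusSpec, preset_geometry,
                       simulate_session)

__all__ = [
    "SessionMaps",
    "RunConfig",
    "analyze_session",
    "itd_study",
    "run_pipeline",
    "make_fixtures",
]


@dataclass(frozen=True)
class SessionMaps:
    """HRTF maps estimated from one session."""

    left: TransferMap
    right: TransferMap
    symmetric: TransferMap


def analyze_session(
    grid: SessionGrid,
    recordings: list,
    calibrations: list,
    reference=None,
    band: tuple[float, float] = ANALYSIS_BAND,
    ramp_points: int = 501,
    smooth: bool = False,
    normalize_before_ramps: bool = False,
) -> SessionMaps:
    """Estimate per-ear and symmetrized HRTF maps from a session.

    Processing order: synchronize (when the emitted stimulus is supplied),
    ramp, RMS-normalize, then single-FFT spectra on a grid shared by every
    recording and calibration in the session.  The ramp/normalize order is
    configurable (both are per-channel scalings as far as the HRTF ratio is
    concerned, so the estimate is unaffected either way).
    """
    if reference is not None:
        recordings = [synchronize(reference, rec) for rec in recordings]

    def _ramped(recs):
        return [
            dataclasses.replace(rec,
                                left=apply_ramps(rec.left, ramp_points),
                                right=apply_ramps(rec.right, ramp_points))
            for rec in recs
        ]

    if normalize_before_ramps:
        recordings = _ramped(rms_normalize(recordings, grid))
    else:
        recordings = rms_normalize(_ramped(recordings), grid)

    nfft = recordings[0].left.n_samples
    spec_kw = dict(band=band, nfft=nfft)
    left_spec = [estimate_spectrum(r.left, **spec_kw) for r in recordings]
    right_spec = [estimate_spectrum(r.right, **spec_kw) for r in recordings]
    cal_left = average_calibration(
        [estimate_spectrum(apply_ramps(c.left, ramp_points), **spec_kw)
         for c in calibrations])
    cal_right = average_calibration(
        [estimate_spectrum(apply_ramps(c.right, ramp_points), **spec_kw)
         for c in calibrations])

    meta = {"condition": recordings[0].condition}
    left = compute_hrtf(left_spec, grid.azimuths, cal_left,
                        metadata={**meta, "ear": "left"})
    right = compute_hrtf(right_spec, grid.azimuths, cal_right,
                         metadata={**meta, "ear": "right"})
    sym = symmetrize(left, right)
    if smooth:
        left, right, sym = (smooth_map(m) for m in (left, right, sym))
    return SessionMaps(left=left, right=right, symmetric=sym)


def itd_study(
    grid: SessionGrid,
    geometry: HeadGeometry,
    scene: SceneConfig,
    seed: int,
    tone_freqs=STANDARD_TONE_FREQS,
) -> list:
    """ITD curves for a pulse and pure tones, with the canal open and blocked.

    Mirrors the skull experiment: the same scene is simulated twice per
    stimulus, differing only in the canal state; each curve is normalized
    to its 0 deg value.  The pulse estimate seeds the tone lag search.
    """
    curves = []
    bound = geometry.interaural_distance * 3 / geometry.speed_of_sound
    for state in ("blocked", "open"):
        geo = dataclasses.replace(geometry, canal_state=state)
        pulse = simulate_session(
            grid, geo, scene, StimulusSpec.pulse(rate=grid.rate),
            seed=seed, n_calibrations=0)
        pulse_curve = itd_curve(pulse.recordings, grid, stimulus="pulse",
                                canal_state=state, max_lag=2 * bound)
        curves.append(pulse_curve)
        for f in tone_freqs:
            tones = simulate_session(
                grid, geo, scene, StimulusSpec.tone(f, rate=grid.rate),
                seed=seed, n_calibrations=0)
            curves.append(itd_curve(
                tones.recordings, grid, tone_freq=f, canal_state=state,
                max_itd_bound=bound, seed_curve=pulse_curve))
    return curves


# ---------------------------------------------------------------------------
# Full synthetic study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic run."""

    out_dir: Path
    geometry: HeadGeometry = field(default_factory=HeadGeometry)
    condition: str = "land"
    seed: int = 0
    sweep_duration: float = 5.0
    rate: float = 44_100.0
    azimuth_step: float = 5.0
    noise_level: float | None = -60.0
    band: tuple[float, float] = ANALYSIS_BAND
    smooth: bool = False
    tone_freqs: tuple = STANDARD_TONE_FREQS
    fit_band: tuple[float, float] = (200.0, 10_000.0)
    write_audio: bool = False

    def __post_init__(self) -> None:
        if self.condition not in ("land", "interface", "free_field"):
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))

    def grid(self) -> SessionGrid:
        return SessionGrid(azimuths=default_azimuths(step=self.azimuth_step),
                           rate=self.rate)

    def scene(self) -> SceneConfig:
        return SceneConfig(condition=self.condition,
                           noise_level=self.noise_level, seed=self.seed)

    def config_hash(self) -> str:
        params = {k: str(v) for k, v in dataclasses.asdict(self).items()
                  if k != "out_dir"}  # identical science, any output path
        blob = json.dumps(params, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study and write every artifact plus a manifest.

    Artifacts: per-ear and symmetrized HRTF CSV maps, ILD map, ITD curves
    (pulse + tones, canal open and blocked), PLL curves for HRTF and ILD
    with dB/octave slope fits, and the canal-interference prediction.  The
    manifest records the package version, seed, config hash and a sha256
    checksum per file, so an identical configuration reproduces identical
    checksums.  All results are computed before anything is written.
    """
    grid = config.grid()
    scene = config.scene()
    stimulus = StimulusSpec(duration=config.sweep_duration, rate=config.rate)
    session = simulate_session(grid, config.geometry, scene, stimulus,
                               seed=config.seed)
    maps = analyze_session(grid, session.recordings, session.calibrations,
                           reference=session.stimulus_signal,
                           band=config.band, smooth=config.smooth)
    ild = compute_ild(maps.symmetric)
    pll_h = compute_pll(maps.symmetric)
    pll_ild = compute_pll(ild)
    slopes = {}
    for name, curve in (("hrtf", pll_h), ("ild", pll_ild)):
        try:
            slopes[name] = fit_slope(curve, band=config.fit_band).to_dict()
        except ValueError as exc:  # too few finite points: report, don't fail
            slopes[name] = {"error": str(exc)}
    crescent = predict_crescent(config.geometry, grid)
    curves = itd_study(grid, config.geometry, scene, seed=config.seed,
                       tone_freqs=config.tone_freqs)

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _put(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    _put(out / "hrtf_left.csv", maps.left.to_csv)
    _put(out / "hrtf_right.csv", maps.right.to_csv)
    _put(out / "hrtf_symmetric.csv", maps.symmetric.to_csv)
    _put(out / "ild.csv", ild.to_csv)
    _put(out / "pll_hrtf.csv", pll_h.to_csv)
    _put(out / "pll_ild.csv", pll_ild.to_csv)
    _put(out / "canal_prediction.csv", crescent.to_csv)
    itd_frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    _put(out / "itd_curves.csv", lambda p: itd_frame.to_csv(p, index=False))
    _put(out / "ground_truth.csv",
         lambda p: session.ground_truth.to_frame().to_csv(p, index=False))
    if config.write_audio:
        from .signals import write_session
        write_session(out / "session", grid, session.recordings,
                      session.calibrations)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "condition": config.condition,
        "n_azimuths": grid.n_azimuths,
        "slopes": slopes,
        "files": {p.name: _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_fixtures(out_dir: Path, scale: str = "tiny", seed: int = 0) -> Path:
    """Write a deterministic synthetic session to disk for tests.

    ``tiny``: 7 azimuths (30 deg steps) and a 0.5 s sweep, fast enough for
    unit tests; ``full``: the canonical 37-azimuth grid with the 5 s sweep.
    """
    if scale == "tiny":
        grid = SessionGrid(azimuths=default_azimuths(step=30.0))
        stimulus = StimulusSpec(duration=0.5)
        n_cal = 3
    elif scale == "full":
        grid = SessionGrid()
        stimulus = StimulusSpec()
        n_cal = 10
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    geometry = preset_geometry("crocodile")
    scene = SceneConfig(condition="land", noise_level=-60.0, seed=seed)
    session = simulate_session(grid, geometry, scene, stimulus, seed=seed,
                               n_calibrations=n_cal)
    from .signals import write_session
    out = Path(out_dir)
    write_session(out, grid, session.recordings, session.calibrations,
                  metadata={"scale": scale, "seed": seed,
                            "version": __version__},
                  ground_truth=session.ground_truth.to_frame())
    return out
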