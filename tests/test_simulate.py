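"""Forward-model contracts: stimuli, head response, reflection, canal, sessions."""

import dataclasses

import numpy as np
import pytest

import hrtfcues as hc
from hrtfcues.signals import TimeSignal
from hrtfcues.simulate import (PropagationPath, _paths_to_spectrum,
                               apply_surface_reflection, direct_paths,
                               woodworth_ear_delays)


class TestStimuli:
    def test_log_sweep_length_and_edge_frequencies(self):
        spec = hc.StimulusSpec()
        sig = hc.make_stimulus(spec)
        assert sig.n_samples == 220_500
        # instantaneous frequency from the analytic phase of a log sweep:
        # f(t) = f0 * (f1/f0)**(t/T); check via zero-crossing spacing near
        # the ends of the sweep
        from scipy.signal import hilbert
        phase = np.unwrap(np.angle(hilbert(sig.samples)))
        inst_f = np.gradient(phase) * sig.rate / (2 * np.pi)
        t = np.arange(sig.n_samples) / sig.rate
        for t_probe in (0.5, 1.5, 2.5, 3.5, 4.5):  # away from Hilbert edges
            i = int(t_probe * sig.rate)
            expected = 20.0 * (10_000.0 / 20.0) ** (t[i] / 5.0)
            assert inst_f[i] == pytest.approx(expected, rel=0.01)
        # whole-sweep check covering both edges: total cycles equal the
        # integral of f(t) = 20 * 500**(t/5) over the 5 s sweep
        crossings = np.count_nonzero(np.diff(np.signbit(sig.samples)))
        total_cycles = (10_000.0 - 20.0) * 5.0 / np.log(500.0)
        assert crossings == pytest.approx(2 * total_cycles, abs=3)

    def test_tone_has_exact_cycle_count(self):
        sig = hc.make_stimulus(hc.StimulusSpec.tone(1000.0))
        assert sig.n_samples == 22_050
        zc = np.nonzero(np.diff(np.signbit(sig.samples)))[0]
        assert zc.size in (999, 1000)  # 500 cycles = ~1000 zero crossings

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="f_start < f_end"):
            hc.StimulusSpec(f_start=1000.0, f_end=1000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            hc.StimulusSpec(f_end=30_000.0)
        with pytest.raises(ValueError, match="duration"):
            hc.StimulusSpec(duration=0.0)
        with pytest.raises(ValueError, match="tone_freq"):
            hc.StimulusSpec(kind="tone")


class TestHeadResponse:
    def test_zero_azimuth_is_symmetric(self):
        geo = hc.HeadGeometry()
        freqs = np.linspace(100, 10_000, 64)
        gl, gr, (dl, dr) = hc.head_response(geo, 0.0, freqs)
        np.testing.assert_allclose(gl, gr)
        assert dl == dr

    def test_woodworth_delay_at_90_degrees(self):
        # (a/c)(1 + pi/2) for a = 0.0235 m, c = 343 m/s: about 176 us.
        geo = hc.HeadGeometry(interaural_distance=0.047, speed_of_sound=343.0)
        itd = hc.woodworth_itd(geo, 90.0)
        assert itd * 1e6 == pytest.approx(176.1, abs=0.2)
        # brute-force oracle: shortest path around a sphere of radius a
        a, c, r = 0.0235, 343.0, 1.0
        src = np.array([r, 0.0])  # at +90 deg (toward left ear at [a, 0])
        near = np.linalg.norm(src - [a, 0.0])
        # far ear: straight to the tangent point plus arc to [-a, 0]
        tangent = np.sqrt(r**2 - a**2)
        arc = a * (np.pi / 2 + np.arcsin(a / r))
        brute = ((tangent + arc) - near) / c
        assert itd == pytest.approx(brute, rel=0.02)

    def test_mirror_symmetry_of_gains(self):
        geo = hc.HeadGeometry()
        freqs = np.linspace(100, 10_000, 32)
        gl_p, gr_p, (dl_p, dr_p) = hc.head_response(geo, 40.0, freqs)
        gl_m, gr_m, (dl_m, dr_m) = hc.head_response(geo, -40.0, freqs)
        np.testing.assert_allclose(gl_p, gr_m)
        np.testing.assert_allclose(gr_p, gl_m)
        assert dl_p == dr_m and dr_p == dl_m

    @pytest.mark.parametrize("azimuth", [5.0, 30.0, 60.0, 90.0])
    def test_ipsi_gain_dominates_and_ild_grows_with_frequency(self, azimuth):
        geo = hc.HeadGeometry()
        freqs = np.logspace(np.log10(50), 4, 200)
        gl, gr, _ = hc.head_response(geo, azimuth, freqs)
        assert np.all(gl >= gr)
        ild = 20 * np.log10(gl / gr)
        assert np.all(np.diff(ild) >= -1e-12)

    def test_itd_antisymmetry_over_grid(self):
        geo = hc.HeadGeometry(interaural_distance=0.03)
        for az in np.arange(0, 95, 5):
            assert hc.woodworth_itd(geo, az) == pytest.approx(
                -hc.woodworth_itd(geo, -az), abs=1e-15)
        assert hc.woodworth_itd(geo, 0.0) == 0.0

    def test_azimuth_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="azimuth"):
            hc.head_response(hc.HeadGeometry(), 120.0, [1000.0])


class TestSurfaceReflection:
    def test_free_field_is_identity(self):
        geo = hc.HeadGeometry()
        scene = hc.SceneConfig(condition="free_field")
        paths = direct_paths(scene, geo, 30.0)
        assert apply_surface_reflection(paths, scene, geo, 30.0) is paths

    def test_vanishing_ear_height_doubles_pressure(self):
        geo = hc.HeadGeometry()
        scene = hc.SceneConfig(condition="land", ear_height=1e-9)
        paths = apply_surface_reflection(direct_paths(scene, geo, 0.0),
                                         scene, geo, 0.0)
        freqs = np.linspace(100, 10_000, 50)
        ones = np.ones_like(freqs)
        direct = _paths_to_spectrum(direct_paths(scene, geo, 0.0)[0], freqs, ones)
        total = _paths_to_spectrum(paths[0], freqs, ones)
        gain_db = 20 * np.log10(np.abs(total) / np.abs(direct))
        np.testing.assert_allclose(gain_db, 6.02, atol=0.01)

    def test_comb_notches_match_two_ray_time_domain_oracle(self):
        # ear height chosen so several comb notches fall in the audio band
        geo = hc.HeadGeometry()
        scene = hc.SceneConfig(condition="land", ear_height=0.2)
        paths = apply_surface_reflection(direct_paths(scene, geo, 0.0),
                                         scene, geo, 0.0)
        (p_direct, p_ref) = paths[0]
        # time-domain oracle: delay-and-sum two impulses at high rate
        rate = 2_000_000.0
        n = int(rate * 0.02)
        x = np.zeros(n)
        x[int(round(p_direct.delay * rate))] = p_direct.amplitude
        x[int(round(p_ref.delay * rate))] += p_ref.amplitude
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(n, 1 / rate)
        band = (freqs > 1000) & (freqs < 20_000)
        from scipy.signal import argrelmin
        oracle_notches = freqs[band][argrelmin(spec[band])[0]]
        assert oracle_notches.size >= 3
        # analytic notches: odd multiples of 1/(2 * delay difference),
        # resolved by the oracle only to its FFT bin spacing
        dt = p_ref.delay - p_direct.delay
        predicted = (2 * np.arange(len(oracle_notches)) + 1) / (2 * dt)
        np.testing.assert_allclose(oracle_notches, predicted,
                                   atol=freqs[1] - freqs[0])

    def test_non_positive_ear_height_rejected(self):
        with pytest.raises(ValueError, match="ear height|positive"):
            hc.SceneConfig(condition="land", ear_height=0.0)

    def test_surface_energy_consistency(self, tiny_grid):
        """Free-field RMS <= surface RMS <= free-field RMS + 6.02 dB."""
        geo = hc.preset_geometry("crocodile", canal_state="blocked")
        stim = hc.StimulusSpec(duration=0.5)
        kw = dict(seed=5, n_calibrations=0)
        ff = hc.simulate_session(
            tiny_grid, geo, hc.SceneConfig(condition="free_field",
                                           noise_level=None), stim, **kw)
        land = hc.simulate_session(
            tiny_grid, geo, hc.SceneConfig(condition="land",
                                           noise_level=None), stim, **kw)
        for rff, rla in zip(ff.recordings, land.recordings):
            for ch in ("left", "right"):
                r0 = getattr(rff, ch).rms()
                r1 = getattr(rla, ch).rms()
                assert r0 * (1 - 1e-9) <= r1 <= 2.0 * r0 * (1 + 1e-9)


class TestCanalCoupling:
    def test_blocked_canal_is_identity(self, rng):
        geo = hc.HeadGeometry(canal_state="blocked")
        left = TimeSignal(rng.normal(size=1000), 44100.0)
        right = TimeSignal(rng.normal(size=1000), 44100.0)
        out_l, out_r = hc.apply_canal_coupling(left, right, geo)
        assert out_l is left and out_r is right

    def test_full_cancellation_at_antiphase_frequency(self):
        # equal-amplitude two-path sum vanishes where the phase lag is pi
        geo = hc.HeadGeometry(canal_delta=0.0343, canal_transmission=1.0)
        f_ic = geo.speed_of_sound / (2 * geo.canal_delta)  # 5000 Hz
        rate = 44100.0
        t = np.arange(int(rate * 0.2)) / rate
        tone = np.sin(2 * np.pi * f_ic * t)
        out_l, _ = hc.apply_canal_coupling(
            TimeSignal(tone, rate), TimeSignal(tone, rate), geo)
        # steady state away from edges; the residual floor is onset-edge
        # ringing of the fractional-delay interpolation, far below -80 dB
        mid = out_l.samples[2000:6000]
        assert np.max(np.abs(mid)) < 1e-4 * np.max(np.abs(tone))

    def test_magnitude_minima_match_brute_force_scan(self):
        # |1 + 0.5 exp(-i 2 pi f delta / c)| minimized at 3430, 10290 Hz
        geo = hc.HeadGeometry(canal_delta=0.05, canal_transmission=0.5)
        freqs = np.linspace(20, 12_000, 600_000)
        mag = np.abs(1 + 0.5 * np.exp(
            -2j * np.pi * freqs * geo.canal_delta / geo.speed_of_sound))
        from scipy.signal import argrelmin
        scan = freqs[argrelmin(mag)[0]]
        np.testing.assert_allclose(scan, [3430.0, 10_290.0], atol=0.05)
        np.testing.assert_allclose(
            hc.destructive_frequencies(0.05, 343.0, (20, 12_000)),
            scan, atol=0.05)

    def test_bad_transmission_rejected(self):
        with pytest.raises(ValueError, match="transmission"):
            hc.HeadGeometry(canal_transmission=0.0)
        with pytest.raises(ValueError, match="transmission"):
            hc.HeadGeometry(canal_transmission=1.5)


class TestSimulateSession:
    def test_default_grid_yields_37_recordings_plus_calibration(self, tiny_grid):
        # tiny grid here: 7 recordings; canonical grid checked via n_azimuths
        assert hc.SessionGrid().n_azimuths == 37
        geo = hc.preset_geometry("caiman")
        sess = hc.simulate_session(
            tiny_grid, geo, hc.SceneConfig(seed=0),
            hc.StimulusSpec(duration=0.25), seed=0, n_calibrations=10)
        assert len(sess.recordings) == tiny_grid.n_azimuths
        assert len(sess.calibrations) == 10

    def test_delay_only_head_gives_pure_interaural_delay(self, tiny_grid):
        """No noise, canal blocked, free field: channels differ by the
        ground-truth ITD only (up to the head-shadow colouring)."""
        geo = hc.preset_geometry("skull_small", canal_state="blocked")
        scene = hc.SceneConfig(condition="free_field", noise_level=None)
        sess = hc.simulate_session(tiny_grid, geo, scene,
                                   hc.StimulusSpec.pulse(), seed=3,
                                   n_calibrations=0)
        for rec, itd in zip(sess.recordings, sess.ground_truth.itd_by_azimuth):
            tau = hc.compute_itd(rec, max_lag=0.002)
            assert abs(tau - itd) < 0.5 / tiny_grid.rate

    def test_same_seed_is_bit_identical(self, tiny_grid):
        geo = hc.preset_geometry("crocodile")
        scene = hc.SceneConfig(condition="land", noise_level=-40.0)
        kw = dict(seed=7, n_calibrations=2)
        a = hc.simulate_session(tiny_grid, geo, scene,
                                hc.StimulusSpec(duration=0.25), **kw)
        b = hc.simulate_session(tiny_grid, geo, scene,
                                hc.StimulusSpec(duration=0.25), **kw)
        for ra, rb in zip(a.recordings + a.calibrations,
                          b.recordings + b.calibrations):
            np.testing.assert_array_equal(ra.left.samples, rb.left.samples)
            np.testing.assert_array_equal(ra.right.samples, rb.right.samples)

    def test_ground_truth_itd_antisymmetric(self, tiny_session):
        itd = tiny_session.ground_truth.itd_by_azimuth
        np.testing.assert_allclose(itd, -itd[::-1], atol=1e-15)
        i0 = tiny_session.grid.index_of(0.0)
        assert itd[i0] == 0.0

    def test_notch_list_empty_when_canal_blocked(self, tiny_session):
        assert all(len(n) == 0
                   for n in tiny_session.ground_truth.canal_notches)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            hc.SessionGrid(azimuths=np.array([]))
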