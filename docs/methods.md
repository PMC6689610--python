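# Methods

This note documents the models, numerical choices and limitations behind
`hrtfcues`, in the package's own terms.

## Measurement model and estimation

A session consists of one binaural recording per azimuth θ on a symmetric
grid (canonically −90°…+90° in 5° steps, N_θ = 37; source at 1 m, 0°
elevation) plus calibration recordings made with both microphones at the
virtual head centre.  The in-ear spectrum is modelled multiplicatively,

    R(f, θ, x) = S(f) · H(f, θ) · μ(f, x),

with S the calibration spectrum and μ the microphone-position colouration.
The estimator uses the session average to identify μ:

    μ(f, x) = (1 / (S(f) N)) Σ_i R_i(f, θ_i, x),
    H(f, θ) = R(f, θ, x) / (S(f) · μ(f, x))  =  R(f, θ) · N / Σ_i R_i(f).

Two consequences are load-bearing and tested:

* any fixed filter multiplying every recording of one ear cancels exactly
  (machine precision), so microphone placement and equipment response
  cannot bias the maps;
* the linear-domain azimuth mean of each estimated per-ear map is exactly
  1 at every frequency.  Estimated maps are therefore identified only up
  to an azimuth-independent factor; every comparison with ground truth
  first removes the azimuth mean on both sides (`remove_azimuth_mean`),
  and the PLL statistic is insensitive to this ambiguity by construction
  (only ∂/∂θ enters).

Pre-processing before spectrum estimation follows the acquisition
protocol: synchronization to the emitted stimulus by the cross-correlation
peak (a common integer shift of both channels, so the interaural lag is
untouched), Hann onset/offset ramps of 501 samples per end (interpreted as
the rising/falling half of a 1001-point Hann window; the ramp/normalize
order is ramp-first and configurable), and RMS normalization of each
channel by the 0° recording of the same ear.  RMS normalization is a
per-ear scalar and provably cannot affect H (it cancels in R·N/ΣR); it is
kept because it fixes the numeric scale of serialized signals.

Spectra are single FFTs of the whole synchronized recording (maximal
resolution for sweep inputs, ~0.2 Hz bins for the 5 s sweep); Welch
averaging is available for noisy non-sweep inputs.  All recordings of a
session share one FFT length and hence one frequency grid, cropped to the
20 Hz–10 kHz analysis band.  Magnitudes are floored at 1e-12 before
taking logs.

Ear symmetrization averages left(f, θ) with right(f, −θ) in the dB domain
(a geometric mean in linear units, consistent with all maps being handled
in dB; linear averaging would differ only at second order in the
left/right mismatch).

## Smoothing

Maps are smoothed with a separable Gaussian whose azimuth kernel is 5 grid
points wide and whose frequency kernel width follows the power law
`w(f) = 3 · (f/20)^β` Hz with β = log(1000/3)/log(500), anchored at
3 Hz @ 20 Hz and 1 kHz @ 10 kHz.  "Width" is interpreted as the kernel's
full width at half maximum.  Kernels are truncated at 3σ and renormalized
to unit sum at every location, so a constant map is exactly invariant,
including at grid edges, and smoothing can never expand a map's value
range.  Because the frequency width varies with f, the adjoint property
(column sums of the weight matrix equal 1, i.e. exact mass conservation of
a spike) holds only approximately — to ~0.1 % at mid-band — while the
row-sum property (the one "normalized in amplitude" requires) is exact.
Double smoothing is refused via a flag on the map.

## Forward model (synthetic sessions)

The simulator exists because the original animal/skull recordings are not
public; it generates sessions with *exact* ground truth so every analysis
stage can be tested by parameter recovery.  Its components:

* **Stimuli** — logarithmic sweep (default 20 Hz–10 kHz, 5 s, 44.1 kHz;
  unit amplitude, the nominal 80 dB SPL level is metadata), 500 ms pure
  tones, and a one-sample unit impulse (band-limited only by sampling, so
  broadband delay estimates are well defined).
* **Interaural delay** — Woodworth spherical-head delays per ear: straight
  path `-(a/c)·cos φ` on the facing side, creeping arc `(a/c)(φ − π/2)` in
  the shadow (φ = angle between source direction and the ear axis,
  a = effective radius = interaural distance / 2, c = 343 m/s default,
  configurable).  ITD(90°) = (a/c)(1 + π/2) ≈ 176 µs for a = 2.35 cm.
* **Head shadow** — the magnitude response of a first-order
  one-pole/one-zero shadow filter, `|H| = sqrt((α²ω² + β²)/(ω² + β²))`
  with β = 2c/a and α(φ) = 1.05 + 0.95·cos φ ∈ [0.1, 2]: unity at DC, a
  high-shelf boost facing the source and a cut in shadow, so the
  ipsi−contra level difference is ≥ 0 and grows monotonically with
  frequency.  The filter is applied **zero-phase**: all interaural delay
  is carried explicitly by the Woodworth term, which keeps the simulator's
  ITD ground truth exact rather than entangled with the shadow filter's
  group delay.  This is a deliberate design choice of the forward model,
  not an approximation error.
* **Surface reflection** — land and interface conditions add one
  image-source path per ear, reflection coefficient +1 (perfectly
  reflective ground/water).  The reflection lags the direct arrival at the
  same ear by the per-ear extra geometric path (so it can never lead it),
  with 1/r amplitude; the reflected ray reuses the direct ray's shadow
  gain and Woodworth term (the elevation dependence of the shadow is out
  of scope).  Ear/source/centre height above the surface defaults to
  0.03 m (plausible for a basking or cruising animal) and is configurable.
* **Interaural canal** — with the canal open, each ear receives the
  opposite ear's external signal delayed by `canal_delta / c` and scaled
  by a transmission coefficient in (0, 1] (default 0.5; 1.0 is reserved
  for analytic full-cancellation checks).  `canal_delta` (the internal
  path length) defaults to the interaural distance.  The total path
  difference at an ear adds the external interaural path, which is how the
  predicted notch frequency falls with |θ| (the "crescent").  δ(θ) is a
  pluggable function in the prediction module; the default (constant canal
  length + Woodworth external difference) is a declared stand-in, since
  the real skull geometry behind such predictions is never published.
* **Colourations and noise** — the equipment response and per-ear
  microphone colourations are smooth random log-magnitude curves
  (Gaussian control points interpolated in log-frequency, zero phase,
  2–3 dB spread); measurement noise is white Gaussian at a configurable
  level relative to the stimulus RMS (default −60 dB, matching a ~20 dB
  SPL room floor under an 80 dB SPL stimulus).  Everything is driven by
  one seed; identical seeds give bit-identical sessions.
* **Calibration** — simulated with both microphones at the head centre:
  no head filtering or canal, but with the equipment response, each ear's
  microphone colouration and the surface reflection; 10 repetitions with
  independent noise are averaged, as in the acquisition protocol.

Geometry presets: crocodile (4.7 cm interaural), caiman (3.9 cm), and
three skulls — the juvenile skull's 2.4 cm interaural distance is the only
one stated for a skull, so the medium and large skulls scale it by head
length (16.5/6.9 and 22.7/6.9).  The canal open/blocked ITD comparison is
run on the small-skull geometry for that reason.

### What the simulator does and does not emulate

It reproduces the *structure* of real sessions: interaural delays and
frequency-growing shadowing, surface-reflection comb filtering,
canal-interference notches that move with azimuth and head size, an
ITD-shortening open canal, nuisance colourations, noise, and the full
acquisition protocol.  It does **not** model pinna-less ear-lid acoustics,
eardrum directionality or middle-ear mechanics, diffraction beyond the
first-order shadow, elevation, or underwater propagation.  Passing
parameter-recovery tests therefore demonstrates the correctness of the
estimation pipeline under the stated model, not the fidelity of the model
to any particular animal; measured PLL magnitudes and slopes from real
animals are not reproduced (those recordings are not available), only the
kind of output and its qualitative behaviour.

## Binaural cue extraction

ITD is the argmax of the unnormalized cross-correlation (the argmax is
scale-invariant), refined by a three-point parabolic fit — at 44.1 kHz a
sample is 22.7 µs, too coarse for canal effects of a few tens of µs.  The
sign convention is declared, not inherited: positive τ means the left ear
(ipsilateral for θ > 0) leads.  Curves are normalized to their 0° value.
For tones, the lag window is ± half a period, centred on the broadband
(pulse) estimate when available; a tone whose half period is below the
physical ITD bound (3 · interaural distance / c, generous) is rejected as
cycle-ambiguous.  On simulated sessions the pulse curve recovers the
ground-truth ITD within half a sample at every azimuth, and opening the
canal shortens the 90° ITD by an offset constant across 125–1000 Hz tones
to within a few µs (~58 µs for the small-skull geometry).

ILD is computed on the θ ≥ 0 half-grid from a symmetric map; ILD(f, 0) is
identically zero.

## PLL and slope fitting

The azimuthal derivative uses central differences on the grid (one-sided
at the ends), with θ in degrees — radians would shift every PLL value by
20·log10(180/π) ≈ 35 dB, so the unit matters and is fixed here.  Whether
the cue map enters in dB or linear units is an interpretation choice; dB
is used, consistent with maps being handled in dB throughout.  A map
constant in azimuth has mean |derivative| 0; its PLL is an explicit
undefined marker (−inf internally, "undefined" in CSV), never a fabricated
number.  The dB/octave slope is ordinary least squares of PLL against
log2 f over a configurable band (default 200 Hz–10 kHz); on a linear FFT
grid, points are weighted by their local log2-spacing so each octave
contributes equally (uniform weighting is available).

## Numerical and interface choices

* WAV I/O is 32-bit float (bit-exact round trips in tests); 16-bit integer
  WAVs are read and scaled.  Session directories carry a YAML descriptor
  and an optional ground-truth CSV; readers fail naming the missing or
  inconsistent file.
* Synchronization is integer-lag (FFT cross-correlation); sub-sample
  alignment is deferred to ITD estimation, the only place it matters.
* The simulator's FFT length is `next_fast_len(n + 4096)`, and recordings
  are emitted at that full length, so analysis reuses the identical
  frequency grid and ground-truth maps align bin-for-bin with estimates.
* `run_pipeline` computes every artifact before writing any, embeds
  version/seed/config-hash in the manifest, and checksums each file; the
  config hash excludes the output path.
* Test problem sizes: most tests run on a 7-azimuth, 0.5 s-sweep session
  (the `tiny` fixture scale, recovery tolerance relaxed to 2 dB RMS);
  full-scale 37-azimuth/5 s runs are reserved for the acceptance suite,
  where symmetrized-HRTF recovery at 40 dB SNR is within 1 dB RMS over
  100 Hz–10 kHz.

## Known limitations

* The first-order shadow filter underestimates the spectral complexity of
  real heads (no pinna/ear-lid notches besides the canal's).
* The zero-phase shadow choice means simulated ITDs carry no
  frequency-dependent external component; real creeping-wave delays are
  mildly dispersive.
* Mass conservation of the variable-width frequency smoother is
  approximate (see Smoothing).
* δ(θ) for the canal prediction is a stand-in; only the constant-δ
  relation f_ic = c/(2δ) is asserted as the geometric model proper.
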