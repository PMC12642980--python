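# Methods

This note documents the models, conventions and design choices behind
`contractile`, in the spirit of a methods appendix: what is computed, under
what assumptions, and where the genuinely open choices were made.

## Data model and conventions

Frames are 0-based; frame `i` of a stack recorded at `fps` is assigned time
`i / fps` seconds, first frame at t = 0. ROIs are 0-based half-open
rectangles `[row0, row1) × [col0, col1)`. Pixels are stored as unsigned 8-
or 16-bit integers; every metric promotes to double precision before any
subtraction, so integer wraparound cannot occur. Multi-page grayscale TIFF
is the canonical stack format, CSV with a `# key=value` header the trace
format (floats written via shortest round-trip repr and parsed with
round-trip precision, so write∘read is bit-exact).

Samples of a running metric with no comparison window (the first N frames)
are emitted as NaN, never zero-filled — zero-filling would fabricate a
quiescent onset that was never observed.

## Acquisition schedule

The interleave model is: colour is the fast axis, well the slow axis — one
camera frame per (well, colour) slot, all colours of one well before the
next well, the whole cycle repeating. Per-well-per-colour sampling rate is
`camera_fps / (W·C·frames_per_slot)`. Demultiplexing keeps trailing
incomplete cycles (stacks may differ in length by one frame) rather than
discarding them, so traces are never silently shortened; analysis code
tolerates the ragged ends. Re-interleaving demuxed stacks in schedule order
reconstructs the original sequence exactly, which is tested as a property.

## Optics model

Closed forms only: depth of field `FWHM_Z = 0.88·2nλ/NA²`; per-colour
in-focus intervals `focal_shift ± FWHM_Z/2` with endpoints rounded to
0.01 mm (half away from zero); total chromatic depth range as the span of
the rounded endpoints; angular cutoff `arcsin(NA/n)` to 0.1°; spatial
sampling `pixel_pitch / magnification`; field of view using the sampling
rounded to two significant figures (the instrument-datasheet printing
convention — derived quantities then agree with the quoted values exactly);
space-bandwidth product as resolvable elements per frame times frame rate,
with the effective resolution degraded by the undersampling factor when
sampling is below Nyquist. The default DOF wavelength is the red channel
(n = 1.0, λ = 0.63 µm — a dry system with a standard red LED); both are
config fields, not constants.

The bundled nine-well preset places the green and red focal planes 0.21 mm
and 0.46 mm above the blue reference. The defocus blur slope used by the
phantom, `NA·Δz / (pixel pitch / magnification)` ≈ 34 px/mm, is the
geometric-optics estimate; blur is zero inside a colour's DOF interval and
grows linearly with excess depth. This is a deliberate simplification of
the slow evolution of a low-NA blur function with depth; it preserves the
feature that matters for focus selection (in-band colours are sharp,
out-of-band colours visibly blurred).

## Metrics

PV uses the *population* (divide-by-count) standard deviation. This is a
choice — sample std would be equally defensible — made because it gives the
exact two-point bridge `pv_speed(N=1) = mm_speed(N=1)/2`, which pins the
two metrics to a common scale and is enforced as an invariant test. The PV
window is trailing (causal), `[t−N, t]`, matching the running-subtraction
convention of the absolute-difference metric. PV sums per-pixel standard
deviations by default (summing variances is an option, `sum_variances`).

The PV absolute-contraction metric estimates per-pixel std in
`adjacent_k`-frame windows centred on the current and reference timepoints
(truncated symmetrically at stack edges, so the window stays centred) and
by default sums per-pixel absolute differences of the two std maps — this
preserves a spatial map analogous to the speed-map frames; differencing the
ROI-summed stds first is exposed as `pv_diff_of_sums`.

Brightness compensation rescales every frame to the reference frame's mean,
exactly nulling pure global-gain drift. It defaults **on** for the MM
absolute-contraction metric (whose baseline a slow drift corrupts) and
**off** for the speed metrics and for PV entirely: the PV response to a
gain change is nonlinear in the gain, so a mean-ratio correction would be
wrong in general.

Bounds: on b-bit input the MM metrics are ≤ (2^b−1)·ROI-area and the PV
per-pixel std over a bounded window is ≤ (2^b−1)/2. A variance computed
over unbounded excursions (e.g. sustained vibration) has no such practical
ceiling, which is why the PV metric responds more strongly to vibration
than MM; that qualitative behaviour is not modelled further.

## Beat analysis

Peak detection uses `scipy.signal.find_peaks` with a prominence threshold
in robust MAD units (default 5), making detection invariant to trace
scaling/normalisation. Consecutive peaks closer than a pairing window —
default 60% of the median inter-peak interval, or set explicitly when the
contraction duration is known — form one beat (contraction then relaxation
velocity peak, interior minimum = maximum contraction). Single-peak beats
are legal: at low effective sampling rates the two velocity peaks merge.
Beat duration spans the 10%-of-peak crossings; the threshold is a
convention, not a claim about any particular software's definition. The
recommended frame delay is 20% of the contraction duration times the
sampling rate (minimum 1), reproducing the sensible choices at both 100 fps
(N = 20 for a 1 s contraction) and 50 fps with cooling-slowed 4 s
contractions (N = 40).

Reference-frame selection returns the centre of the longest run of speed
samples at or below a quantile (default 0.2) — a quiescent stretch —
deterministically (earliest run on ties). No claim is made that this
matches any external tool's internal auto-selection.

Jolt rejection exploits the one property that separates a mechanical
disturbance from biology: simultaneity across wells. Per well, spike
samples have robust z-score (vs median / 1.4826·MAD) above a threshold
(default 5); a frame is flagged when ≥ quorum wells (default ⌈2W/3⌉) spike
within ±1 frame of it and at least one well spikes exactly at it. Demuxed
wells sample at staggered camera-frame offsets, so "common time base" is
enforced as equal rate with sample times aligned within one sample period,
trimmed to the common length.

## Focus selection

The focus score is normalized variance — spatial variance over squared
spatial mean, averaged over the first 5 frames. The metric choice is the
implementer's: normalized variance is invariant to the brightness
differences between LED channels (scaling a frame leaves it unchanged) and
strictly decreasing under Gaussian blur on a fixed texture, which is all
the selection task needs. Tenengrad is available as an alternative.
Averaging over a few frames suppresses contraction-phase differences
between the colour channels, which are sampled at slightly different
times. Ties break deterministically in R, G, B order.

## Phantom generator

The phantom is the test substrate; its defaults were fixed once as the
study conditions and are not tuned per test.

* **Texture**: band-passed white noise (spatial periods 4–16 px by
  default), contrast-stretched to ~80% of the bit range around a
  20000-count baseline — a stand-in for high-contrast Schlieren-like
  monolayer texture. It reproduces the *statistics* the metrics care about
  (strong gradients everywhere), not cell morphology.
* **Twitch kinetics**: each beat contributes
  `s(t) = (1 − e^{−Δt/τ_rise}) · e^{−Δt/τ_fall}` normalized to unit peak
  (closed-form peak at `τ_rise·ln(1 + τ_fall/τ_rise)`), beats spaced at the
  beat period, first beat at half a period. The shape is invented — chosen
  because its speed profile has the two-peaks-with-dip structure of real
  contraction traces. Defaults τ_rise 0.08 s, τ_fall 0.25 s at 1 Hz
  (≈1 s contraction); the slow cooled regime is emulated with 0.25 Hz and
  τ 0.3/1.0 s (≈4 s contraction interval).
* **Deformation**: displacement pulls pixels toward Gaussian-weighted foci,
  `u(p) = s·A·Σ_j w_j·e^{−|p−c_j|²/2r_j²}·(ĉ_j−p̂)`, weights normalized to
  sum to 1 so |u| ≤ s·A everywhere. Warping is inverse-mapped bilinear
  interpolation. Default peak displacement 3 px on 64×64 px frames — the
  frames are desk-scale (real wells are ~500×500 px); every pipeline
  property tested is resolution-independent at these scales.
* **Noise**: shot noise as a clipped normal approximation with variance =
  gain × mean (gain 0.5 counts by default), valid at the >100-count means
  used; exact Poisson behind `poisson_noise`. A regression of pixel
  variance on mean recovers the gain within 10% (tested).
* **Artefacts**: bubbles are dark Gaussian annuli on a random walk; jolts
  are whole-frame translations on listed frames; baseline drift is a slow
  sinusoidal gain. Parameters are invented; all artefacts default off.
* **Determinism**: one seeded generator; per-well substreams (texture, beat
  phase within ±20% of a period, bubble walks) derive from
  `SeedSequence.spawn`, so identical configs replay bit-identically.

What passing phantom tests does *not* show: performance on real optics
(true Schlieren contrast, condensation transients, meniscus effects),
cell-scale texture, or non-elastic motion; the phantom validates the
pipeline's arithmetic and detection logic, not biological image formation.

## Fringe visualization

The per-pixel std maps behind the PV speed trace retain spatial structure;
overlaying the maps from the contraction- and relaxation-velocity peaks
(red/blue, green zero, each channel min-max normalized — display scaling is
a convention) shows the spatial contraction pattern. The fringe-spacing
estimator (Hann-windowed local FFT, radially binned spectrum, parabolically
refined peak, undefined where the spectral peak is below a contrast
threshold) is an extension beyond the qualitative description of fringes;
it recovers known sinusoidal periods within ±1 px and, on phantoms, ranks
larger displacement amplitudes as larger median fringe spacing once the
displacement exceeds the texture period (below that no true fringes form
and the estimator reports the texture scale).

## Problem sizes and numerical choices

Test and example phantoms use 32–96 px frames, 2–15 s durations, and the
two sampling regimes of interest (100 fps single-well; 100 fps camera over
9 wells × 3 colours = 3.7 fps effective). Noise-scaling comparisons use
200-frame static stacks over frame delays {1, 2, 4, 8, 16} with 20 fixed
seeds, with the trace CV evaluated on the common support (samples ≥ 16) so
trace length does not confound the comparison. Variance computations clamp
tiny negative round-off to zero before the square root. The moving average
is a centred box-car with truncated edges; even windows use the
earlier-shifted alignment (`[i − w/2, i + w/2 − 1]`).

## Known limitations

* The PV "unbounded under vibration" behaviour is qualitative; no vibration
  model or detector is provided beyond jolt rejection.
* The blur model ignores diffraction PSF shape and aberrations other than
  the stated chromatic shifts.
* Beat duration and pairing defaults are conventions, exposed as
  parameters; they are not calibrated against any external plugin's output.
* The fringe-spacing estimator assumes locally quasi-periodic fringes; it
  is undefined (NaN) elsewhere by design.
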