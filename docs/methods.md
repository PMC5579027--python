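# Methods

This note documents the models, estimators and numerical choices behind
`pulsemap`, and what the synthetic-data generator does and does not
emulate.

## Physical model

**Geometry.**  Channels are straight (constant width w) or carry one
central cavity (narrow width w_n at both ends, wide width w_w over the
middle third).  The catalogue of study geometries (`pulsemap.studies`) is
150 µm long and 20 µm high: straight widths 15, 25 and 30 µm, cavity
channels 17.5/30 and 20/50 µm.  The tracked particle is a rigid 10 µm
sphere.  All lengths are micrometres; resistivity is Ω·m (default 0.092,
roughly 1 M KCl).

**Amplitude model.**  The instantaneous relative blockade is a separable
product of three factors:

1. *Local resistance term*: the sphere-in-cylinder expression
   ΔR(x) = 4ρd³/(πD(x)⁴)·[1−0.8(d/D(x))³]⁻¹ at the local equal-area
   equivalent diameter D(x) = √(4w(x)h/π), divided by the whole-channel
   series resistance R₀ = ρ∫dx/A(x).  For a straight channel this reduces
   exactly to the on-axis formula d³/(LD²)·[1−0.8(d/D)³]⁻¹.
2. *Off-axis excess* in straight/narrow sections: 1 + α(y_norm·d/D)³ with
   y_norm the particle-centre displacement over the channel radius,
   clipped at the accessible limit (D−d)/D.  In rectangular channels the
   geometric displacement can exceed that limit (the 30 µm channel); the
   clip keeps the correction bounded at its wall-contact value.  Inside a
   cavity the factor is 1 by default; an optional phenomenological
   "suppressed-near-wall" cosine taper (magnitude m ∈ [0,1]) reproduces
   an inverted lateral trend without claiming a physical mechanism.
3. *Transition envelope*: a cubic smoothstep ramp from the access level to
   1 over a length ℓ_t (default 15 µm) inside each channel end, and an
   exponential access-resistance tail outside (fraction 0.5 at the mouth,
   decay length 10 µm).  Width changes at cavity edges are blended over a
   6 µm smoothstep — the field adjusts over a finite length comparable to
   the channel height, and an abrupt step would be both unphysical and a
   source of filter ringing.

The recorded current is the exact Ohmic inversion
I = I₀(1+drift)/(1+a) plus white Gaussian noise, so (I₀−I)/I recovers
ΔR/R₀ without first-order bias (this matters at the percent level).

**Transport.**  Flow is plane Poiseuille across the width only; the
channel height is comparable to the bead, suppressing vertical motion.
Particles follow streamlines: their relative lateral position 2y/w(x) is
constant, so in a section of width w the axial speed is
v_max·(w_n/w)·(1−(2y₀/w_n)²) (2D continuity), giving the closed-form
transit-time law T(y)/T(0) = 1/(1−(2y₀/w)²) that the lateral statistics
are validated against.  Approach/departure outside the channel use a
reduced constant speed (default 0.3× the adjacent in-channel speed) over
a 25 µm margin.

**Clocks.**  Both instruments record the same physical interval; a current
sample stamped τ occurred at true time τ(1+ε) (rate mismatch ε, default
10⁻⁵ in clock studies), while frame j (true time j·T_frame) is stamped
j·T_frame + offset.  Frame content is rendered at mid-exposure.

## Detection and estimation choices

* **Filtering**: zero-phase 4-pole Bessel low-pass (10 kHz default).
  Bessel rather than Butterworth because its step response does not
  overshoot — deep pulses would otherwise ring through the detection
  threshold and fragment into spurious events.
* **Baseline**: centred moving median (50 ms default), two passes; the
  second pass masks detected event spans so pulses do not drag the
  baseline.  This estimator needs channel occupancy well below ~50%; the
  reference runs are sized for roughly 20% occupancy, which also matches
  realistic event rates.
* **Thresholding**: events open at k·σ̂ below baseline (k = 6) and close at
  0.5·k·σ̂ (hysteresis), with σ̂ a MAD-based noise scale estimated on
  event-free spans.  A relative floor of 10⁻⁹·I₀ keeps noiseless traces
  detectable without tripping on numerical ripple.
* **Amplitude scalar**: per-sample blockade is a(t) = (I₀(t)−I(t))/I(t);
  the event amplitude is the mean blockade over the central half of the
  FWHM span (an unbiased plateau estimate — the smoothed-peak value is
  noise-biased upward).  When synchronized positions exist, the amplitude
  instead averages all samples taken within ±50 µm of the channel centre.
* **Extrema**: Savitzky–Golay smoothing (window 15, order 2), derivative
  sign changes, prominence pruning at max(3σ̂, 2% of peak).  Cavity pulses
  must show the two-maxima/one-interior-minimum morphology.
* **Cavity region amplitudes**: medians of the blockade samples on the
  proper side of the half-peak level (narrow: above-half samples on each
  side of the interior minimum; cavity: below-half samples between the
  maxima).  This is position-blind and robust to noise displacing the
  extremum indices; it assumes the cavity blockade stays below half the
  narrow blockade, true for both catalogue cavity geometries.
* **Imaging**: template subtraction, threshold at 5 robust σ of the
  difference image, flood-fill labeling (8-connectivity default,
  minimum area = ¼ of the expected disk), intensity-weighted centroids.
  Linking is greedy by sorted distance, deterministic and independent of
  within-frame detection order; an exhaustive minimum-total-distance
  assignment serves as a test oracle on small scenes.
* **Matching**: coarse candidate offsets are the pairwise event-time
  differences, screened by a vectorized nearest-neighbour count and
  scored by greedy matching within a 2 ms tolerance (ties to the smallest
  |offset|; at least two matches required for a valid alignment).  The
  per-event fine offset anchors the interpolated mid-channel frame time
  to the median-index sample of the pulse's above-threshold span,
  evaluated on the smoothed blockade (raw threshold crossings jitter by
  tens of µs at realistic SNR and would defeat the one-frame-period
  alignment target).
* **Maps and profiles**: 1 µm bins / ±1 µm moving windows by default
  (matching the positional uncertainty scale); empty bins are NaN.
  Samples recorded while a second particle occupied the channel are
  dropped from maps rather than deconvolved.  The axial profile reports a
  saturation position: the first x at which the profile reaches 99% of
  its maximum.

## Reference run conditions

The `studies` module fixes the free conditions once: flow speeds give
few-ms transits (5×10⁴ µm/s default; 1.5×10⁵ µm/s when 100+ events must
fit in a 1 s recording at low occupancy); recordings are sized for ~20%
occupancy; event counts use a jittered-grid arrival mode that guarantees
the requested count with non-overlapping channel occupancy (a hard-core
Poisson mode is also available); lateral offsets are uniform over the
accessible width.  The off-axis recovery run uses the 25 µm channel,
where the full geometric lateral range maps inside the accessible range
of the equivalent-diameter description, so α is identifiable without
clipping.  Baseline current is 100 nA with 20 pA RMS noise unless a run
specifies its SNR directly.

## What the generator does and does not emulate

Emulated: Poiseuille transport with streamline following, position- and
geometry-dependent blockades with entrance/exit transition zones and
access resistance, exact Ohmic current response, white current noise and
slow sinusoidal drift, camera exposure timing, pixel noise, anti-aliased
particle images, independent stream clocks with offset and rate mismatch.

Not emulated: Brownian lateral diffusion, particle–particle hydrodynamic
interactions, aspherical or deformable particles, wall roughness and
debris, electrokinetic surface effects, a first-principles field model of
the cavity's radial dependence (only the phenomenological taper), defocus
and illumination non-uniformity.  Passing tests therefore demonstrate
that the estimators recover the *model's* ground truth under realistic
noise and clocking, not that the model captures every feature of real
recordings.

## Numerical notes and degenerate inputs

Noiseless traces are handled through explicit floors (σ̂ and prominence);
single-bin maps arise when all samples share a lateral position (on-axis
runs) and are padded to one bin width; incomplete imaging tracks (no full
channel crossing) are flagged and excluded from durations; events touching
the trace boundary are flagged truncated and excluded from statistics;
degenerate amplitude–duration fits (zero variance) raise rather than
return meaningless slopes.  All stochastic draws descend from a single
integer seed through named child streams (arrivals, lateral offsets,
trace noise, per-block frame noise), making every dataset and the full
pipeline bit-reproducible; frame noise is seeded per fixed-size block so
rendering is chunk-independent.

## Known limitations

The cavity region estimator requires the cavity blockade below half the
narrow blockade (wide/narrow width ratio ≳ 1.3).  The median-baseline
approach degrades above ~50% channel occupancy.  The coarse aligner
assumes event sequences that are not strictly periodic at the tolerance
scale; heavy jitter in arrival spacing (present in all generator modes)
protects against lattice aliasing.  The equal-area cylindrical mapping is
an approximation that worsens for very flat cross-sections (e.g. the
50 × 20 µm cavity), where the true rectangular-geometry resistance is
somewhat higher than the equivalent-area prediction.
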