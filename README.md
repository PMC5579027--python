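# pulsemap

Hybrid resistive-pulse / optical-imaging analysis of microfluidic particle
translocations.

## The problem

In resistive-pulse (RP) sensing, an insulating particle passing through an
ion-conducting channel transiently raises the channel's resistance, and the
relative current blockade ΔI/I_p = ΔR/R₀ reports the particle's size.  The
blockade also depends on *where* the particle is — its axial position in
channels of varying width, and its lateral (off-axis) position everywhere —
which a single current trace cannot resolve.  At the microscale, high-speed
imaging can watch the particle while the current is recorded, so each
instant of a pulse can be attributed to a position in the channel.

`pulsemap` implements that hybrid platform end to end for 10 µm beads in
straight and cavity-bearing PDMS microchannels (~150 µm long, ~20 µm high):

* a **physics-based simulator** of synchronized current traces (4 µs
  sampling) and camera frames (50,000 fps, 5 µs exposure), with plane
  Poiseuille transport, entrance/exit transition zones, access resistance,
  baseline drift, noise, and a clock-rate mismatch between the two streams;
* **pulse extraction** from the current trace (Bessel low-pass,
  moving-median baseline, MAD-robust hysteresis thresholding, FWHM and
  threshold durations, extrema analysis, amplitude–duration gating);
* **particle detection and tracking** in frames (template subtraction,
  thresholding, flood-fill labeling, minimum-distance linking) and a
  corner-anchored pixel→channel coordinate transform;
* **event matching**: a coarse global time shift aligning the two event
  sequences, then a per-event fine offset anchored at the channel midpoint
  that absorbs the accumulating clock skew;
* **resistance maps** — 2D binned means of the instantaneous ΔI/I_p over
  channel coordinates — plus axial profiles, lateral duration/amplitude
  statistics, and cavity/narrow amplitude ratio distributions.

## The models at its core

On-axis blockade of a sphere (diameter d) in a long cylindrical channel
(length L, diameter D):

    ΔI/I_p = d³/(L·D²) · [1 − 0.8(d/D)³]⁻¹

Local resistance increase in a channel of varying diameter D(x):

    ΔR = 4ρd³/(π·D(x)⁴) · [1 − 0.8(d/D(x))³]⁻¹

which depends only on the geometry local to the particle and predicts the
amplitude ratio between any two channel sections.  Off-axis passages carry
an empirical excess

    ΔI(y)/ΔI(0) = 1 + α·(y_norm·d/D)³,   α ≈ 5–7.5

with y_norm the lateral displacement of the particle centre normalized by
the channel radius.  Rectangular sections are mapped to these cylindrical
formulas via the equal-area equivalent diameter D_eq = √(4wh/π).

## Worked example

`examples/02_detect_pulses.py` simulates 20 on-axis translocations through
the 150 × 30 µm channel at pulse SNR 20 and runs the detector:

```
simulated events : 20
detected events  : 20
mean dI/I_p      : 9.0702e-03  (model: 9.0703e-03, -0.00 %)
mean FWHM        : 2.943 ms  (true transit: 3.000 ms)
```

Every planted pulse is recovered; the mean plateau amplitude agrees with
the sphere-in-cylinder prediction at the equivalent diameter (9.07×10⁻³)
to a fraction of a percent, and the FWHM duration matches the true
entrance-to-exit transit time.  The other examples each exercise one
capability — the closed-form models (`01`), clock alignment under skew
(`03`), resistance maps and the ~15 µm amplitude-saturation depth (`04`),
cavity/narrow ratios against theory (`05`), and the Poiseuille/off-axis
lateral statistics with recovery of α (`06`).

A full pipeline can also be driven from a YAML configuration:

```bash
pulsemap all --config run.yaml --out results/run1
```

which writes detected events (JSONL), matched pairs, the resistance-map
grid (TSV) and the axial profile (CSV).

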