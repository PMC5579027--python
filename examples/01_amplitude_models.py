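"""Closed-form pulse-amplitude models for microfluidic channels.

Computes the on-axis blockade of a 10 µm bead in each straight channel,
the predicted off-axis excess at the wall, and the cavity/narrow amplitude
ratios for the two cavity channels — the analytic backbone everything else
is validated against.
"""

from pulsemap.geometry import (
    TheoryParams,
    amplitude_ratio,
    equivalent_diameter,
    offaxis_factor,
    smythe_amplitude,
)

D_BEAD = 10.0   # bead diameter, µm
HEIGHT = 20.0   # channel height, µm
LENGTH = 150.0  # channel length, µm

print("Straight channels (on-axis blockade and off-axis excess, alpha = 7.5):")
for width in (15.0, 25.0, 30.0):
    d_eq = equivalent_diameter(width, HEIGHT)
    a0 = smythe_amplitude(D_BEAD, d_eq, LENGTH)
    y_max = (d_eq - D_BEAD) / d_eq  # wall contact of the particle centre
    excess = offaxis_factor(y_max, D_BEAD, d_eq, TheoryParams(alpha=7.5)) - 1
    print(f"  w = {width:4.0f} um  D_eq = {d_eq:5.2f} um  "
          f"dI/I_p = {a0:.4e}  max off-axis excess = {100 * excess:5.2f} %")

print("\nCavity channels (predicted wide/narrow amplitude ratio):")
for name, (w_n, w_w) in {"17.5/30": (17.5, 30.0), "20/50": (20.0, 50.0)}.items():
    r = amplitude_ratio(D_BEAD, equivalent_diameter(w_w, HEIGHT),
                        equivalent_diameter(w_n, HEIGHT))
    print(f"  {name:8s} um  ratio = {r:.4f}")

print("\nThe off-axis excess stays in the 6-12% band reported for micropores;")
print("the cavity ratios are what the detector should recover from pulses.")
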