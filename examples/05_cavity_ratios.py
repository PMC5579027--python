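"""Cavity-channel pulses: wide/narrow amplitude ratios versus theory.

Simulates noisy on-axis events in the 20/50 µm cavity channel.  Each pulse
shows two blockade maxima (narrow constrictions) and one interior minimum
(cavity); the per-event ratio of the cavity to narrow amplitudes is
compared with the local-resistance prediction at the equal-area
equivalent diameters.
"""

import numpy as np

from pulsemap import analysis, pipeline, studies
from pulsemap.geometry import Particle
from pulsemap.io import DetectionParams
from pulsemap.simulate import generate_dataset

config = studies.cavity_ratio_config("20/50", n_events=30)
dataset = generate_dataset(config, seed=7)
trace, events = pipeline.detect_rp_events(dataset.trace,
                                          DetectionParams(min_duration_s=1e-3))
events = [ev for ev in events if not ev.truncated]

res = analysis.ratio_distribution(events, config.geometry, Particle(10.0))
r = res["ratios"]

print(f"events analysed     : {len(r)}")
print(f"ratio mean +/- std  : {r.mean():.4f} +/- {r.std():.4f}")
print(f"theory (Deq ratio)  : {res['predicted']:.4f}")
print(f"relative deviation  : {100 * (r.mean() / res['predicted'] - 1):+.1f} %")
print("\nThe measured cavity/narrow ratio clusters on the prediction of the")
print("local-resistance model with equal-area cylindrical cross-sections.")
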