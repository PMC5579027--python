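"""Lateral position: transit times and the off-axis amplitude excess.

Simulates particles entering the 150 x 25 µm channel at uniformly
distributed lateral offsets, measures each event's transit time and
synchronized amplitude, and recovers the off-axis coefficient alpha from
the amplitude-versus-position trend.
"""

import numpy as np

from pulsemap import analysis, pipeline, studies, sync
from pulsemap.geometry import Particle
from pulsemap.io import DetectionParams
from pulsemap.simulate import generate_dataset

config = studies.lateral_config(alpha=6.0, n_events=120)
dataset = generate_dataset(config, seed=5)
trace, rp_events = pipeline.detect_rp_events(dataset.trace,
                                             DetectionParams(min_duration_s=2e-4))
rp_events = [ev for ev in rp_events if not ev.truncated]
im_events = pipeline.detect_im_events(dataset, DetectionParams())
matches = sync.match_events(rp_events, im_events, config.geometry, trace)

stats = analysis.lateral_stats(matches, "whole", geom=config.geometry)
alpha_hat, a0 = analysis.fit_offaxis_alpha(stats["y_um"], stats["amplitude"],
                                           Particle(10.0), config.geometry)
fit = analysis.amp_duration_fit(matches, "whole", geom=config.geometry)

dur = stats["duration_profile"]
print(f"matched events          : {len(matches)}")
print(f"duration profile minimum: y_c = {dur.centers[np.argmin(dur.mean)]:+.1f} um")
print(f"duration quad coeff     : {stats['duration_quad_coeff']:+.2e} s/um^2 (convex)")
print(f"recovered alpha         : {alpha_hat:.2f}  (simulated with 6.0)")
print(f"on-axis amplitude a0    : {a0:.4e}")
print(f"amplitude-duration fit  : slope {fit.slope:+.3e}, r = {fit.rvalue:.2f}")
print("\nSlow events travel near the walls (Poiseuille flow) and carry larger")
print("amplitudes (off-axis field distortion) — hence the positive")
print("amplitude-duration correlation seen in straight channels.")
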