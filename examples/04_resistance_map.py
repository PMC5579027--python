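"""Build a resistance map and locate where the pulse fully develops.

Runs a noiseless hybrid recording with a 15 µm entrance/exit transition
zone, pairs every frame with the instantaneous blockade, bins the samples
over channel coordinates, and reports how far into the channel the
amplitude saturates — the observation behind preferring FWHM durations
over threshold durations.
"""

import numpy as np

from pulsemap import analysis, pipeline, studies, sync
from pulsemap.io import DetectionParams
from pulsemap.simulate import generate_dataset

config = studies.transition_config(n_events=10)
dataset = generate_dataset(config, seed=2)
trace, rp_events = pipeline.detect_rp_events(dataset.trace,
                                             DetectionParams(min_duration_s=2e-4))
rp_events = [ev for ev in rp_events if not ev.truncated]
im_events = pipeline.detect_im_events(dataset, DetectionParams())
matches = sync.match_events(rp_events, im_events, config.geometry, trace)

rmap = analysis.build_map(matches, bin_um=1.0, geom=config.geometry)
axial = analysis.axial_profile(matches, geom=config.geometry)
ratios = analysis.fwhm_vs_entrance_check(matches)

filled = int((rmap.count > 0).sum())
print(f"matched events       : {len(matches)}")
print(f"map bins (non-empty) : {filled}")
print(f"peak blockade        : {axial['a_max']:.4e}")
print(f"blockade at entrance : {axial['a_entrance']:.4e} "
      f"({100 * axial['a_entrance'] / axial['a_max']:.0f} % of peak)")
print(f"saturation position  : {axial['x_saturation_um']:.1f} um into the channel")
print(f"entrance/exit vs peak: {ratios['entrance_ratio'].mean():.2f} / "
      f"{ratios['exit_ratio'].mean():.2f}")
print("\nThe amplitude saturates ~15 um inside the channel (beyond the bead's")
print("own diameter), and the physical entrance/exit sit at roughly half the")
print("peak — so a pulse's FWHM is the better transit-time estimate.")
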