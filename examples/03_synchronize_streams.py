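"""Match imaging and current events and align the two instrument clocks.

Simulates a hybrid recording whose camera timestamps are offset by 0.2 s
and whose DAQ clock runs 1e-5 fast, detects events independently in both
streams, and shows the coarse offset plus the per-event fine offsets that
absorb the accumulating skew.
"""

import numpy as np

from pulsemap import pipeline, studies, sync
from pulsemap.io import DetectionParams
from pulsemap.simulate import generate_dataset

config = studies.sync_config(n_events=40, clock_skew=1e-5,
                             stream_offset_s=0.2, duration_s=0.5)
dataset = generate_dataset(config, seed=4)

trace, rp_events = pipeline.detect_rp_events(dataset.trace,
                                             DetectionParams(min_duration_s=2e-4))
rp_events = [ev for ev in rp_events if not ev.truncated]
im_events = pipeline.detect_im_events(dataset, DetectionParams())
matches = sync.match_events(rp_events, im_events, config.geometry, trace)

fine = np.array([m.fine_offset_s for m in matches])
t = np.array([m.rp_event.time_peak_s for m in matches])
slope = np.polyfit(t, fine, 1)[0]

print(f"RP events / IM events / matched : {len(rp_events)} / "
      f"{sum(e.complete for e in im_events)} / {len(matches)}")
print(f"coarse offset    : {matches[0].coarse_offset_s * 1e3:+.2f} ms "
      f"(camera labels lead by 200 ms)")
print(f"fine offsets     : {fine.min() * 1e6:+.1f} .. {fine.max() * 1e6:+.1f} us")
print(f"fine-offset drift: {slope:+.2e} s/s  (clock-rate mismatch 1e-5)")
print("\nOne global shift aligns the event sequences; the per-event fine")
print("offsets grow linearly because the DAQ clock runs slightly fast, and")
print("each event uses only its own offset for sample-level pairing.")
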