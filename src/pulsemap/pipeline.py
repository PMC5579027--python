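"""End-to-end orchestration: simulate, detect in both streams, match, map.

The imaging stream is processed in chunks of frames so that multi-second
50 kfps recordings never have to be held in memory at once.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, imaging, rp, simulate, sync
from .io import RunConfig, geometry_to_dict, write_frames, write_jsonl, write_trace
from .imaging import Detection, FrameSequence

__all__ = ["detect_rp_events", "detect_im_events", "run_all", "write_map_tsv"]

log = logging.getLogger(__name__)


def detect_rp_events(trace: rp.CurrentTrace, det) -> tuple[rp.CurrentTrace, list[rp.RPEvent]]:
    """Preprocess a trace and return characterized, non-truncated events."""
    trace = rp.preprocess(trace, lowpass_hz=det.lowpass_hz,
                          detrend_window_s=det.detrend_window_s, k_exclude=det.k)
    events = rp.detect_and_characterize(trace, k=det.k, hysteresis=det.hysteresis,
                                        min_duration_s=det.min_duration_s,
                                        max_duration_s=det.max_duration_s,
                                        smoothing_window=det.smoothing_window)
    return trace, events


def detect_im_events(dataset: simulate.Dataset, det, chunk: int = 4096) -> list[imaging.IMEvent]:
    """Chunked template subtraction, labeling and tracking over a dataset."""
    acq = dataset.config.acquisition
    template = dataset.template_frame()
    r_px = dataset.config.particle.diameter_um / 2.0 / acq.um_per_px
    detections: list[Detection] = []
    theta = det.theta
    for j0 in range(0, dataset.n_frames, chunk):
        frames, ts = dataset.frames(j0, j0 + chunk)
        seq = FrameSequence(frames=frames, timestamps_s=ts, um_per_px=acq.um_per_px,
                            template=template, exposure_s=acq.exposure_s)
        if theta is None:
            theta = imaging.robust_threshold(
                imaging.subtract_template(frames[0], template), det.n_sigma)
        dets = imaging.detect_sequence(seq, theta=theta, connectivity=det.connectivity,
                                       min_area_px=det.min_area_px,
                                       expected_radius_px=r_px)
        for d in dets:
            d.frame_index += j0
        detections.extend(dets)
    tracks = imaging.link_tracks(detections, max_disp_px=det.max_disp_px,
                                 max_frame_gap=det.max_frame_gap)
    events = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        events.append(imaging.to_im_event(tr, dataset.camera, dataset.config.geometry))
    return events


def write_map_tsv(rmap: analysis.ResistanceMap, path) -> None:
    """Non-empty bins as TSV (x_c_bin, y_c_bin, mean, std, count)."""
    xs, ys = np.meshgrid(rmap.x_centers_um, rmap.y_centers_um, indexing="ij")
    ok = rmap.count > 0
    pd.DataFrame({"x_c_um": xs[ok], "y_c_um": ys[ok], "mean": rmap.mean[ok],
                  "std": rmap.std[ok], "count": rmap.count[ok].astype(int)}) \
        .to_csv(path, sep="\t", index=False, float_format="%.6e")


def run_all(config: RunConfig, outdir=None, write_raw: bool = False) -> dict:
    """Run the full pipeline from one configuration and seed.

    Returns a results dict (dataset, events, matches, map, profile, counts);
    with ``outdir`` set, also writes events, the matched pairs, the
    resistance map TSV, the axial profile CSV and a run summary.  With
    ``write_raw`` the synthetic trace/TIFF/ground truth are written too.
    """
    dataset = simulate.generate_dataset(config.simulation, config.seed)
    trace, rp_events = detect_rp_events(dataset.trace, config.detection)
    rp_events = [ev for ev in rp_events if not ev.truncated]
    im_events = detect_im_events(dataset, config.detection)
    matches = sync.match_events(rp_events, im_events, config.geometry, trace,
                                tol_s=config.sync.tol_s,
                                max_fine_offset_s=config.sync.max_fine_offset_s)
    rmap = analysis.build_map(matches, bin_um=config.analysis.map_bin_um,
                              geom=config.geometry)
    axial = analysis.axial_profile(matches,
                                   half_window_um=config.analysis.profile_half_window_um,
                                   geom=config.geometry)
    results = {"dataset": dataset, "trace": trace, "rp_events": rp_events,
               "im_events": im_events, "matches": matches, "map": rmap,
               "axial": axial,
               "counts": {"truth": len(dataset.truth), "rp": len(rp_events),
                          "im": len([e for e in im_events if e.complete]),
                          "matched": len(matches)}}
    log.info("pipeline counts: %s", results["counts"])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if write_raw:
            write_trace(dataset.trace, outdir / "trace.csv",
                        i0_a=config.simulation.acquisition.baseline_current_a)
            frames, ts = dataset.frames()
            write_frames(frames, ts, outdir / "frames.tif")
            write_jsonl(dataset.truth, outdir / "truth.jsonl")
            (outdir / "geometry.yaml").write_text(
                _geometry_yaml(config, dataset))
        write_jsonl(rp_events, outdir / "events_rp.jsonl")
        write_jsonl(im_events, outdir / "events_im.jsonl")
        write_jsonl(matches, outdir / "matched.jsonl")
        write_map_tsv(rmap, outdir / "map.tsv")
        prof = axial["profile"]
        pd.DataFrame({"x_c_um": prof.centers, "mean": prof.mean,
                      "std": prof.std, "count": prof.count}) \
            .to_csv(outdir / "axial_profile.csv", index=False, float_format="%.6e")
        summary = {"counts": results["counts"],
                   "x_saturation_um": axial["x_saturation_um"],
                   "a_max": axial["a_max"], "seed": config.seed}
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return results


def _geometry_yaml(config: RunConfig, dataset: simulate.Dataset) -> str:
    import yaml

    d = geometry_to_dict(config.geometry, frame=dataset.camera,
                         um_per_px=config.simulation.acquisition.um_per_px)
    return yaml.safe_dump({"geometry": d})
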