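"""File formats: current-trace CSV, frame TIFF stacks, event JSONL, YAML
configuration.

Traces are two-column CSV (``time_s,current_A``) with a JSON sidecar holding
the sample rate and baseline current; frames are multi-page grayscale TIFF
with a ``frame_index,time_s`` timestamp CSV; events and ground truth are
JSONL (one record per line); run configuration is YAML validated against the
package's dataclasses with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ChannelFrame, ChannelGeometry, Particle, TheoryParams, make_frame
from .imaging import FrameSequence, IMEvent
from .rp import ConfigError, CurrentTrace, RPEvent
from .simulate import AcquisitionModel, FlowModel, SimulationConfig, TransitionModel
from .sync import MatchedEvent

__all__ = [
    "write_trace", "read_trace", "write_frames", "read_frames",
    "write_jsonl", "read_jsonl", "rp_event_from_dict", "im_event_from_dict",
    "matched_event_from_dict", "geometry_from_dict", "geometry_to_dict",
    "RunConfig", "load_config",
]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: CurrentTrace, path, i0_a: float | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times_s, "current_A": trace.current_a})
    df.to_csv(path, index=False, float_format="%.12e")
    sidecar = {"sample_rate_hz": 1.0 / trace.sample_period_s}
    if i0_a is not None:
        sidecar["I0_A"] = i0_a
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_trace(path) -> CurrentTrace:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigError(
            f"missing sidecar {sidecar.name}: write it as JSON with at least "
            "{'sample_rate_hz': <float>} next to the trace CSV")
    meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path)
        current = df["current_A"].to_numpy(dtype=float)
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"malformed trace CSV {path}: {exc}") from exc
    return CurrentTrace(sample_period_s=1.0 / float(meta["sample_rate_hz"]),
                        current_a=current)


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------


def write_frames(frames: np.ndarray, timestamps_s: np.ndarray, path,
                 timestamps_path=None) -> None:
    path = Path(path)
    tifffile.imwrite(path, frames, photometric="minisblack")
    ts_path = Path(timestamps_path) if timestamps_path else path.with_suffix(".timestamps.csv")
    pd.DataFrame({"frame_index": np.arange(len(timestamps_s)),
                  "time_s": timestamps_s}).to_csv(ts_path, index=False,
                                                  float_format="%.9e")


def read_frames(path, timestamps_path=None, um_per_px: float = 1.0,
                template: np.ndarray | None = None,
                exposure_s: float = 0.0) -> FrameSequence:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if frames.dtype not in (np.uint8, np.uint16):
        raise ConfigError(f"unsupported frame bit depth {frames.dtype}")
    ts_path = Path(timestamps_path) if timestamps_path else path.with_suffix(".timestamps.csv")
    ts = pd.read_csv(ts_path)["time_s"].to_numpy(dtype=float)
    if len(ts) != len(frames):
        raise ConfigError(f"timestamp count ({len(ts)}) != page count ({len(frames)})")
    return FrameSequence(frames=frames, timestamps_s=ts, um_per_px=um_per_px,
                         template=template, exposure_s=exposure_s)


# ---------------------------------------------------------------------------
# JSONL events
# ---------------------------------------------------------------------------


def write_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if hasattr(rec, "to_dict"):
                rec = rec.to_dict()
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def rp_event_from_dict(d: dict, sample_period_s: float) -> RPEvent:
    ev = RPEvent(start=d["start"], end=d["end"], core_start=d["core_start"],
                 core_end=d["core_end"], sample_period_s=sample_period_s,
                 baseline_i0_a=d["baseline_i0_a"], plateau_ip_a=d["plateau_ip_a"],
                 amplitude=d["amplitude"], peak_amplitude=d["peak_amplitude"],
                 fwhm_s=d["fwhm_s"], threshold_duration_s=d["threshold_duration_s"],
                 extrema=[(i, v, k) for i, v, k in d["extrema"]],
                 truncated=d["truncated"])
    ev.peak_index = int(round(d["time_peak_s"] / sample_period_s))
    if "blockade" in d:
        ev.blockade = np.asarray(d["blockade"], dtype=float)
    return ev


def im_event_from_dict(d: dict) -> IMEvent:
    return IMEvent(times_s=np.asarray(d["times_s"]), x_c_um=np.asarray(d["x_c_um"]),
                   y_c_um=np.asarray(d["y_c_um"]),
                   frame_indices=np.asarray(d["frame_indices"], dtype=int),
                   complete=d["complete"], t_entry_s=d["t_entry_s"],
                   t_exit_s=d["t_exit_s"], duration_s=d["duration_s"],
                   y_mean_um=d["y_mean_um"])


def matched_event_from_dict(d: dict, sample_period_s: float) -> MatchedEvent:
    m = MatchedEvent(rp_event=rp_event_from_dict(d["rp_event"], sample_period_s),
                     im_event=im_event_from_dict(d["im_event"]),
                     coarse_offset_s=d["coarse_offset_s"],
                     fine_offset_s=d["fine_offset_s"])
    if "samples" in d:
        s = d["samples"]
        m.samples = np.rec.fromarrays(
            [np.asarray(s[k], dtype=float) for k in ("t", "x_um", "y_um", "blockade")],
            names=["t", "x_um", "y_um", "blockade"])
    return m


# ---------------------------------------------------------------------------
# geometry / configuration
# ---------------------------------------------------------------------------


_GEOM_KEYS = {"kind", "length_um", "height_um", "width_um", "width_narrow_um",
              "width_wide_um", "cavity_start_um", "cavity_end_um",
              "resistivity_ohm_m"}


def geometry_from_dict(d: dict) -> ChannelGeometry:
    unknown = set(d) - _GEOM_KEYS - {"corners_px", "um_per_px"}
    if unknown:
        raise ConfigError(f"unknown geometry keys: {sorted(unknown)}")
    return ChannelGeometry(**{k: v for k, v in d.items() if k in _GEOM_KEYS})


def geometry_to_dict(geom: ChannelGeometry, frame: ChannelFrame | None = None,
                     um_per_px: float | None = None) -> dict:
    d = {k: v for k, v in dataclasses.asdict(geom).items() if v is not None}
    if frame is not None:
        d["corners_px"] = {"entrance": frame.entrance_corners_px.tolist(),
                           "exit": frame.exit_corners_px.tolist()}
    if um_per_px is not None:
        d["um_per_px"] = um_per_px
    return d


def frame_from_dict(d: dict, geom: ChannelGeometry) -> ChannelFrame:
    corners = d["corners_px"]
    return make_frame(corners["entrance"], corners["exit"], geom.length_um)


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


@dataclasses.dataclass
class DetectionParams:
    """Detection knobs for both streams."""

    k: float = 6.0
    hysteresis: float = 0.5
    lowpass_hz: float | None = 10e3
    detrend_window_s: float = 50e-3
    min_duration_s: float = 1e-4
    max_duration_s: float = 1.0
    smoothing_window: int = 15
    theta: float | None = None
    n_sigma: float = 5.0
    connectivity: int = 8
    min_area_px: int | None = None
    max_disp_px: float = 6.0
    max_frame_gap: int = 2


@dataclasses.dataclass
class SyncParams:
    tol_s: float = 2e-3
    max_fine_offset_s: float = 5e-3


@dataclasses.dataclass
class AnalysisParams:
    map_bin_um: float = 1.0
    profile_half_window_um: float = 1.0


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    geometry: ChannelGeometry
    simulation: SimulationConfig
    detection: DetectionParams
    sync: SyncParams
    analysis: AnalysisParams
    seed: int = 0


_TOP_KEYS = {"geometry", "particle", "flow", "acquisition", "transition",
             "theory", "simulation", "detection", "sync", "analysis", "seed"}


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere raise :class:`ConfigError` with the offending
    section and field names.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        raw = yaml.safe_load(Path(path_or_dict).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "geometry" not in raw:
        raise ConfigError("configuration needs a 'geometry' section")
    geom = geometry_from_dict(raw["geometry"])
    particle = _build(Particle, raw.get("particle", {"diameter_um": 10.0}), "particle")
    flow = _build(FlowModel, raw.get("flow", {}), "flow")
    acq = _build(AcquisitionModel, raw.get("acquisition", {}), "acquisition")
    transition = _build(TransitionModel, raw.get("transition", {}), "transition")
    theory = _build(TheoryParams, raw.get("theory", {}), "theory")
    sim_section = dict(raw.get("simulation", {}))
    sim = _build(
        SimulationConfig,
        {"geometry": geom, "particle": particle, "flow": flow, "acquisition": acq,
         "transition": transition, "theory": theory, **sim_section},
        "simulation")
    det = _build(DetectionParams, raw.get("detection", {}), "detection")
    syn = _build(SyncParams, raw.get("sync", {}), "sync")
    ana = _build(AnalysisParams, raw.get("analysis", {}), "analysis")
    return RunConfig(geometry=geom, simulation=sim, detection=det, sync=syn,
                     analysis=ana, seed=int(raw.get("seed", 0)))
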