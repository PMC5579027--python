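"""Particle detection and tracking in high-speed microscopy frames.

Dark beads on a bright background are found by subtracting each frame from a
particle-free template, thresholding the difference, grouping pixels into
connected components (flood fill) and tracking cluster centroids across
frames with a minimum-distance linker.  Tracks are then mapped into the
channel coordinate frame to produce imaging events with entrance/exit
crossing times and a mean lateral position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ChannelFrame, ChannelGeometry, to_channel_coords

__all__ = [
    "FrameSequence",
    "Detection",
    "IMEvent",
    "subtract_template",
    "robust_threshold",
    "threshold_and_label",
    "detect_sequence",
    "link_tracks",
    "to_im_event",
]

log = logging.getLogger(__name__)


@dataclass
class FrameSequence:
    """A block of grayscale frames with timestamps and a template frame.

    ``timestamps_s`` carry the camera-stream clock; the representative
    instant of frame ``k`` is ``timestamps_s[k] + exposure_s / 2``
    (mid-exposure).
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    um_per_px: float
    template: np.ndarray | None = None
    exposure_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) array")
        if len(self.timestamps_s) != len(self.frames):
            raise ValueError("timestamp count must equal the frame count")
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.template is not None and self.template.shape != self.frames.shape[1:]:
            raise ValueError("template shape must match the frame shape")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def sample_times_s(self) -> np.ndarray:
        return self.timestamps_s + self.exposure_s / 2.0


@dataclass
class Detection:
    """One thresholded pixel cluster: intensity-weighted centroid in pixel
    coordinates (x = column, y = row) and its area."""

    frame_index: int
    centroid_px: tuple[float, float]
    area_px: int
    time_s: float = np.nan


@dataclass
class IMEvent:
    """One particle's imaging trajectory in channel coordinates."""

    times_s: np.ndarray
    x_c_um: np.ndarray
    y_c_um: np.ndarray
    frame_indices: np.ndarray
    complete: bool
    t_entry_s: float = np.nan
    t_exit_s: float = np.nan
    duration_s: float = np.nan
    y_mean_um: float = np.nan

    def time_at_x(self, x_um: float) -> float:
        """Interpolated time at which the particle sits at axial position x."""
        return float(np.interp(x_um, self.x_c_um, self.times_s))

    def to_dict(self) -> dict:
        return {"t_entry_s": float(self.t_entry_s), "t_exit_s": float(self.t_exit_s),
                "duration_s": float(self.duration_s), "y_mean_um": float(self.y_mean_um),
                "complete": bool(self.complete),
                "frame_indices": [int(i) for i in self.frame_indices],
                "times_s": [float(v) for v in self.times_s],
                "x_c_um": [float(v) for v in self.x_c_um],
                "y_c_um": [float(v) for v in self.y_c_um]}


# ---------------------------------------------------------------------------
# per-frame detection
# ---------------------------------------------------------------------------


def subtract_template(frame: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Signed difference (template - frame): dark particles give a positive
    response.  A uniform brightness offset shifts the whole difference and is
    absorbed by the robust threshold."""
    if frame.shape != template.shape:
        raise ValueError("frame and template shapes differ")
    return template.astype(np.float32) - frame.astype(np.float32)


def robust_threshold(diff: np.ndarray, n_sigma: float = 5.0) -> float:
    """Threshold at ``n_sigma`` robust (MAD) noise sigmas of the difference."""
    med = np.median(diff)
    mad = np.median(np.abs(diff - med))
    sigma = 1.4826 * mad
    if sigma <= 0:
        sigma = max(float(np.std(diff)), 1e-6)
    return float(med + n_sigma * sigma)


_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


def threshold_and_label(diff: np.ndarray, theta: float, connectivity: int = 8,
                        min_area_px: int = 1) -> list[Detection]:
    """Connected components (flood fill) of {diff >= theta}; clusters smaller
    than ``min_area_px`` are dropped.  Centroids are intensity-weighted."""
    if not theta > 0:
        raise ValueError("threshold must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = diff >= theta
    labels, n = ndimage.label(mask, structure=_STRUCT4 if connectivity == 4 else _STRUCT8)
    if n == 0:
        return []
    lab = labels[mask]
    weight = diff[mask]  # >= theta > 0, safe as centroid weights
    yy, xx = np.nonzero(mask)
    area = np.bincount(lab, minlength=n + 1)
    wsum = np.bincount(lab, weights=weight, minlength=n + 1)
    wsum[0] = 1.0  # background bin, never reported
    cx = np.bincount(lab, weights=weight * xx, minlength=n + 1) / wsum
    cy = np.bincount(lab, weights=weight * yy, minlength=n + 1) / wsum
    return [Detection(frame_index=-1, centroid_px=(float(cx[i]), float(cy[i])),
                      area_px=int(area[i]))
            for i in range(1, n + 1) if area[i] >= min_area_px]


def detect_sequence(seq: FrameSequence, theta: float | None = None,
                    n_sigma: float = 5.0, connectivity: int = 8,
                    min_area_px: int | None = None,
                    expected_radius_px: float | None = None) -> list[Detection]:
    """Detect particles in every frame of a sequence.

    ``theta=None`` picks the threshold automatically at ``n_sigma`` robust
    sigmas of the first frame's difference image.  ``min_area_px`` defaults
    to a quarter of the expected disk area when ``expected_radius_px`` is
    given, else 4.  Frames whose difference never reaches the threshold are
    skipped cheaply.
    """
    if seq.template is None:
        raise ValueError("sequence has no template frame")
    template = seq.template.astype(np.float32)
    if theta is None:
        theta = robust_threshold(subtract_template(seq.frames[0], seq.template), n_sigma)
    if min_area_px is None:
        min_area_px = int(0.25 * np.pi * expected_radius_px ** 2) if expected_radius_px else 4

    # cheap per-frame maximum response to skip empty frames
    diffs = template[None, :, :] - seq.frames.astype(np.float32)
    busy = diffs.max(axis=(1, 2)) >= theta
    out: list[Detection] = []
    times = seq.sample_times_s
    for k in np.nonzero(busy)[0]:
        for det in threshold_and_label(diffs[k], theta, connectivity, min_area_px):
            det.frame_index = int(k)
            det.time_s = float(times[k])
            out.append(det)
    return out


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def link_tracks(detections: list[Detection], max_disp_px: float,
                max_frame_gap: int = 2) -> list[list[Detection]]:
    """Link detections into tracks with a greedy minimum-distance assignment.

    For every new frame, all (active track, detection) pairs are sorted by
    centroid distance and accepted in order while both endpoints are free
    and the distance is at most ``max_disp_px`` (scaled by the frame gap).
    Unmatched detections open new tracks; tracks not extended for more than
    ``max_frame_gap`` frames are closed.  Deterministic and independent of
    the detection order within a frame.
    """
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame_index, []).append(det)

    active: list[list[Detection]] = []
    done: list[list[Detection]] = []
    for fi in sorted(by_frame):
        # retire stale tracks
        still = []
        for tr in active:
            if fi - tr[-1].frame_index > max_frame_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        dets = sorted(by_frame[fi], key=lambda d: d.centroid_px)
        pairs = []
        for ti, tr in enumerate(active):
            gap = fi - tr[-1].frame_index
            p = np.asarray(tr[-1].centroid_px)
            for di, det in enumerate(dets):
                dist = float(np.hypot(*(np.asarray(det.centroid_px) - p)))
                if dist <= max_disp_px * gap:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            active[ti].append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, det in enumerate(dets):
            if di not in used_d:
                active.append([det])
    done.extend(active)
    done.sort(key=lambda tr: (tr[0].frame_index, tr[0].centroid_px))
    return done


def brute_force_link(detections: list[Detection], max_disp_px: float,
                     max_frame_gap: int = 2) -> list[list[Detection]]:
    """Exhaustive minimum-total-distance frame-to-frame assignment.

    Test oracle for :func:`link_tracks` on small scenes (<= ~6 particles
    per frame); enumerates all injective assignments per frame transition.
    """
    from itertools import permutations

    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame_index, []).append(det)

    active: list[list[Detection]] = []
    done: list[list[Detection]] = []
    for fi in sorted(by_frame):
        still = []
        for tr in active:
            if fi - tr[-1].frame_index > max_frame_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        dets = sorted(by_frame[fi], key=lambda d: d.centroid_px)

        n_t, n_d = len(active), len(dets)
        best = (float("inf"), -1, ())  # (total distance, -n_matched, assignment)
        slots = list(range(n_d)) + [None] * n_t
        seen = set()
        for perm in permutations(slots, n_t):
            if perm in seen:
                continue
            seen.add(perm)
            total, matched, ok = 0.0, 0, True
            for ti, di in enumerate(perm):
                if di is None:
                    continue
                gap = fi - active[ti][-1].frame_index
                dist = float(np.hypot(*(np.asarray(dets[di].centroid_px)
                                        - np.asarray(active[ti][-1].centroid_px))))
                if dist > max_disp_px * gap:
                    ok = False
                    break
                total += dist
                matched += 1
            if ok and (-matched, total) < (best[1], best[0]):
                best = (total, -matched, perm)
        assigned = set()
        for ti, di in enumerate(best[2]):
            if di is not None:
                active[ti].append(dets[di])
                assigned.add(di)
        for di, det in enumerate(dets):
            if di not in assigned:
                active.append([det])
    done.extend(active)
    done.sort(key=lambda tr: (tr[0].frame_index, tr[0].centroid_px))
    return done


# ---------------------------------------------------------------------------
# channel-frame events
# ---------------------------------------------------------------------------


def _crossing_time(t: np.ndarray, x: np.ndarray, level: float) -> float:
    """First time x(t) crosses ``level`` going forward (linear interpolation)."""
    above = x >= level
    if not above.any() or above.all():
        return np.nan
    i = int(np.argmax(above))
    if i == 0:
        return np.nan
    f = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def to_im_event(track: list[Detection], frame: ChannelFrame,
                geom: ChannelGeometry) -> IMEvent:
    """Convert a pixel track to an imaging event in channel coordinates.

    Entrance and exit times are linear interpolations of x_c(t) at 0 and L;
    the mean lateral position averages y_c over in-channel frames.  Tracks
    that never cross both planes are flagged incomplete (no duration).
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 detections")
    pts = np.array([d.centroid_px for d in track])
    t = np.array([d.time_s for d in track])
    order = np.argsort(t)
    pts, t = pts[order], t[order]
    x_c, y_c = to_channel_coords(pts, frame)

    L = geom.length_um
    t_entry = _crossing_time(t, x_c, 0.0)
    t_exit = _crossing_time(t, x_c, L)
    complete = np.isfinite(t_entry) and np.isfinite(t_exit)
    inside = (x_c >= 0) & (x_c <= L)
    y_mean = float(np.mean(y_c[inside])) if inside.any() else np.nan
    ev = IMEvent(times_s=t, x_c_um=x_c, y_c_um=y_c,
                 frame_indices=np.array([track[i].frame_index for i in order]),
                 complete=bool(complete),
                 t_entry_s=t_entry, t_exit_s=t_exit,
                 duration_s=(t_exit - t_entry) if complete else np.nan,
                 y_mean_um=y_mean)
    if not complete:
        log.warning("incomplete imaging track (no full channel crossing)")
    return ev
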