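"""Matching resistive-pulse and imaging events and aligning their clocks.

The two streams are recorded by independent hardware clocks that differ by a
global offset and a small relative rate mismatch.  Alignment is two-stage:

* **Coarse**: one global time shift is found by scanning candidate offsets
  (all pairwise event-time differences) and keeping the one that maximizes
  the number of greedy nearest matches within a tolerance.  Events left
  unpaired on either side are reported and dropped.
* **Fine**: because of the rate mismatch, a single offset drifts over the
  recording; a unique per-event offset is computed by anchoring the frame
  where the particle sits mid-channel to the middle-most sample of the
  matched pulse's above-threshold span, and is applied to that event only.

After alignment, each in-span frame is paired with the interpolated current
sample at the same instant, producing (t, x_c, y_c, dI/I_p) tuples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import ChannelGeometry
from .imaging import IMEvent
from .rp import CurrentTrace, RPEvent

__all__ = [
    "AlignmentError",
    "CoarseAlignment",
    "MatchedEvent",
    "coarse_align",
    "fine_align",
    "pair_samples",
    "match_events",
]

log = logging.getLogger(__name__)


class AlignmentError(RuntimeError):
    pass


@dataclass
class CoarseAlignment:
    offset_s: float
    pairs: list[tuple[int, int]]
    unpaired_rp: list[int]
    unpaired_im: list[int]


@dataclass
class MatchedEvent:
    """A synchronized (RP event, IM event) pair.

    ``samples`` is a record array with fields t (RP-clock seconds), x_um,
    y_um and blockade.
    """

    rp_event: RPEvent
    im_event: IMEvent
    coarse_offset_s: float
    fine_offset_s: float
    samples: np.ndarray | None = None

    @property
    def total_offset_s(self) -> float:
        return self.coarse_offset_s + self.fine_offset_s

    def to_dict(self) -> dict:
        d = {"coarse_offset_s": float(self.coarse_offset_s),
             "fine_offset_s": float(self.fine_offset_s),
             "rp_event": self.rp_event.to_dict(),
             "im_event": self.im_event.to_dict()}
        if self.samples is not None:
            d["samples"] = {k: [float(v) for v in self.samples[k]]
                            for k in self.samples.dtype.names}
        return d


def _greedy_match(a: np.ndarray, b: np.ndarray, tol: float):
    """Greedy nearest matching of two sorted time lists within ``tol``."""
    pairs = []
    j = 0
    used = np.zeros(len(b), dtype=bool)
    for i, t in enumerate(a):
        while j < len(b) and b[j] < t - tol:
            j += 1
        best, best_dt = -1, tol
        for k in range(j, len(b)):
            if b[k] > t + tol:
                break
            dt = abs(b[k] - t)
            if not used[k] and dt <= best_dt:
                best, best_dt = k, dt
        if best >= 0:
            used[best] = True
            pairs.append((i, best))
    return pairs


def coarse_align(rp_times_s, im_times_s, tol_s: float = 2e-3,
                 max_candidates: int = 10_000) -> CoarseAlignment:
    """Find the global shift aligning the two event-time sequences.

    Candidate offsets are the pairwise differences rp_i - im_j (strided
    subsample if there are more than ``max_candidates``); the returned
    offset maximizes the match count, ties broken towards the smallest
    magnitude.  Because any single pair trivially aligns with itself, an
    alignment requires at least two matches whenever both streams hold two
    or more events; otherwise :class:`AlignmentError` is raised.
    """
    rp = np.sort(np.asarray(rp_times_s, dtype=float))
    im = np.sort(np.asarray(im_times_s, dtype=float))
    if len(rp) == 0 or len(im) == 0:
        raise AlignmentError("both streams need at least one event")

    diffs = (rp[:, None] - im[None, :]).ravel()
    if len(diffs) > max_candidates:
        stride = int(np.ceil(len(diffs) / max_candidates))
        diffs = diffs[::stride]
    candidates = np.unique(diffs)

    # cheap screening: count rp times with any im neighbour within tol
    approx = np.empty(len(candidates), dtype=int)
    for ci, off in enumerate(candidates):
        pos = np.searchsorted(im + off, rp)
        left = np.where(pos > 0, rp - (im + off)[np.maximum(pos - 1, 0)], np.inf)
        right = np.where(pos < len(im), (im + off)[np.minimum(pos, len(im) - 1)] - rp, np.inf)
        approx[ci] = int(np.sum(np.minimum(left, right) <= tol_s))
    min_matches = 2 if min(len(rp), len(im)) >= 2 else 1
    if approx.max() < min_matches:
        raise AlignmentError("no candidate offset aligns the event sequences")
    shortlist = candidates[approx >= max(min_matches, approx.max() - 1)]

    best = None  # ((n_matches, -|offset|), offset, pairs)
    for off in shortlist:
        pairs = _greedy_match(rp, im + off, tol_s)
        key = (len(pairs), -abs(off))
        if len(pairs) >= min_matches and (best is None or key > best[0]):
            best = (key, float(off), pairs)
    if best is None:
        raise AlignmentError("no candidate offset aligns the event sequences")
    _, offset, pairs = best
    matched_rp = {i for i, _ in pairs}
    matched_im = {j for _, j in pairs}
    unpaired_rp = [i for i in range(len(rp)) if i not in matched_rp]
    unpaired_im = [j for j in range(len(im)) if j not in matched_im]
    if unpaired_rp or unpaired_im:
        log.info("coarse_align: %d RP / %d IM events unpaired",
                 len(unpaired_rp), len(unpaired_im))
    return CoarseAlignment(offset_s=offset, pairs=pairs,
                           unpaired_rp=unpaired_rp, unpaired_im=unpaired_im)


def fine_align(rp_event: RPEvent, im_event: IMEvent, geom: ChannelGeometry,
               coarse_offset_s: float, max_fine_offset_s: float = 5e-3) -> float:
    """Per-event residual offset from the mid-channel anchor.

    The IM anchor is the interpolated time at x_c = L/2; the RP anchor is
    the median-index sample of the pulse's above-threshold span.  The fine
    offset maps this event's IM timestamps onto the RP clock on top of the
    coarse offset.  Incomplete IM events are rejected.
    """
    if not im_event.complete:
        raise AlignmentError("cannot fine-align an incomplete imaging event")
    anchor_im = im_event.time_at_x(geom.length_um / 2.0)
    anchor_rp = rp_event.anchor_time_s
    fine = anchor_rp - (anchor_im + coarse_offset_s)
    if abs(fine) > max_fine_offset_s:
        log.warning("fine offset %.3g s exceeds the configured bound", fine)
    return float(fine)


def pair_samples(matched: MatchedEvent, trace: CurrentTrace) -> np.ndarray:
    """Pair each frame of the IM event with the current at the same instant.

    Frame times are shifted by the event's total offset into the RP clock
    and the filtered current and baseline are linearly interpolated there;
    only frames whose aligned time falls inside the RP event's padded span
    are kept.  Fills and returns ``matched.samples``.
    """
    if trace.filtered_a is None:
        raise AlignmentError("trace must be preprocessed")
    ev = matched.rp_event
    t_aligned = matched.im_event.times_s + matched.total_offset_s
    t0 = ev.start * trace.sample_period_s
    t1 = (ev.end - 1) * trace.sample_period_s
    keep = (t_aligned >= t0) & (t_aligned <= t1)

    tt = trace.times_s
    i_f = np.interp(t_aligned[keep], tt, trace.filtered_a)
    i_0 = np.interp(t_aligned[keep], tt, trace.baseline_a)
    a = (i_0 - i_f) / i_f
    samples = np.rec.fromarrays(
        [t_aligned[keep], matched.im_event.x_c_um[keep],
         matched.im_event.y_c_um[keep], a],
        names=["t", "x_um", "y_um", "blockade"])
    matched.samples = samples
    return samples


def central_amplitude(matched: MatchedEvent, geom: ChannelGeometry,
                      half_window_um: float = 50.0) -> float:
    """Event amplitude from synchronized data: the mean blockade over all
    samples taken while the particle was within ``half_window_um`` of the
    channel centre (averages out noise without ramp contamination)."""
    if matched.samples is None:
        raise AlignmentError("pair samples first")
    s = matched.samples
    keep = np.abs(s["x_um"] - geom.length_um / 2.0) <= half_window_um
    if not keep.any():
        return float("nan")
    return float(np.mean(s["blockade"][keep]))


def match_events(rp_events: list[RPEvent], im_events: list[IMEvent],
                 geom: ChannelGeometry, trace: CurrentTrace,
                 tol_s: float = 2e-3, max_fine_offset_s: float = 5e-3) -> list[MatchedEvent]:
    """Full matching protocol: coarse align on event times (RP peak time vs
    IM mid-channel time), per-event fine alignment, sample pairing."""
    complete = [ev for ev in im_events if ev.complete]
    rp_times = [ev.time_peak_s for ev in rp_events]
    im_times = [ev.time_at_x(geom.length_um / 2.0) for ev in complete]
    coarse = coarse_align(rp_times, im_times, tol_s=tol_s)
    out = []
    for i, j in coarse.pairs:
        rp_ev, im_ev = rp_events[i], complete[j]
        fine = fine_align(rp_ev, im_ev, geom, coarse.offset_s, max_fine_offset_s)
        m = MatchedEvent(rp_event=rp_ev, im_event=im_ev,
                         coarse_offset_s=coarse.offset_s, fine_offset_s=fine)
        pair_samples(m, trace)
        out.append(m)
    return out
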