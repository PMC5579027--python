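"""Resistive-pulse event extraction from an ionic-current trace.

The pipeline is: zero-phase low-pass filtering and moving-median baseline
estimation (two passes, excluding detected event spans from the second), a
robust MAD-based noise estimate, threshold detection with hysteresis, and
per-event characterization (peak and plateau amplitudes, FWHM and
above-threshold durations, smoothed-derivative extrema).  Scatter gating in
amplitude-duration space removes noise triggers and aggregates.

The per-sample blockade is defined pointwise as a(t) = (I0(t) - I(t)) / I(t),
the exact Ohmic inversion equal to dR/R0; the event's scalar amplitude
dI/I_p is the mean blockade over the central half of the FWHM span (an
unbiased plateau estimate for well-developed pulses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import signal

__all__ = [
    "ConfigError",
    "CurrentTrace",
    "RPEvent",
    "preprocess",
    "noise_sigma",
    "detect_events",
    "characterize_event",
    "detect_and_characterize",
    "gate_events",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class CurrentTrace:
    """A sampled ionic-current recording.

    ``filtered_a`` and ``baseline_a`` are filled by :func:`preprocess`.
    Recorded timestamps are ``index * sample_period_s`` on this stream's own
    clock.
    """

    sample_period_s: float
    current_a: np.ndarray
    filtered_a: np.ndarray | None = None
    baseline_a: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sample_period_s > 0:
            raise ValueError("sample period must be positive")
        self.current_a = np.asarray(self.current_a, dtype=float)
        if not np.all(np.isfinite(self.current_a)):
            raise ValueError("current samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.current_a)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_period_s

    def blockade(self, indices=None) -> np.ndarray:
        """Per-sample relative blockade a = (I0 - I)/I on the filtered trace."""
        if self.filtered_a is None or self.baseline_a is None:
            raise ConfigError("trace must be preprocessed first")
        sl = slice(None) if indices is None else indices
        f = self.filtered_a[sl]
        return (self.baseline_a[sl] - f) / f


@dataclass
class RPEvent:
    """One resistive-pulse event.

    ``start``/``end`` delimit the padded analysis span (Python slice
    convention); ``core_start``/``core_end`` the above-threshold span.
    Amplitudes are dimensionless dI/I_p; durations in seconds.  ``extrema``
    is a list of (sample index, blockade value, "max"|"min") after
    persistence pruning.
    """

    start: int
    end: int
    core_start: int
    core_end: int
    sample_period_s: float
    baseline_i0_a: float = np.nan
    plateau_ip_a: float = np.nan
    amplitude: float = np.nan
    peak_amplitude: float = np.nan
    peak_index: int = -1
    fwhm_s: float = np.nan
    fwhm_span: tuple[float, float] | None = None
    threshold_duration_s: float = np.nan
    close_threshold_blockade: float = np.nan
    extrema: list[tuple[int, float, str]] = field(default_factory=list)
    truncated: bool = False
    blockade: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("event span must be non-empty")

    @property
    def time_peak_s(self) -> float:
        return self.peak_index * self.sample_period_s

    @property
    def anchor_time_s(self) -> float:
        """Time of the median-index sample of the above-threshold span
        (the 'middle-most data point' used for fine alignment)."""
        return ((self.core_start + self.core_end - 1) // 2) * self.sample_period_s

    def to_dict(self) -> dict:
        return {
            "start": int(self.start), "end": int(self.end),
            "core_start": int(self.core_start), "core_end": int(self.core_end),
            "time_peak_s": float(self.time_peak_s),
            "baseline_i0_a": float(self.baseline_i0_a),
            "plateau_ip_a": float(self.plateau_ip_a),
            "amplitude": float(self.amplitude),
            "peak_amplitude": float(self.peak_amplitude),
            "fwhm_s": float(self.fwhm_s),
            "threshold_duration_s": float(self.threshold_duration_s),
            "extrema": [[int(i), float(v), k] for i, v, k in self.extrema],
            "truncated": bool(self.truncated),
        }


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x).rolling(window, center=True, min_periods=1).median()
    return s.to_numpy()


def preprocess(trace: CurrentTrace, lowpass_hz: float | None = 10e3,
               detrend_window_s: float = 50e-3, k_exclude: float = 6.0) -> CurrentTrace:
    """Low-pass filter the trace and estimate a drift-following baseline.

    The filter is a zero-phase 4-pole Bessel (the patch-clamp standard:
    essentially no overshoot, so deep pulses do not ring through the
    detection threshold).  The baseline is a
    centred moving median; a second pass masks spans flagged as events
    (excursions beyond ``k_exclude`` robust sigmas) so deep pulses do not
    drag the baseline down.  Returns a new trace with ``filtered_a`` and
    ``baseline_a`` set.
    """
    fs = 1.0 / trace.sample_period_s
    x = trace.current_a
    if lowpass_hz is not None:
        if not 0 < lowpass_hz < fs / 2:
            raise ConfigError("low-pass cutoff must be below the Nyquist frequency")
        sos = signal.bessel(4, lowpass_hz, btype="low", fs=fs, output="sos",
                            norm="mag")
        filt = signal.sosfiltfilt(sos, x)
    else:
        filt = x.astype(float)

    window = int(round(detrend_window_s / trace.sample_period_s))
    if window < 10:
        raise ConfigError("detrend window must span at least 10 samples")
    baseline = _rolling_median(filt, window)

    # second pass: exclude event spans from the median
    dev = baseline - filt
    sigma = noise_sigma(dev)
    mask = dev > k_exclude * sigma
    if mask.any():
        masked = pd.Series(np.where(mask, np.nan, filt))
        baseline = masked.rolling(window, center=True, min_periods=1).median()
        baseline = baseline.interpolate(limit_direction="both").to_numpy()
    return replace(trace, filtered_a=filt, baseline_a=baseline)


def noise_sigma(deviation: np.ndarray) -> float:
    """Robust (MAD-based) noise scale of a deviation signal.

    Can be 0 for noiseless data; callers apply their own floors.
    """
    med = np.median(deviation)
    return float(1.4826 * np.median(np.abs(deviation - med)))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_events(trace: CurrentTrace, k: float = 6.0, hysteresis: float = 0.5,
                  min_duration_s: float = 0.0, max_duration_s: float = np.inf,
                  pad_s: float | None = None) -> list[RPEvent]:
    """Detect downward current excursions by thresholding with hysteresis.

    An event opens when the baseline-subtracted deviation exceeds
    ``k * sigma_hat`` (sigma_hat = MAD noise estimate on event-free spans)
    and closes when it falls back below ``hysteresis * k * sigma_hat``; two
    pulses whose excursions never drop below the closing threshold merge.
    Events outside the duration gates are discarded; surviving spans are
    padded by ``pad_s`` (default: 10 samples) for downstream amplitude work.
    """
    if trace.filtered_a is None or trace.baseline_a is None:
        raise ConfigError("trace must be preprocessed before detection")
    if not k > 0:
        raise ConfigError("k must be positive")
    dev = trace.baseline_a - trace.filtered_a
    sigma0 = noise_sigma(dev)
    quiet = dev < k * sigma0
    sigma = noise_sigma(dev[quiet]) if sigma0 > 0 and quiet.any() else sigma0
    # floor keeps noiseless traces detectable without tripping on numerical ripple
    sigma = max(sigma, 1e-9 * abs(float(np.median(trace.baseline_a))))

    open_thr = k * sigma
    close_thr = hysteresis * k * sigma
    above_close = dev > close_thr
    # contiguous runs above the closing threshold that contain an opening sample
    edges = np.diff(above_close.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above_close[0]:
        starts = np.concatenate([[0], starts])
    if above_close[-1]:
        ends = np.concatenate([ends, [len(dev)]])

    pad = int(round((pad_s / trace.sample_period_s))) if pad_s is not None else 10
    events: list[RPEvent] = []
    n_rejected = 0
    for s, e in zip(starts, ends):
        if not np.any(dev[s:e] > open_thr):
            continue
        dur = (e - s) * trace.sample_period_s
        if dur < min_duration_s or dur > max_duration_s:
            n_rejected += 1
            continue
        events.append(RPEvent(start=max(0, s - pad), end=min(len(dev), e + pad),
                              core_start=int(s), core_end=int(e),
                              sample_period_s=trace.sample_period_s,
                              threshold_duration_s=dur,
                              close_threshold_blockade=close_thr / float(np.median(trace.baseline_a))))
    if n_rejected:
        log.info("detect_events: %d spans rejected by duration gates", n_rejected)
    return events


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """Linearly interpolated first (rising) or last (falling) crossing time."""
    above = y >= level
    idx = np.nonzero(above)[0]
    if len(idx) == 0:
        return np.nan
    if rising:
        i = idx[0]
        if i == 0:
            return t[0]
        f = (level - y[i - 1]) / (y[i] - y[i - 1])
        return t[i - 1] + f * (t[i] - t[i - 1])
    i = idx[-1]
    if i == len(y) - 1:
        return t[-1]
    f = (level - y[i + 1]) / (y[i] - y[i + 1])
    return t[i + 1] - f * (t[i + 1] - t[i])


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    window = min(window, len(y) if len(y) % 2 else len(y) - 1)
    if window < 5:
        return y.copy()
    if window % 2 == 0:
        window -= 1
    return signal.savgol_filter(y, window, polyorder=2)


def _pruned_extrema(a_s: np.ndarray, prominence: float):
    """Alternating extrema of a smoothed signal with prominence pruning."""
    imax, _ = signal.find_peaks(a_s, prominence=prominence)
    imin, _ = signal.find_peaks(-a_s, prominence=prominence)
    ext = sorted([(int(i), float(a_s[i]), "max") for i in imax]
                 + [(int(i), float(a_s[i]), "min") for i in imin])
    # enforce strict alternation, keeping the more extreme of adjacent twins
    out = []
    for item in ext:
        if out and out[-1][2] == item[2]:
            keep_new = (item[1] > out[-1][1]) if item[2] == "max" else (item[1] < out[-1][1])
            if keep_new:
                out[-1] = item
        else:
            out.append(item)
    return out


def characterize_event(event: RPEvent, trace: CurrentTrace,
                       smoothing_window: int = 15,
                       extrema_prominence_sigma: float = 3.0) -> RPEvent:
    """Fill in amplitudes, durations and extrema for a detected span.

    Peak amplitude is the maximum of the Savitzky-Golay-smoothed blockade;
    the FWHM duration is the interpolated width at half that peak; the
    scalar amplitude is the mean blockade over the central half of the FWHM
    span.  Extrema are derivative sign changes of the smoothed blockade with
    prominence below ``extrema_prominence_sigma`` noise sigmas pruned.
    Events touching the trace boundary are flagged truncated.
    """
    a = trace.blockade(slice(event.start, event.end))
    a_s = _smooth(a, smoothing_window)
    t = (event.start + np.arange(len(a))) * trace.sample_period_s

    peak_rel = int(np.argmax(a_s))
    peak = float(a_s[peak_rel])
    half = peak / 2.0
    t_lo = _interp_crossing(t, a_s, half, rising=True)
    t_hi = _interp_crossing(t, a_s, half, rising=False)
    fwhm = t_hi - t_lo

    # plateau amplitude: mean blockade over the central half of the FWHM span
    t_mid_lo = t_lo + 0.25 * fwhm
    t_mid_hi = t_hi - 0.25 * fwhm
    central = (t >= t_mid_lo) & (t <= t_mid_hi)
    amplitude = float(np.mean(a[central])) if central.any() else peak

    # noise scale in blockade units; small relative floor for noiseless data
    dev = trace.baseline_a - trace.filtered_a
    sigma_a = noise_sigma(dev) / float(np.median(trace.filtered_a))
    prominence = max(extrema_prominence_sigma * sigma_a, 0.02 * peak)
    extrema = [(event.start + i, v, kind) for i, v, kind in
               _pruned_extrema(a_s, prominence)]

    i0 = float(np.mean(trace.baseline_a[event.start:event.end]))
    ip = i0 / (1.0 + amplitude)
    truncated = event.start == 0 or event.end == trace.n_samples or \
        np.isnan(t_lo) or np.isnan(t_hi)

    # anchor span: above-threshold run of the *smoothed* blockade containing
    # the peak (far less crossing jitter than the merely low-pass-filtered one)
    level = event.close_threshold_blockade
    if not np.isfinite(level):
        level = half
    core_start, core_end = event.core_start, event.core_end
    above = a_s >= level
    if above[peak_rel]:
        lo = peak_rel
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = peak_rel
        while hi < len(a_s) - 1 and above[hi + 1]:
            hi += 1
        core_start = event.start + lo
        core_end = event.start + hi + 1

    return replace(event, baseline_i0_a=i0, plateau_ip_a=ip, amplitude=amplitude,
                   peak_amplitude=peak, peak_index=event.start + peak_rel,
                   fwhm_s=fwhm, fwhm_span=(t_lo, t_hi), truncated=truncated,
                   extrema=extrema, blockade=a,
                   core_start=core_start, core_end=core_end)


def detect_and_characterize(trace: CurrentTrace, k: float = 6.0, hysteresis: float = 0.5,
                            min_duration_s: float = 0.0, max_duration_s: float = np.inf,
                            smoothing_window: int = 15) -> list[RPEvent]:
    events = detect_events(trace, k=k, hysteresis=hysteresis,
                           min_duration_s=min_duration_s, max_duration_s=max_duration_s)
    return [characterize_event(ev, trace, smoothing_window=smoothing_window)
            for ev in events]


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


def gate_events(events: list[RPEvent], amplitude_range=None, duration_range=None,
                polygon=None) -> list[RPEvent]:
    """Keep events inside all amplitude-duration gates.

    ``polygon`` is a sequence of (amplitude, duration_s) vertices; events
    inside the polygon are *kept*.  Counts removed per gate are logged.
    """
    out = events
    if amplitude_range is not None:
        lo, hi = amplitude_range
        kept = [e for e in out if lo <= e.amplitude <= hi]
        log.info("gate amplitude: removed %d", len(out) - len(kept))
        out = kept
    if duration_range is not None:
        lo, hi = duration_range
        kept = [e for e in out if lo <= e.fwhm_s <= hi]
        log.info("gate duration: removed %d", len(out) - len(kept))
        out = kept
    if polygon is not None:
        path = MplPath(np.asarray(polygon, dtype=float))
        pts = np.array([[e.amplitude, e.fwhm_s] for e in out]) if out else np.empty((0, 2))
        inside = path.contains_points(pts) if len(pts) else np.array([], dtype=bool)
        kept = [e for e, ok in zip(out, inside) if ok]
        log.info("gate polygon: removed %d", len(out) - len(kept))
        out = kept
    return out
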