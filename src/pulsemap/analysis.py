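"""Resistance maps and positional-dependence statistics.

A resistance map is a 2D histogram over channel coordinates whose bin values
are the mean instantaneous relative blockade dI/I_p measured whenever a
particle occupied that position — a spatial image of the channel's local
resistance.  The companion statistics resolve the axial profile (where the
pulse saturates relative to the entrance), the lateral dependence of
duration and amplitude (Poiseuille transport and the off-axis excess), the
amplitude-duration correlation, and the cavity/narrow amplitude ratio
against the sphere-in-cylinder prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import (
    ChannelGeometry,
    Particle,
    amplitude_ratio,
    equivalent_diameter,
)
from .rp import RPEvent
from .sync import MatchedEvent, central_amplitude

__all__ = [
    "ResistanceMap",
    "Profile1D",
    "build_map",
    "axial_profile",
    "fwhm_vs_entrance_check",
    "region_amplitudes",
    "lateral_stats",
    "fit_offaxis_alpha",
    "amp_duration_fit",
    "ratio_distribution",
]

log = logging.getLogger(__name__)


@dataclass
class ResistanceMap:
    """Binned mean blockade over (x_c, y_c); empty bins are NaN, never 0."""

    x_edges_um: np.ndarray
    y_edges_um: np.ndarray
    mean: np.ndarray      # shape (nx, ny)
    std: np.ndarray
    count: np.ndarray

    @property
    def x_centers_um(self) -> np.ndarray:
        return 0.5 * (self.x_edges_um[:-1] + self.x_edges_um[1:])

    @property
    def y_centers_um(self) -> np.ndarray:
        return 0.5 * (self.y_edges_um[:-1] + self.y_edges_um[1:])


@dataclass
class Profile1D:
    """Moving-window mean with a +/- 1 sigma band."""

    centers: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    count: np.ndarray


def _gather_samples(events: list[MatchedEvent], exclude_multiparticle: bool,
                    geom: ChannelGeometry | None):
    """Concatenate per-sample tuples, optionally dropping samples recorded
    while more than one particle occupied the channel."""
    if exclude_multiparticle and geom is not None:
        spans = []
        for ev in events:
            t_in = ev.im_event.times_s + ev.total_offset_s
            inside = (ev.im_event.x_c_um >= 0) & (ev.im_event.x_c_um <= geom.length_um)
            spans.append((t_in[inside].min(), t_in[inside].max()) if inside.any()
                         else (np.nan, np.nan))
    parts = []
    n_dropped = 0
    for idx, ev in enumerate(events):
        if ev.samples is None:
            continue
        s = ev.samples
        if exclude_multiparticle and geom is not None:
            keep = np.ones(len(s), dtype=bool)
            for jdx, (lo, hi) in enumerate(spans):
                if jdx == idx or not np.isfinite(lo):
                    continue
                keep &= ~((s["t"] >= lo) & (s["t"] <= hi))
            n_dropped += int((~keep).sum())
            s = s[keep]
        parts.append(s)
    if n_dropped:
        log.info("dropped %d multi-particle samples", n_dropped)
    if not parts:
        raise ValueError("no paired samples available")
    return np.concatenate(parts)


def build_map(events: list[MatchedEvent], bin_um: float = 1.0,
              extent=None, geom: ChannelGeometry | None = None,
              exclude_multiparticle: bool = True) -> ResistanceMap:
    """Accumulate all per-sample (x_c, y_c, blockade) tuples into a grid.

    ``extent`` is ((x_min, x_max), (y_min, y_max)) in µm; by default it
    spans the data.  Samples recorded while a second particle occupied the
    channel are excluded (they would imprint one particle's resistance onto
    the other's position).
    """
    if not events:
        raise ValueError("build_map needs at least one matched event")
    s = _gather_samples(events, exclude_multiparticle, geom)
    if extent is None:
        extent = ((s["x_um"].min(), s["x_um"].max()),
                  (s["y_um"].min(), s["y_um"].max()))
    (x0, x1), (y0, y1) = extent

    def _edges(lo, hi):
        if hi - lo < bin_um:  # degenerate extent (e.g. all on-axis): one bin
            mid = 0.5 * (lo + hi)
            lo, hi = mid - bin_um / 2.0, mid + bin_um / 2.0
        return np.arange(lo, hi + bin_um, bin_um)

    x_edges = _edges(x0, x1)
    y_edges = _edges(y0, y1)
    mean, _, _, _ = stats.binned_statistic_2d(
        s["x_um"], s["y_um"], s["blockade"], statistic="mean",
        bins=[x_edges, y_edges])
    std, _, _, _ = stats.binned_statistic_2d(
        s["x_um"], s["y_um"], s["blockade"], statistic="std",
        bins=[x_edges, y_edges])
    count, _, _, _ = stats.binned_statistic_2d(
        s["x_um"], s["y_um"], s["blockade"], statistic="count",
        bins=[x_edges, y_edges])
    return ResistanceMap(x_edges_um=x_edges, y_edges_um=y_edges,
                         mean=mean, std=std, count=count)


def _moving_profile(x: np.ndarray, v: np.ndarray, half_window: float,
                    min_count: int, step: float | None = None) -> Profile1D:
    step = half_window / 2.0 if step is None else step
    centers = np.arange(x.min(), x.max() + step, step)
    order = np.argsort(x)
    xs, vs = x[order], v[order]
    lo = np.searchsorted(xs, centers - half_window)
    hi = np.searchsorted(xs, centers + half_window)
    csum = np.concatenate([[0.0], np.cumsum(vs)])
    csq = np.concatenate([[0.0], np.cumsum(vs ** 2)])
    n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (csum[hi] - csum[lo]) / n
        var = (csq[hi] - csq[lo]) / n - mean ** 2
        std = np.sqrt(np.clip(var, 0.0, None))
    ok = n >= min_count
    return Profile1D(centers=centers[ok], mean=mean[ok], std=std[ok],
                     count=n[ok].astype(int))


def axial_profile(events: list[MatchedEvent], half_window_um: float = 1.0,
                  min_count: int = 5, geom: ChannelGeometry | None = None,
                  saturation_fraction: float = 0.99):
    """Moving mean (+/- 1 sigma) of blockade versus axial position.

    Also reports the entrance/exit amplitudes, the position of the profile
    maximum, and the saturation position: the first x_c at which the profile
    reaches ``saturation_fraction`` of its maximum (how far into the channel
    the pulse fully develops).
    """
    s = _gather_samples(events, False, None)
    prof = _moving_profile(s["x_um"], s["blockade"], half_window_um, min_count)
    i_max = int(np.argmax(prof.mean))
    a_max = float(prof.mean[i_max])
    sat = prof.mean >= saturation_fraction * a_max
    x_saturation = float(prof.centers[np.argmax(sat)]) if sat.any() else np.nan
    L = geom.length_um if geom is not None else None
    a_entrance = float(np.interp(0.0, prof.centers, prof.mean))
    a_exit = float(np.interp(L, prof.centers, prof.mean)) if L is not None else np.nan
    return {"profile": prof, "a_entrance": a_entrance, "a_exit": a_exit,
            "x_at_max_um": float(prof.centers[i_max]), "a_max": a_max,
            "x_saturation_um": x_saturation}


def fwhm_vs_entrance_check(events: list[MatchedEvent]) -> dict:
    """Blockade at the observed entrance/exit instants relative to the peak.

    Ratios near 0.5 mean the channel's physical entrance and exit coincide
    with the pulse's half-maximum crossings, supporting FWHM-based duration
    estimates over threshold-based ones.
    """
    r_in, r_out = [], []
    for ev in events:
        if ev.samples is None or not ev.im_event.complete:
            continue
        peak = ev.rp_event.peak_amplitude
        if not np.isfinite(peak) or peak <= 0:
            continue
        s = ev.samples
        # evaluate one frame period inside the channel: the crossing instant
        # itself sits on the (possibly discontinuous, filter-limited)
        # entrance step
        dt_frame = float(np.median(np.diff(ev.im_event.times_s))) if \
            len(ev.im_event.times_s) > 1 else 0.0
        t_entry = ev.im_event.t_entry_s + ev.total_offset_s + dt_frame
        t_exit = ev.im_event.t_exit_s + ev.total_offset_s - dt_frame
        a_entry = float(np.interp(t_entry, s["t"], s["blockade"]))
        a_exit = float(np.interp(t_exit, s["t"], s["blockade"]))
        r_in.append(a_entry / peak)
        r_out.append(a_exit / peak)
    return {"entrance_ratio": np.asarray(r_in), "exit_ratio": np.asarray(r_out)}


# ---------------------------------------------------------------------------
# region amplitudes and lateral statistics
# ---------------------------------------------------------------------------


def region_amplitudes(rp_event: RPEvent) -> dict:
    """Narrow and cavity amplitudes of a cavity-channel pulse.

    Requires the characteristic three-extrema morphology (blockade maximum
    in each narrow constriction, interior minimum in the cavity).  Each
    region amplitude is the median blockade of the samples on the proper
    side of the half-peak level — narrow plateaus: above-half samples
    outside the interior minimum's side spans; cavity plateau: below-half
    samples between the two maxima — which is position-blind and far less
    noise-biased than raw extremum values.  Assumes the cavity blockade
    stays below half the narrow blockade (true when the wide section is
    substantially wider than the narrow one).
    """
    maxima = [e for e in rp_event.extrema if e[2] == "max"]
    minima = [e for e in rp_event.extrema if e[2] == "min"]
    interior = [m for m in minima
                if any(a[0] < m[0] for a in maxima) and any(a[0] > m[0] for a in maxima)]
    if len(maxima) < 2 or not interior:
        raise ValueError("event lacks the two-maxima/one-interior-minimum cavity morphology")
    i_mid = min(interior, key=lambda m: m[1])[0]
    # narrow peaks = the dominant maximum on each side of the interior
    # minimum (robust to residual noise extrema inside the cavity plateau)
    i_lo = max((a for a in maxima if a[0] < i_mid), key=lambda a: a[1])[0]
    i_hi = max((a for a in maxima if a[0] > i_mid), key=lambda a: a[1])[0]
    a = rp_event.blockade
    if a is None:
        raise ValueError("event has no stored blockade samples")
    half = rp_event.peak_amplitude / 2.0
    rel_mid, rel_lo, rel_hi = (i - rp_event.start for i in (i_mid, i_lo, i_hi))

    def _median(seg: np.ndarray, above: bool) -> float:
        sel = seg[seg >= half] if above else seg[seg < half]
        if len(sel) == 0:
            raise ValueError("no samples on the requested side of the half-peak level")
        return float(np.median(sel))

    first = _median(a[:rel_mid], above=True)
    second = _median(a[rel_mid:], above=True)
    cavity = _median(a[rel_lo:rel_hi + 1], above=False)
    return {"narrow_first": first, "narrow_second": second,
            "narrow_mean": 0.5 * (first + second), "cavity": cavity}


def _event_scalars(events: list[MatchedEvent], region: str,
                   geom: ChannelGeometry | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y_mean, duration, amplitude) per event for the requested region."""
    ys, dts, amps = [], [], []
    for ev in events:
        if not ev.im_event.complete:
            continue
        if region == "whole":
            # synchronized events use the +/-50 um-of-centre averaging rule
            if ev.samples is not None and geom is not None:
                amp = central_amplitude(ev, geom)
            else:
                amp = ev.rp_event.amplitude
        else:
            try:
                reg = region_amplitudes(ev.rp_event)
            except ValueError:
                continue
            amp = reg["narrow_mean"] if region == "narrow" else reg["cavity"]
        ys.append(ev.im_event.y_mean_um)
        dts.append(ev.im_event.duration_s)
        amps.append(amp)
    return np.asarray(ys), np.asarray(dts), np.asarray(amps)


def lateral_stats(events: list[MatchedEvent], region: str = "whole",
                  half_window_um: float = 1.0, min_count: int = 3,
                  density_bins: int = 25, geom: ChannelGeometry | None = None) -> dict:
    """Duration and amplitude versus mean lateral position.

    Returns moving-window profiles, a 2D point-density grid, and the
    quadratic coefficient of each profile (convexity diagnostic: positive
    for the Poiseuille duration profile and the off-axis amplitude excess in
    narrow sections, negative for the inverted cavity trend).
    """
    if region not in ("whole", "narrow", "cavity"):
        raise ValueError("region must be whole | narrow | cavity")
    ys, dts, amps = _event_scalars(events, region, geom)
    if len(ys) < 3:
        raise ValueError("too few complete events for lateral statistics")
    dur_prof = _moving_profile(ys, dts, half_window_um, min_count)
    amp_prof = _moving_profile(ys, amps, half_window_um, min_count)
    dens, ye, ae = np.histogram2d(ys, amps, bins=density_bins)

    def _quad_coeff(x, v):
        if len(np.unique(x)) < 3:
            return np.nan, np.nan
        coeffs, cov = np.polyfit(x, v, 2, cov=True)
        return float(coeffs[0]), float(np.sqrt(cov[0, 0]))

    qd, qd_err = _quad_coeff(ys, dts)
    qa, qa_err = _quad_coeff(ys, amps)
    return {"y_um": ys, "duration_s": dts, "amplitude": amps,
            "duration_profile": dur_prof, "amplitude_profile": amp_prof,
            "density": dens, "density_edges": (ye, ae),
            "duration_quad_coeff": qd, "duration_quad_err": qd_err,
            "amplitude_quad_coeff": qa, "amplitude_quad_err": qa_err}


def fit_offaxis_alpha(y_um: np.ndarray, amplitude: np.ndarray,
                      particle: Particle, geom: ChannelGeometry) -> tuple[float, float]:
    """Recover the off-axis coefficient alpha from (y_c, amplitude) data.

    Fits a = a0 (1 + alpha u^3) with u = y_norm d / D by linear least
    squares in (a0, a0 alpha); ``y_norm`` uses the radius normalization
    clipped to the accessible range.  Returns (alpha, a0).
    """
    d = particle.diameter_um
    D = equivalent_diameter(geom.min_width_um, geom.height_um)
    y_norm = np.minimum(2.0 * np.abs(y_um) / D, (D - d) / D)
    u3 = (y_norm * d / D) ** 3
    X = np.column_stack([np.ones_like(u3), u3])
    coef, *_ = np.linalg.lstsq(X, amplitude, rcond=None)
    a0, slope = coef
    return float(slope / a0), float(a0)


def amp_duration_fit(events: list[MatchedEvent], region: str = "whole",
                     geom: ChannelGeometry | None = None):
    """Ordinary least squares of amplitude on duration.

    Returns a :class:`scipy.stats.linregress` result (slope, intercept,
    rvalue, ...).  Degenerate inputs (all-identical points) are flagged by
    raising ``ValueError``.
    """
    _, dts, amps = _event_scalars(events, region, geom)
    if len(dts) < 10:
        raise ValueError("need at least 10 events for a meaningful fit")
    if np.allclose(dts, dts[0]) or np.allclose(amps, amps[0]):
        raise ValueError("degenerate amplitude-duration data (no variance)")
    return stats.linregress(dts, amps)


def ratio_distribution(events, geom: ChannelGeometry, particle: Particle,
                       convention: str = "mean") -> dict:
    """Per-event cavity/narrow amplitude ratios with the model prediction.

    ``events`` may be RP events or matched events from a cavity channel.
    ``convention`` selects the narrow reference: "mean" of the two blockade
    maxima (lower variance) or "entrance" (first maximum only).  The theory
    overlay is the local-resistance ratio at the equal-area equivalent
    diameters.
    """
    if geom.kind != "cavity":
        raise ValueError("ratio_distribution requires a cavity channel")
    if convention not in ("mean", "entrance"):
        raise ValueError("convention must be 'mean' or 'entrance'")
    ratios = []
    n_skipped = 0
    for ev in events:
        rp_ev = ev.rp_event if isinstance(ev, MatchedEvent) else ev
        try:
            reg = region_amplitudes(rp_ev)
        except ValueError:
            n_skipped += 1
            continue
        ref = reg["narrow_mean"] if convention == "mean" else reg["narrow_first"]
        ratios.append(reg["cavity"] / ref)
    if not ratios:
        raise ValueError("no event shows the cavity morphology "
                         "(straight-channel events have no interior minimum)")
    if n_skipped:
        log.info("ratio_distribution: skipped %d events without cavity morphology",
                 n_skipped)
    d = particle.diameter_um
    d_wide = equivalent_diameter(geom.width_wide_um, geom.height_um)
    d_narrow = equivalent_diameter(geom.width_narrow_um, geom.height_um)
    predicted = amplitude_ratio(d, d_wide, d_narrow)
    return {"ratios": np.asarray(ratios), "predicted": float(predicted)}
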