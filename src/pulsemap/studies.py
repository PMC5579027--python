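"""Canonical study conditions: the channel geometries and reference runs.

The channels mirror the systems the platform was built around: 10 µm
polystyrene beads in ~150 µm long, ~20 µm high PDMS channels — straight
widths 15/25/30 µm and cavity channels with 17.5/30 µm and 20/50 µm
narrow/wide widths — imaged at 50,000 fps with the current sampled at
250 kHz.  The run builders below fix the remaining free conditions
(recording length, event count, flow speed, noise level) at values chosen
once for each protocol; tests, examples and reproduction scripts all draw
from here so results refer to a single set of conditions.

Flow speeds are set so that transit times are a few milliseconds (as in
the experiments) while keeping channel occupancy low enough (~20%) for
median baseline tracking; runs that pack many events into one second use a
proportionally faster flow.
"""

from __future__ import annotations

from .geometry import ChannelGeometry, Particle, TheoryParams, equivalent_diameter, smythe_amplitude
from .simulate import AcquisitionModel, FlowModel, SimulationConfig, TransitionModel

__all__ = [
    "BEAD",
    "straight_geometry",
    "cavity_geometry",
    "max_offaxis_excess_percent",
    "onaxis_amplitude_config",
    "sync_config",
    "cavity_ratio_config",
    "lateral_config",
    "transition_config",
]

BEAD = Particle(10.0)

_STRAIGHT_WIDTHS = (15.0, 25.0, 30.0)
_CAVITY_WIDTHS = {"17.5/30": (17.5, 30.0), "20/50": (20.0, 50.0)}


def straight_geometry(width_um: float = 30.0, length_um: float = 150.0,
                      height_um: float = 20.0) -> ChannelGeometry:
    return ChannelGeometry.straight(length_um, width_um, height_um)


def cavity_geometry(name: str = "20/50", length_um: float = 150.0,
                    height_um: float = 20.0) -> ChannelGeometry:
    """Cavity channel with the wide section over the central third."""
    w_n, w_w = _CAVITY_WIDTHS[name]
    return ChannelGeometry.with_cavity(length_um, w_n, w_w, height_um,
                                       length_um / 3.0, 2.0 * length_um / 3.0)


def max_offaxis_excess_percent(alpha: float = 7.5,
                               widths_um=_STRAIGHT_WIDTHS,
                               height_um: float = 20.0,
                               particle: Particle = BEAD):
    """Largest predicted off-axis amplitude excess (%) over the straight
    channels, evaluated at the maximal accessible lateral displacement
    y_norm = (D - d)/D of the equal-area equivalent diameter."""
    d = particle.diameter_um
    excesses = {}
    for w in widths_um:
        D = equivalent_diameter(w, height_um)
        y_max = (D - d) / D
        excesses[w] = 100.0 * alpha * (y_max * d / D) ** 3
    return max(excesses.values()), excesses


# ---------------------------------------------------------------------------
# reference runs
# ---------------------------------------------------------------------------


def onaxis_amplitude_config(n_events: int = 100, snr: float = 20.0,
                            width_um: float = 30.0) -> SimulationConfig:
    """On-axis events in a straight channel at a given pulse SNR.

    The recording is sized for ~20% channel occupancy so the moving-median
    baseline stays uncontaminated.
    """
    geom = straight_geometry(width_um)
    a = smythe_amplitude(BEAD.diameter_um,
                         equivalent_diameter(width_um, geom.height_um),
                         geom.length_um)
    acq = AcquisitionModel(noise_sigma_a=a * 100e-9 / snr)
    return SimulationConfig(geometry=geom, particle=BEAD, acquisition=acq,
                            n_events=n_events, rate_per_s=None,
                            duration_s=0.03 * n_events, y0_mode="on-axis")


def sync_config(n_events: int = 100, clock_skew: float = 1e-5,
                stream_offset_s: float = 0.5, duration_s: float = 1.0) -> SimulationConfig:
    """Hybrid run for clock alignment: events packed into a short recording
    with a camera/DAQ clock offset and rate mismatch.  Flow is fast enough
    that 100 events fit in one second at low occupancy with inter-event
    gaps well above the coarse-matching tolerance."""
    geom = straight_geometry(30.0)
    acq = AcquisitionModel(noise_sigma_a=20e-12, clock_skew=clock_skew,
                           stream_offset_s=stream_offset_s)
    return SimulationConfig(geometry=geom, particle=BEAD, acquisition=acq,
                            flow=FlowModel(v_max_um_s=1.5e5),
                            n_events=n_events, rate_per_s=None,
                            duration_s=duration_s, y0_mode="uniform",
                            min_gap_s=4.1e-3)


def cavity_ratio_config(name: str = "20/50", n_events: int = 100) -> SimulationConfig:
    """On-axis cavity-channel events with noise sigma = a_narrow / 20."""
    geom = cavity_geometry(name)
    d_n = equivalent_diameter(geom.width_narrow_um, geom.height_um)
    d_w = equivalent_diameter(geom.width_wide_um, geom.height_um)
    l_wide = geom.cavity_end_um - geom.cavity_start_um
    denom = (geom.length_um - l_wide) / d_n ** 2 + l_wide / d_w ** 2
    a_narrow = BEAD.diameter_um ** 3 / d_n ** 4 \
        / (1.0 - 0.8 * (BEAD.diameter_um / d_n) ** 3) / denom
    acq = AcquisitionModel(noise_sigma_a=a_narrow * 100e-9 / 20.0)
    return SimulationConfig(geometry=geom, particle=BEAD, acquisition=acq,
                            n_events=n_events, rate_per_s=None,
                            duration_s=0.04 * n_events, y0_mode="on-axis")


def lateral_config(alpha: float, n_events: int = 300,
                   width_um: float = 25.0) -> SimulationConfig:
    """Uniform-lateral-position hybrid run for Poiseuille/off-axis profiles.

    The 25 µm channel is used because its full geometric lateral range maps
    inside the accessible range of the equivalent-diameter description, so
    the off-axis model applies without clipping.
    """
    geom = straight_geometry(width_um)
    acq = AcquisitionModel(noise_sigma_a=20e-12)
    return SimulationConfig(geometry=geom, particle=BEAD, acquisition=acq,
                            flow=FlowModel(v_max_um_s=1.5e5),
                            theory=TheoryParams(alpha=alpha),
                            n_events=n_events, rate_per_s=None,
                            duration_s=n_events / 150.0, y0_mode="uniform",
                            min_gap_s=1e-3, margin_um=15.0,
                            approach_fraction=0.6)


def transition_config(n_events: int = 20,
                      transition_length_um: float = 15.0) -> SimulationConfig:
    """Noiseless on-axis run resolving the entrance/exit transition zones."""
    geom = straight_geometry(30.0)
    acq = AcquisitionModel(noise_sigma_a=0.0, pixel_noise_sigma=0.0)
    trans = TransitionModel(transition_length_um=transition_length_um)
    return SimulationConfig(geometry=geom, particle=BEAD, acquisition=acq,
                            transition=trans, flow=FlowModel(v_max_um_s=1e5),
                            n_events=n_events, rate_per_s=None,
                            duration_s=0.03 * n_events, y0_mode="on-axis")
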