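"""Physics-based simulator of synchronized current traces and camera frames.

The generator emulates a microfluidic resistive-pulse experiment with
simultaneous high-speed imaging: 10 µm polystyrene beads advected by
pressure-driven flow through straight or cavity PDMS channels
(~150 µm long, ~20 µm high), with the ionic current sampled every 4 µs and
frames captured at 50,000 fps with 5 µs exposure.

Model summary
-------------
* Flow is plane Poiseuille in the width dimension only (the channel height is
  comparable to the bead diameter, constraining vertical motion); particles
  follow streamlines, so their relative lateral position ``2 y / w(x)`` is
  constant through the channel and the axial speed in a section of width
  ``w`` is ``v_max * (w_narrow / w) * (1 - (2 y0 / w_narrow)^2)`` (2D
  continuity across width changes).
* The instantaneous blockade is a separable product of (i) the local
  resistance increase (sphere-in-cylinder model at the local equivalent
  diameter) divided by the whole-channel series resistance, (ii) the
  empirical off-axis excess factor in straight/narrow sections, and (iii) an
  entrance/exit envelope: a cubic smoothstep ramp of length ``l_t`` inside
  each end and an exponential access-resistance decay outside.
* The recorded current is the exact Ohm inversion
  ``I = I0 (1 + drift) / (1 + a)`` plus white Gaussian noise; the current
  stream's recorded timestamps run on a clock with a relative rate error
  ``epsilon`` and a global offset relative to the camera clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    ChannelFrame,
    ChannelGeometry,
    Particle,
    TheoryParams,
    channel_to_pixel,
    equivalent_diameter,
    make_frame,
    width_profile,
)
from .rp import CurrentTrace

__all__ = [
    "FlowModel",
    "AcquisitionModel",
    "TransitionModel",
    "TruthRecord",
    "Trajectory",
    "SimulationConfig",
    "Dataset",
    "simulate_trajectory",
    "ground_truth_amplitude",
    "synthesize_current",
    "default_camera",
    "render_frames",
    "generate_dataset",
]


@dataclass(frozen=True)
class FlowModel:
    """Pressure-driven flow: parabolic (Poiseuille-like) profile across the
    channel width, no lateral drift (particles follow streamlines)."""

    v_max_um_s: float = 5e4
    profile_exponent: int = 2
    lateral_drift: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_max_um_s > 0:
            raise ValueError("v_max must be positive")
        if self.profile_exponent != 2 or self.lateral_drift != 0.0:
            raise ValueError("only the parabolic, zero-drift flow model is supported")


@dataclass(frozen=True)
class AcquisitionModel:
    """Clocks, electronics and camera parameters of the two streams.

    Both instruments record the same physical interval but label it with
    independent clocks: a current sample recorded at timestamp ``tau``
    occurred at true time ``tau * (1 + clock_skew)``, while frame ``j``
    (true time ``j * frame_period``) carries the recorded timestamp
    ``j * frame_period + stream_offset_s``.
    """

    current_sample_period_s: float = 4e-6
    frame_period_s: float = 20e-6
    exposure_s: float = 5e-6
    clock_skew: float = 0.0
    stream_offset_s: float = 0.0
    baseline_current_a: float = 100e-9
    noise_sigma_a: float = 20e-12
    drift_amplitude: float = 0.0
    drift_timescale_s: float = 5.0
    um_per_px: float = 1.0
    background_level: float = 180.0
    particle_depth: float = 120.0
    pixel_noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        if min(self.current_sample_period_s, self.frame_period_s, self.exposure_s) <= 0:
            raise ValueError("periods must be positive")
        if self.noise_sigma_a < 0 or self.pixel_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if abs(self.clock_skew) >= 1e-3:
            raise ValueError("|clock_skew| must be below 1e-3")


@dataclass(frozen=True)
class TransitionModel:
    """Entrance/exit transition and access-resistance model.

    ``transition_length_um`` is the in-channel ramp length over which the
    blockade rises from the access level to its fully developed value;
    ``access_fraction`` is the blockade fraction right at the channel mouth;
    ``access_decay_um`` the exponential decay length outside.  The optional
    ``cavity_radial_mode = "suppressed-near-wall"`` applies a phenomenological
    cosine taper to the cavity blockade for off-axis passages (magnitude in
    [0, 1]); the default is no radial dependence in the cavity.
    """

    transition_length_um: float = 15.0
    access_fraction: float = 0.5
    access_decay_um: float = 10.0
    cavity_edge_blend_um: float = 6.0
    cavity_radial_mode: str = "none"
    cavity_radial_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.transition_length_um < 0:
            raise ValueError("transition length must be non-negative")
        if not self.access_decay_um > 0:
            raise ValueError("access decay length must be positive")
        if not 0 <= self.access_fraction <= 1:
            raise ValueError("access fraction must be in [0, 1]")
        if self.cavity_edge_blend_um < 0:
            raise ValueError("cavity edge blend length must be non-negative")
        if self.cavity_radial_mode not in ("none", "suppressed-near-wall"):
            raise ValueError("unknown cavity radial mode")
        if not 0 <= self.cavity_radial_magnitude <= 1:
            raise ValueError("cavity radial magnitude must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated translocation (true-clock times)."""

    index: int
    y0_um: float
    t_entry_s: float
    t_exit_s: float
    duration_s: float

    def to_dict(self) -> dict:
        return {"index": self.index, "y0_um": self.y0_um, "t_entry_s": self.t_entry_s,
                "t_exit_s": self.t_exit_s, "duration_s": self.duration_s}


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Piecewise-linear x(t) path of one particle plus its streamline y(x)."""

    geom: ChannelGeometry
    y0_um: float
    t_breaks_s: np.ndarray
    x_breaks_um: np.ndarray

    @property
    def t_start_s(self) -> float:
        return float(self.t_breaks_s[0])

    @property
    def t_end_s(self) -> float:
        return float(self.t_breaks_s[-1])

    @property
    def t_entry_s(self) -> float:
        return float(np.interp(0.0, self.x_breaks_um, self.t_breaks_s))

    @property
    def t_exit_s(self) -> float:
        return float(np.interp(self.geom.length_um, self.x_breaks_um, self.t_breaks_s))

    @property
    def duration_s(self) -> float:
        return self.t_exit_s - self.t_entry_s

    def lateral_position(self, x_um):
        """Streamline y(x): the lateral offset scales with the local width."""
        w = np.asarray(width_profile(self.geom, x_um), dtype=float)
        w_ref = self.geom.min_width_um
        scale = np.where(np.isfinite(w), w / w_ref, 1.0)
        return self.y0_um * scale

    def position(self, t_s):
        """(x_c, y_c) in µm at true time(s) ``t_s`` (clamped to the path)."""
        x = np.interp(t_s, self.t_breaks_s, self.x_breaks_um)
        return x, self.lateral_position(x)


def _sections(geom: ChannelGeometry):
    """(x0, x1, width) section list of the channel interior."""
    if geom.kind == "straight":
        return [(0.0, geom.length_um, geom.width_um)]
    return [(0.0, geom.cavity_start_um, geom.width_narrow_um),
            (geom.cavity_start_um, geom.cavity_end_um, geom.width_wide_um),
            (geom.cavity_end_um, geom.length_um, geom.width_narrow_um)]


def simulate_trajectory(geom: ChannelGeometry, flow: FlowModel, y0_um: float,
                        t_entry_s: float, particle: Particle | None = None,
                        margin_um: float = 25.0,
                        approach_fraction: float = 0.3) -> Trajectory:
    """Advect one particle along its streamline through the channel.

    ``y0_um`` is the lateral offset in the narrowest section; ``t_entry_s``
    the true time at which the particle crosses the entrance plane x_c = 0.
    The path extends ``margin_um`` beyond both ends at a reduced approach
    speed (``approach_fraction`` of the adjacent in-channel speed).
    """
    w_ref = geom.min_width_um
    if particle is not None:
        y_max = (w_ref - particle.diameter_um) / 2.0
        if abs(y0_um) >= y_max:
            raise ValueError(f"|y0| = {abs(y0_um)} µm outside accessible range (< {y_max} µm)")
    u0 = 2.0 * y0_um / w_ref
    if abs(u0) >= 1.0:
        raise ValueError("y0 outside the channel half-width")
    profile = 1.0 - u0 ** 2

    xs = [-margin_um]
    speeds = []
    v_entry = flow.v_max_um_s * (w_ref / _sections(geom)[0][2]) * profile
    xs.append(0.0)
    speeds.append(approach_fraction * v_entry)
    for (x0, x1, w) in _sections(geom):
        xs.append(x1)
        speeds.append(flow.v_max_um_s * (w_ref / w) * profile)
    v_exit_section = speeds[-1]
    xs.append(geom.length_um + margin_um)
    speeds.append(approach_fraction * v_exit_section)

    xs = np.asarray(xs)
    dts = np.diff(xs) / np.asarray(speeds)
    t_at_entry_index = 1  # xs[1] == 0.0
    t_breaks = np.concatenate([[0.0], np.cumsum(dts)])
    t_breaks += t_entry_s - t_breaks[t_at_entry_index]
    return Trajectory(geom=geom, y0_um=y0_um, t_breaks_s=t_breaks, x_breaks_um=xs)


# ---------------------------------------------------------------------------
# blockade model
# ---------------------------------------------------------------------------


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def ground_truth_amplitude(geom: ChannelGeometry, particle: Particle, x_um, y_um,
                           theory: TheoryParams = TheoryParams(),
                           transition: TransitionModel = TransitionModel()):
    """Instantaneous relative blockade a = dR/R0 at particle position (x, y).

    Separable product of the local sphere-in-cylinder term (at the local
    equivalent diameter), the off-axis excess in straight/narrow sections,
    and the entrance/exit transition envelope.  Vectorized over positions.
    """
    x = np.atleast_1d(np.asarray(x_um, dtype=float))
    y = np.atleast_1d(np.asarray(y_um, dtype=float))
    d = particle.diameter_um
    h = geom.height_um
    L = geom.length_um

    # R0 ~ sum_i L_i / D_i^2 (series integral over the width profile)
    denom = sum((x1 - x0) / equivalent_diameter(w, h) ** 2 for (x0, x1, w) in _sections(geom))

    def _base(w):
        D = equivalent_diameter(w, h)
        return d ** 3 / D ** 4 / (1.0 - 0.8 * (d / D) ** 3) / denom

    def _off_narrow(w, y_loc):
        D = equivalent_diameter(w, h)
        y_norm = np.minimum(2.0 * np.abs(y_loc) / D, (D - d) / D)
        return 1.0 + theory.alpha * (y_norm * d / D) ** 3

    if geom.kind == "straight":
        base = np.full_like(x, _base(geom.width_um))
        off = _off_narrow(geom.width_um, y)
    else:
        # blend smoothly across the cavity edges: the field (and hence the
        # local blockade) adjusts over a finite length, not a step
        w_n, w_w = geom.width_narrow_um, geom.width_wide_um
        b = transition.cavity_edge_blend_um
        if b > 0:
            up = _smoothstep((x - (geom.cavity_start_um - b / 2.0)) / b)
            down = _smoothstep(((geom.cavity_end_um + b / 2.0) - x) / b)
            blend = np.minimum(up, down)
        else:
            blend = ((x >= geom.cavity_start_um) & (x <= geom.cavity_end_um)).astype(float)
        base = _base(w_n) + (_base(w_w) - _base(w_n)) * blend
        # streamline-equivalent narrow-section offset for the off-axis term
        w_loc_abrupt = np.asarray(width_profile(geom, np.clip(x, 0.0, L)), dtype=float)
        y0_eq = y * w_n / w_loc_abrupt
        off_n = _off_narrow(w_n, y0_eq)
        if transition.cavity_radial_mode == "suppressed-near-wall":
            y_rel = np.clip(2.0 * np.abs(y) / w_loc_abrupt, 0.0, 1.0)
            off_c = 1.0 - transition.cavity_radial_magnitude * 0.5 * (1.0 - np.cos(np.pi * y_rel))
        else:
            off_c = np.ones_like(x)
        off = off_n * (1.0 - blend) + off_c * blend

    # transition envelope
    inside = (x >= 0.0) & (x <= L)
    s = np.minimum(x, L - x)
    lt = transition.transition_length_um
    af = transition.access_fraction
    if lt > 0:
        env_in = af + (1.0 - af) * _smoothstep(s / lt)
    else:
        env_in = np.ones_like(x)
    dist_out = np.where(x < 0, -x, x - L)
    env_out = af * np.exp(-np.clip(dist_out, 0.0, None) / transition.access_decay_um)
    env = np.where(inside, env_in, env_out)

    a = base * off * env
    return a if np.ndim(x_um) else float(a[0])


# ---------------------------------------------------------------------------
# current stream
# ---------------------------------------------------------------------------


def synthesize_current(geom: ChannelGeometry, particle: Particle,
                       trajectories: list[Trajectory], acq: AcquisitionModel,
                       theory: TheoryParams = TheoryParams(),
                       transition: TransitionModel = TransitionModel(),
                       duration_s: float = 1.0,
                       rng: np.random.Generator | None = None) -> tuple[CurrentTrace, list[TruthRecord]]:
    """Synthesize the recorded current trace for a set of trajectories.

    Recorded sample k carries timestamp ``k * dt`` on the current-stream
    clock; the physical state is evaluated at the corresponding true time
    ``k * dt * (1 + skew)``.  Returns the trace and one ground-truth record
    per trajectory.
    """
    dt = acq.current_sample_period_s
    n = int(round(duration_s / dt))
    tau = np.arange(n) * dt
    t_true = tau * (1.0 + acq.clock_skew)

    a = np.zeros(n)
    for traj in trajectories:
        i0 = int(np.searchsorted(t_true, traj.t_start_s))
        i1 = int(np.searchsorted(t_true, traj.t_end_s))
        if i1 <= i0:
            continue
        x, y = traj.position(t_true[i0:i1])
        a[i0:i1] += ground_truth_amplitude(geom, particle, x, y, theory, transition)

    i0_t = acq.baseline_current_a
    drift = acq.drift_amplitude * np.sin(2.0 * np.pi * t_true / acq.drift_timescale_s) \
        if acq.drift_amplitude else 0.0
    current = i0_t * (1.0 + drift) / (1.0 + a)
    if acq.noise_sigma_a > 0:
        if rng is None:
            rng = np.random.default_rng()
        current = current + rng.normal(0.0, acq.noise_sigma_a, size=n)

    trace = CurrentTrace(sample_period_s=dt, current_a=current)
    truth = [TruthRecord(index=i, y0_um=traj.y0_um, t_entry_s=traj.t_entry_s,
                         t_exit_s=traj.t_exit_s, duration_s=traj.duration_s)
             for i, traj in enumerate(trajectories)]
    return trace, truth


# ---------------------------------------------------------------------------
# imaging stream
# ---------------------------------------------------------------------------


def default_camera(geom: ChannelGeometry, acq: AcquisitionModel,
                   margin_um: float = 25.0, pad_um: float = 10.0):
    """Camera model for the synthetic microscope: channel axis along image x.

    Returns the channel's pixel frame and the image shape ``(ny, nx)``.
    """
    s = acq.um_per_px
    nx = int(math.ceil((geom.length_um + 2 * margin_um) / s))
    ny = int(math.ceil((geom.max_width_um + 2 * pad_um) / s))
    if ny % 2 == 0:
        ny += 1  # odd height -> integer-pixel channel axis
    origin = np.array([margin_um / s, (ny - 1) / 2.0])
    w_ent = _sections(geom)[0][2]
    w_exit = _sections(geom)[-1][2]
    ent = [origin + np.array([0.0, sgn * w_ent / 2.0 / s]) for sgn in (-1, 1)]
    exi = [origin + np.array([geom.length_um / s, sgn * w_exit / 2.0 / s]) for sgn in (-1, 1)]
    frame = make_frame(ent, exi, geom.length_um)
    return frame, (ny, nx)


def _draw_disk(img: np.ndarray, cx: float, cy: float, r_px: float, depth: float) -> None:
    """Subtract an anti-aliased dark disk centred at pixel (cx, cy) in place."""
    ny, nx = img.shape
    x0 = max(int(math.floor(cx - r_px - 1)), 0)
    x1 = min(int(math.ceil(cx + r_px + 2)), nx)
    y0 = max(int(math.floor(cy - r_px - 1)), 0)
    y1 = min(int(math.ceil(cy + r_px + 2)), ny)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
    img[y0:y1, x0:x1] -= depth * coverage


def render_frames(trajectories: list[Trajectory], geom: ChannelGeometry,
                  acq: AcquisitionModel, camera: ChannelFrame,
                  image_shape: tuple[int, int], frame_indices,
                  particle: Particle = Particle(10.0),
                  noise_seed: int | None = None):
    """Render grayscale frames for the given frame indices.

    Each frame is the uniform bright background plus per-pixel Gaussian
    noise, with an anti-aliased dark disk at every particle position taken at
    the frame's mid-exposure true time.  Recorded frame timestamps carry the
    camera clock (``j * frame_period + stream_offset``); noise is seeded per
    noise block so frames are reproducible regardless of chunking.  Returns
    (frames uint8, recorded timestamps).
    """
    frame_indices = np.asarray(frame_indices, dtype=int)
    ny, nx = image_shape
    t_frame_true = frame_indices * acq.frame_period_s
    timestamps = t_frame_true + acq.stream_offset_s
    t_mid = t_frame_true + acq.exposure_s / 2.0
    r_px = particle.diameter_um / 2.0 / acq.um_per_px

    stack = np.full((len(frame_indices), ny, nx), float(acq.background_level),
                    dtype=np.float32)
    if acq.pixel_noise_sigma > 0 and len(frame_indices):
        # noise drawn in fixed blocks of frames, seeded per block, so a
        # frame's noise is identical however the rendering is chunked
        block = 1024
        seed0 = noise_seed if noise_seed is not None else 0
        contiguous = len(frame_indices) == 1 or np.all(np.diff(frame_indices) == 1)
        for b in range(int(frame_indices.min()) // block,
                       int(frame_indices.max()) // block + 1):
            sel = (frame_indices >= b * block) & (frame_indices < (b + 1) * block)
            if not sel.any():
                continue
            rng = np.random.default_rng((seed0, b))
            noise = rng.standard_normal((block, ny, nx), dtype=np.float32)
            noise *= acq.pixel_noise_sigma
            if contiguous:
                o = int(np.argmax(sel))
                idx = frame_indices[sel] - b * block
                stack[o:o + len(idx)] += noise[idx[0]:idx[-1] + 1]
            else:
                stack[sel] += noise[frame_indices[sel] - b * block]

    if trajectories:
        starts = np.array([tr.t_start_s for tr in trajectories])
        ends = np.array([tr.t_end_s for tr in trajectories])
        for out_i, t in enumerate(t_mid):
            for k in np.nonzero((starts <= t) & (ends >= t))[0]:
                x, y = trajectories[k].position(t)
                cx, cy = channel_to_pixel(x, y, camera)
                _draw_disk(stack[out_i], float(cx), float(cy), r_px, acq.particle_depth)
    np.clip(stack, 0, 255, out=stack)
    frames = stack.astype(np.uint8)
    return frames, timestamps


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording."""

    geometry: ChannelGeometry
    particle: Particle = Particle(10.0)
    flow: FlowModel = FlowModel()
    acquisition: AcquisitionModel = AcquisitionModel()
    transition: TransitionModel = TransitionModel()
    theory: TheoryParams = TheoryParams()
    duration_s: float = 1.0
    n_events: int | None = None
    rate_per_s: float | None = 100.0
    min_gap_s: float = 2e-3
    y0_mode: str = "uniform"   # "uniform" | "on-axis"
    y0_fill: float = 1.0
    margin_um: float = 25.0
    approach_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_events is None and self.rate_per_s is None:
            raise ValueError("one of n_events or rate_per_s is required")
        if self.y0_mode not in ("uniform", "on-axis"):
            raise ValueError("y0_mode must be 'uniform' or 'on-axis'")
        if not 0 < self.y0_fill <= 1:
            raise ValueError("y0_fill must be in (0, 1]")
        if self.particle.diameter_um >= self.geometry.min_width_um:
            raise ValueError("particle larger than the narrowest channel width")


@dataclass
class Dataset:
    """An in-memory synthetic recording with its ground truth.

    Frames are rendered on demand (``frames(j0, j1)``) so long 50 kfps
    recordings never have to be materialized at once.
    """

    config: SimulationConfig
    seed: int
    camera: ChannelFrame
    image_shape: tuple[int, int]
    trace: CurrentTrace
    truth: list[TruthRecord]
    trajectories: list[Trajectory]
    n_frames: int
    frame_noise_seed: int

    def frames(self, j0: int = 0, j1: int | None = None):
        j1 = self.n_frames if j1 is None else min(j1, self.n_frames)
        return render_frames(self.trajectories, self.config.geometry,
                             self.config.acquisition, self.camera, self.image_shape,
                             np.arange(j0, j1), particle=self.config.particle,
                             noise_seed=self.frame_noise_seed)

    def template_frame(self):
        """A particle-free frame (independent noise realization)."""
        frames, _ = render_frames([], self.config.geometry, self.config.acquisition,
                                  self.camera, self.image_shape, [self.n_frames + 1],
                                  particle=self.config.particle,
                                  noise_seed=self.frame_noise_seed)
        return frames[0]


def _draw_entry_times(cfg: SimulationConfig, max_event_span_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Entry times with non-overlapping channel occupancy.

    Fixed-count mode places events on a jittered grid (guaranteeing the
    requested count); rate mode draws exponential gaps thinned by the
    refractory span (hard-core Poisson process).
    """
    edge = max_event_span_s + cfg.min_gap_s
    if cfg.n_events is not None:
        usable = cfg.duration_s - 2 * edge
        slot = usable / cfg.n_events
        if slot < max_event_span_s + cfg.min_gap_s:
            raise ValueError("requested event count does not fit in the recording duration")
        jitter_half = max(0.0, (slot - max_event_span_s - cfg.min_gap_s) / 2.0)
        centers = edge + (np.arange(cfg.n_events) + 0.5) * slot
        return centers + rng.uniform(-jitter_half, jitter_half, size=cfg.n_events)
    times = []
    t = edge + rng.exponential(1.0 / cfg.rate_per_s)
    while t < cfg.duration_s - edge:
        times.append(t)
        t += max_event_span_s + cfg.min_gap_s + rng.exponential(1.0 / cfg.rate_per_s)
    return np.asarray(times)


def generate_dataset(config: SimulationConfig, seed: int) -> Dataset:
    """Generate a fully reproducible synthetic recording.

    All stochastic draws (arrival times, lateral offsets, current noise,
    pixel noise) derive from a single integer seed in a documented order:
    one child stream each for arrivals, lateral offsets, trace noise and
    frame noise.
    """
    ss = np.random.SeedSequence(seed)
    rng_arrivals, rng_y0, rng_trace, ss_frames = \
        [np.random.default_rng(c) for c in ss.spawn(3)] + [ss.spawn(1)[0]]
    frame_noise_seed = int(ss_frames.generate_state(1)[0] % (2 ** 31))

    geom, particle = config.geometry, config.particle
    y_max = config.y0_fill * (geom.min_width_um - particle.diameter_um) / 2.0

    # worst-case event span (slowest streamline) for occupancy bookkeeping
    y_worst = y_max if config.y0_mode == "uniform" else 0.0
    worst = simulate_trajectory(geom, config.flow, 0.999 * y_worst if y_worst else 0.0,
                                0.0, margin_um=config.margin_um,
                                approach_fraction=config.approach_fraction)
    max_span = worst.t_end_s - worst.t_start_s

    entries = _draw_entry_times(config, max_span, rng_arrivals)
    if config.y0_mode == "uniform":
        y0s = rng_y0.uniform(-y_max, y_max, size=len(entries))
    else:
        y0s = np.zeros(len(entries))

    trajectories = [simulate_trajectory(geom, config.flow, y0, t, particle=particle,
                                        margin_um=config.margin_um,
                                        approach_fraction=config.approach_fraction)
                    for y0, t in zip(y0s, entries)]

    trace, truth = synthesize_current(geom, particle, trajectories, config.acquisition,
                                      config.theory, config.transition,
                                      duration_s=config.duration_s, rng=rng_trace)
    camera, image_shape = default_camera(geom, config.acquisition,
                                         margin_um=config.margin_um)
    n_frames = int(round(config.duration_s / config.acquisition.frame_period_s))
    return Dataset(config=config, seed=seed, camera=camera, image_shape=image_shape,
                   trace=trace, truth=truth, trajectories=trajectories,
                   n_frames=n_frames, frame_noise_seed=frame_noise_seed)
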