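"""Simulator physics: trajectories, blockade ground truth, clocks, frames."""

import numpy as np
import pytest
from scipy import stats

from pulsemap.geometry import (
    ChannelGeometry,
    Particle,
    TheoryParams,
    equivalent_diameter,
    smythe_amplitude,
    to_channel_coords,
)
from pulsemap.imaging import subtract_template, threshold_and_label
from pulsemap.simulate import (
    AcquisitionModel,
    FlowModel,
    SimulationConfig,
    TransitionModel,
    default_camera,
    generate_dataset,
    ground_truth_amplitude,
    render_frames,
    simulate_trajectory,
    synthesize_current,
)

BEAD = Particle(10.0)
STRAIGHT = ChannelGeometry.straight(150, 30, 20)
CAVITY = ChannelGeometry.with_cavity(150, 20, 50, 20, 50, 100)


class TestTrajectories:
    def test_centerline_duration(self):
        tr = simulate_trajectory(STRAIGHT, FlowModel(v_max_um_s=5e4), 0.0, 0.0)
        assert tr.duration_s == pytest.approx(150 / 5e4, rel=1e-12)

    def test_lateral_symmetry_and_slowdown(self):
        flow = FlowModel(v_max_um_s=5e4)
        on = simulate_trajectory(STRAIGHT, flow, 0.0, 0.0)
        plus = simulate_trajectory(STRAIGHT, flow, 8.0, 0.0, particle=BEAD)
        minus = simulate_trajectory(STRAIGHT, flow, -8.0, 0.0, particle=BEAD)
        assert plus.duration_s == pytest.approx(minus.duration_s, rel=1e-12)
        assert plus.duration_s > on.duration_s
        # parabolic profile: T(y)/T(0) = 1 / (1 - (2y/w)^2)
        assert plus.duration_s / on.duration_s == pytest.approx(
            1 / (1 - (16 / 30) ** 2), rel=1e-12)

    def test_wall_contact_rejected(self):
        with pytest.raises(ValueError):
            simulate_trajectory(STRAIGHT, FlowModel(), 10.0, 0.0, particle=BEAD)

    def test_flux_conservation_in_cavity(self):
        """Centerline speed in the cavity is v_narrow * w_narrow / w_wide."""
        tr = simulate_trajectory(CAVITY, FlowModel(v_max_um_s=5e4), 0.0, 0.0)
        t_mid = np.array([tr.t_entry_s]) + 0.0
        # numerical velocity at cavity centre (x = 75)
        t75 = np.interp(75.0, tr.x_breaks_um, tr.t_breaks_s)
        dt = 1e-6
        x1, _ = tr.position(t75 + dt)
        x0, _ = tr.position(t75 - dt)
        v_cavity = (x1 - x0) / (2 * dt)
        assert v_cavity == pytest.approx(5e4 * 20 / 50, rel=1e-6)

    def test_streamline_widening_in_cavity(self):
        tr = simulate_trajectory(CAVITY, FlowModel(), 4.0, 0.0, particle=BEAD)
        assert tr.lateral_position(25.0) == pytest.approx(4.0)
        assert tr.lateral_position(75.0) == pytest.approx(4.0 * 50 / 20)

    def test_passage_time_distribution_matches_plane_poiseuille(self):
        """KS test of transit durations over uniform y0 against the analytic
        passage-time law T(u) = T0/(1-u^2), u uniform on [0, u_max]."""
        rng = np.random.default_rng(42)
        w, d, v = 30.0, 10.0, 5e4
        u_max = (w - d) / w
        y0s = rng.uniform(-u_max * w / 2, u_max * w / 2, size=500)
        durs = np.array([simulate_trajectory(STRAIGHT, FlowModel(v_max_um_s=v), y, 0.0).duration_s
                         for y in y0s])
        t0 = 150 / v

        def cdf(t):
            t = np.clip(t, t0, t0 / (1 - u_max ** 2))
            return np.sqrt(1 - t0 / t) / u_max

        res = stats.kstest(durs, cdf)
        assert res.pvalue > 0.01


class TestBlockadeModel:
    def test_straight_plateau_equals_smythe(self):
        d_eq = equivalent_diameter(30, 20)
        trans = TransitionModel(transition_length_um=0.0)
        a = ground_truth_amplitude(STRAIGHT, BEAD, 75.0, 0.0, transition=trans)
        assert a == pytest.approx(smythe_amplitude(10, d_eq, 150), rel=1e-12)

    def test_closed_form_along_full_trajectory(self):
        """With sigma=0 the synthesized blockade equals the closed form at
        every sample (exact Ohmic inversion)."""
        trans = TransitionModel(transition_length_um=0.0)
        tr = simulate_trajectory(STRAIGHT, FlowModel(), 3.0, 0.01, particle=BEAD)
        acq = AcquisitionModel(noise_sigma_a=0.0)
        trace, _ = synthesize_current(STRAIGHT, BEAD, [tr], acq, transition=trans,
                                      duration_s=0.02)
        t = trace.times_s
        x, y = tr.position(t)
        a_true = ground_truth_amplitude(STRAIGHT, BEAD, x, y, TheoryParams(), trans)
        a_true[(t < tr.t_start_s) | (t > tr.t_end_s)] = 0.0
        a_meas = (acq.baseline_current_a - trace.current_a) / trace.current_a
        np.testing.assert_allclose(a_meas, a_true, atol=1e-10 * a_true.max())

    def test_cavity_ratio_morphology(self):
        """On-axis cavity blockade: two equal narrow plateaus, interior
        plateau at the local-resistance ratio."""
        a_n = ground_truth_amplitude(CAVITY, BEAD, 25.0, 0.0)
        a_n2 = ground_truth_amplitude(CAVITY, BEAD, 125.0, 0.0)
        a_c = ground_truth_amplitude(CAVITY, BEAD, 75.0, 0.0)
        assert a_n == pytest.approx(a_n2, rel=1e-12)
        from pulsemap.geometry import amplitude_ratio
        expected = amplitude_ratio(10, equivalent_diameter(50, 20), equivalent_diameter(20, 20))
        assert a_c / a_n == pytest.approx(expected, rel=1e-9)

    def test_transition_envelope(self):
        trans = TransitionModel(transition_length_um=15.0, access_fraction=0.5,
                                access_decay_um=10.0)
        a_mid = ground_truth_amplitude(STRAIGHT, BEAD, 75.0, 0.0, transition=trans)
        a_edge = ground_truth_amplitude(STRAIGHT, BEAD, 0.0, 0.0, transition=trans)
        a_out = ground_truth_amplitude(STRAIGHT, BEAD, -10.0, 0.0, transition=trans)
        assert a_edge == pytest.approx(0.5 * a_mid, rel=1e-9)
        assert a_out == pytest.approx(0.5 * a_mid * np.exp(-1.0), rel=1e-9)
        a_at_lt = ground_truth_amplitude(STRAIGHT, BEAD, 15.0, 0.0, transition=trans)
        assert a_at_lt == pytest.approx(a_mid, rel=1e-9)

    def test_empty_trajectory_list_gives_baseline(self):
        acq = AcquisitionModel(noise_sigma_a=0.0)
        trace, truth = synthesize_current(STRAIGHT, BEAD, [], acq, duration_s=0.01)
        assert truth == []
        np.testing.assert_allclose(trace.current_a, acq.baseline_current_a)

    def test_clock_consistency_without_skew(self):
        acq = AcquisitionModel(clock_skew=0.0, stream_offset_s=0.25)
        cam, shape = default_camera(STRAIGHT, acq)
        _, ts = render_frames([], STRAIGHT, acq, cam, shape, np.arange(5))
        np.testing.assert_allclose(ts, np.arange(5) * acq.frame_period_s + 0.25,
                                   rtol=0, atol=0)


class TestFrames:
    def test_empty_frames_are_background(self):
        acq = AcquisitionModel(pixel_noise_sigma=0.0)
        cam, shape = default_camera(STRAIGHT, acq)
        frames, _ = render_frames([], STRAIGHT, acq, cam, shape, [0, 1, 2])
        assert np.all(frames == int(acq.background_level))

    def test_rendered_centroid_accuracy(self):
        """Noiseless rendered disk: thresholded centroid within 0.5 px."""
        acq = AcquisitionModel(pixel_noise_sigma=0.0)
        cam, shape = default_camera(STRAIGHT, acq)
        tr = simulate_trajectory(STRAIGHT, FlowModel(), 2.0, 0.0, particle=BEAD)
        t = tr.t_entry_s + 1e-3  # mid-channel-ish instant
        frames, ts = render_frames([tr], STRAIGHT, acq, cam, shape,
                                   [int(t / acq.frame_period_s)])
        template = np.full(shape, acq.background_level, dtype=np.uint8)
        diff = subtract_template(frames[0], template)
        dets = threshold_and_label(diff, theta=30.0, min_area_px=10)
        assert len(dets) == 1
        x_c, y_c = to_channel_coords(dets[0].centroid_px, cam)
        t_mid = ts[0] + acq.exposure_s / 2.0
        x_true, y_true = tr.position(t_mid)
        assert abs(x_c - x_true) < 0.5 * acq.um_per_px
        assert abs(y_c - y_true) < 0.5 * acq.um_per_px

    def test_constant_velocity_centroid_displacement(self):
        """A particle crossing the channel in N frames moves L/N per frame."""
        acq = AcquisitionModel(pixel_noise_sigma=0.0)
        cam, shape = default_camera(STRAIGHT, acq)
        v = 150.0 / (100 * acq.frame_period_s)  # one channel length per 100 frames
        tr = simulate_trajectory(STRAIGHT, FlowModel(v_max_um_s=v), 0.0, 0.0)
        j0 = int((tr.t_entry_s + 20 * acq.frame_period_s) / acq.frame_period_s)
        frames, ts = render_frames([tr], STRAIGHT, acq, cam, shape, [j0, j0 + 1])
        template = np.full(shape, acq.background_level, dtype=np.uint8)
        cents = []
        for fr in frames:
            det = threshold_and_label(subtract_template(fr, template), 30.0)[0]
            cents.append(to_channel_coords(det.centroid_px, cam))
        dx = cents[1][0] - cents[0][0]
        assert dx == pytest.approx(150 / 100, abs=0.1)


class TestDatasets:
    def test_reproducibility_same_seed(self):
        cfg = SimulationConfig(geometry=STRAIGHT, n_events=5, rate_per_s=None,
                               duration_s=0.3)
        a = generate_dataset(cfg, 123)
        b = generate_dataset(cfg, 123)
        np.testing.assert_array_equal(a.trace.current_a, b.trace.current_a)
        fa, _ = a.frames(0, 50)
        fb, _ = b.frames(0, 50)
        np.testing.assert_array_equal(fa, fb)
        assert [t.to_dict() for t in a.truth] == [t.to_dict() for t in b.truth]

    def test_event_count_by_construction(self):
        cfg = SimulationConfig(geometry=STRAIGHT, n_events=12, rate_per_s=None,
                               duration_s=0.6)
        ds = generate_dataset(cfg, 1)
        assert len(ds.truth) == 12
        entries = np.array([t.t_entry_s for t in ds.truth])
        assert np.all(np.diff(entries) > 0)

    def test_zero_rate_gives_baseline_only(self):
        cfg = SimulationConfig(geometry=STRAIGHT, rate_per_s=1e-9, duration_s=0.2,
                               acquisition=AcquisitionModel(noise_sigma_a=0.0))
        ds = generate_dataset(cfg, 1)
        assert len(ds.truth) == 0
        np.testing.assert_allclose(ds.trace.current_a, 100e-9)

    def test_overpacked_recording_rejected(self):
        cfg = SimulationConfig(geometry=STRAIGHT, n_events=1000, rate_per_s=None,
                               duration_s=0.5)
        with pytest.raises(ValueError, match="does not fit"):
            generate_dataset(cfg, 1)

    def test_particle_wider_than_channel_rejected(self):
        narrow = ChannelGeometry.straight(150, 8, 20)
        with pytest.raises(ValueError):
            SimulationConfig(geometry=narrow, particle=BEAD, n_events=1,
                             rate_per_s=None, duration_s=0.5)
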