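"""Resistance maps, axial/lateral profiles, ratios and correlations."""

import numpy as np
import pytest

from pulsemap import analysis, studies
from pulsemap.geometry import (
    Particle,
    equivalent_diameter,
    smythe_amplitude,
)
from pulsemap.simulate import TransitionModel
from pulsemap.sync import MatchedEvent

from conftest import run_hybrid, run_rp_only

BEAD = Particle(10.0)


def _fake_match(t, x, y, a):
    """Minimal matched event carrying only per-sample tuples."""
    from pulsemap.imaging import IMEvent
    from pulsemap.rp import RPEvent

    rp_ev = RPEvent(start=0, end=len(t), core_start=0, core_end=len(t),
                    sample_period_s=4e-6)
    im_ev = IMEvent(times_s=np.asarray(t), x_c_um=np.asarray(x),
                    y_c_um=np.asarray(y), frame_indices=np.arange(len(t)),
                    complete=True, t_entry_s=t[0], t_exit_s=t[-1],
                    duration_s=t[-1] - t[0], y_mean_um=float(np.mean(y)))
    m = MatchedEvent(rp_event=rp_ev, im_event=im_ev, coarse_offset_s=0.0,
                     fine_offset_s=0.0)
    m.samples = np.rec.fromarrays(
        [np.asarray(t), np.asarray(x), np.asarray(y), np.asarray(a)],
        names=["t", "x_um", "y_um", "blockade"])
    return m


class TestBuildMap:
    def test_constant_amplitude_event(self):
        t = np.linspace(0, 1e-3, 50)
        m = _fake_match(t, np.linspace(0, 150, 50), np.zeros(50), np.full(50, 0.01))
        rmap = analysis.build_map([m], bin_um=1.0)
        assert np.nanmax(rmap.mean) == pytest.approx(0.01)
        assert np.nanmin(rmap.mean[rmap.count > 0]) == pytest.approx(0.01)

    def test_bin_larger_than_channel_gives_grand_mean(self):
        t = np.linspace(0, 1e-3, 50)
        a = np.linspace(0.01, 0.02, 50)
        m = _fake_match(t, np.linspace(0, 150, 50), np.zeros(50), a)
        rmap = analysis.build_map([m], bin_um=1000.0)
        assert rmap.mean[rmap.count > 0][0] == pytest.approx(a.mean())

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            analysis.build_map([], bin_um=1.0)

    def test_empty_bins_are_nan_not_zero(self):
        t = np.linspace(0, 1e-3, 10)
        m = _fake_match(t, np.linspace(0, 10, 10), np.zeros(10), np.full(10, 0.01))
        rmap = analysis.build_map([m], bin_um=1.0,
                                  extent=((0, 20), (-5, 5)))
        assert np.isnan(rmap.mean[rmap.count == 0]).all()

    def test_noiseless_map_matches_model(self, transition_run):
        """sigma=0 on-axis run: central-bin means equal the model amplitude."""
        cfg = transition_run["dataset"].config
        rmap = analysis.build_map(transition_run["matches"], bin_um=1.0,
                                  geom=cfg.geometry)
        pred = smythe_amplitude(10, equivalent_diameter(30, 20), 150)
        xc = rmap.x_centers_um
        sel = (xc > 20) & (xc < 130)
        vals = rmap.mean[sel, :][rmap.count[sel, :] > 0]
        np.testing.assert_allclose(vals, pred, rtol=2e-3)

    def test_streaming_consistency(self, transition_run):
        """Splitting the events and merging the sample sets leaves the
        binned statistics unchanged (profiles are order-independent)."""
        matches = transition_run["matches"]
        geom = transition_run["dataset"].config.geometry
        full = analysis.build_map(matches, bin_um=2.0, geom=geom,
                                  extent=((-20, 170), (-3, 3)))
        reordered = analysis.build_map(matches[::-1], bin_um=2.0, geom=geom,
                                       extent=((-20, 170), (-3, 3)))
        np.testing.assert_allclose(full.mean, reordered.mean, equal_nan=True)
        np.testing.assert_array_equal(full.count, reordered.count)


class TestAxialProfile:
    def test_saturation_position_at_transition_length(self, transition_run):
        """With a 15 um transition zone the profile saturates ~15 um into
        the channel — well beyond the 10 um particle diameter."""
        res = analysis.axial_profile(transition_run["matches"],
                                     geom=transition_run["dataset"].config.geometry)
        assert res["x_saturation_um"] == pytest.approx(15.0, abs=2.0)
        assert res["a_entrance"] < 0.6 * res["a_max"]

    def test_flat_profile_without_transition_zone(self):
        cfg = studies.transition_config(n_events=5, transition_length_um=0.0)
        run = run_hybrid(cfg, seed=21)
        res = analysis.axial_profile(run["matches"], geom=cfg.geometry)
        prof = res["profile"]
        inside = (prof.centers > 5) & (prof.centers < 145)
        assert np.ptp(prof.mean[inside]) < 0.02 * res["a_max"]

    def test_profile_symmetric_about_center(self, transition_run):
        res = analysis.axial_profile(transition_run["matches"],
                                     geom=transition_run["dataset"].config.geometry)
        prof = res["profile"]
        mid = 75.0
        inside = (prof.centers >= 0) & (prof.centers <= 150)
        c, v = prof.centers[inside], prof.mean[inside]
        mirrored = np.interp(2 * mid - c, c, v)
        np.testing.assert_allclose(v, mirrored, rtol=5e-2)


class TestFwhmVsEntrance:
    def test_half_access_fraction_gives_half_peak_at_entrance(self, transition_run):
        """access_fraction = 0.5 puts the entrance/exit at the half-peak
        level, so FWHM durations equal entrance-to-exit transit times."""
        res = analysis.fwhm_vs_entrance_check(transition_run["matches"])
        assert np.allclose(res["entrance_ratio"].mean(), 0.5, atol=0.05)
        assert np.allclose(res["exit_ratio"].mean(), 0.5, atol=0.05)
        # sigma=0: reproducible across events
        assert res["entrance_ratio"].std() < 0.02

    def test_no_transition_zone_ratios_near_one(self):
        from pulsemap.io import DetectionParams

        cfg = studies.transition_config(n_events=5, transition_length_um=0.0)
        run = run_hybrid(cfg, seed=22,
                         det=DetectionParams(min_duration_s=2e-4, lowpass_hz=80e3))
        res = analysis.fwhm_vs_entrance_check(run["matches"])
        assert res["entrance_ratio"].mean() > 0.8


class TestLateralStats:
    def test_poiseuille_duration_profile(self, lateral_run_alpha6):
        """Transit time is convex in lateral position with its minimum on
        the channel axis, following 1/(1-(2y/w)^2)."""
        geom = lateral_run_alpha6["dataset"].config.geometry
        res = analysis.lateral_stats(lateral_run_alpha6["matches"], "whole", geom=geom)
        assert res["duration_quad_coeff"] > 5 * res["duration_quad_err"]
        prof = res["duration_profile"]
        assert abs(prof.centers[np.argmin(prof.mean)]) < 2.0
        # exact duration law at sigma=0 transport: T(y)/T(0) = 1/(1-(2y/w)^2)
        y, t = res["y_um"], res["duration_s"]
        t0 = t[np.abs(y) < 1.0].mean()
        sel = np.abs(y) > 4
        np.testing.assert_allclose(t[sel] / t0, 1 / (1 - (2 * y[sel] / 25) ** 2),
                                   rtol=0.03)

    def test_alpha_recovery(self, lateral_run_alpha6):
        geom = lateral_run_alpha6["dataset"].config.geometry
        res = analysis.lateral_stats(lateral_run_alpha6["matches"], "whole", geom=geom)
        alpha, a0 = analysis.fit_offaxis_alpha(res["y_um"], res["amplitude"], BEAD, geom)
        assert alpha == pytest.approx(6.0, rel=0.2)
        assert a0 == pytest.approx(
            smythe_amplitude(10, equivalent_diameter(25, 20), 150), rel=0.02)

    def test_alpha_zero_gives_flat_amplitude_profile(self, lateral_run_alpha0):
        geom = lateral_run_alpha0["dataset"].config.geometry
        res = analysis.lateral_stats(lateral_run_alpha0["matches"], "whole", geom=geom)
        assert abs(res["amplitude_quad_coeff"]) < 3 * res["amplitude_quad_err"] + 1e-9
        alpha, _ = analysis.fit_offaxis_alpha(res["y_um"], res["amplitude"], BEAD, geom)
        assert abs(alpha) < 1.0

    def test_amp_duration_positive_correlation(self, lateral_run_alpha6):
        geom = lateral_run_alpha6["dataset"].config.geometry
        fit = analysis.amp_duration_fit(lateral_run_alpha6["matches"], "whole", geom=geom)
        assert fit.slope > 0
        assert fit.rvalue > 0.5

    def test_degenerate_fit_flagged(self):
        t = np.linspace(0, 1e-3, 30)
        ms = [_fake_match(t, np.linspace(0, 150, 30), np.zeros(30), np.full(30, 0.01))
              for _ in range(12)]
        with pytest.raises(ValueError, match="degenerate"):
            analysis.amp_duration_fit(ms)


class TestCavity:
    def test_ratio_distribution_both_channels(self, cavity_run):
        cfg = cavity_run["dataset"].config
        res = analysis.ratio_distribution(cavity_run["rp_events"], cfg.geometry, BEAD)
        assert len(res["ratios"]) >= 95
        assert res["ratios"].mean() == pytest.approx(res["predicted"], rel=0.05)

    def test_ratio_noiseless_is_exact(self):
        cfg = studies.cavity_ratio_config("17.5/30", n_events=3)
        from dataclasses import replace
        cfg = replace(cfg, acquisition=replace(cfg.acquisition, noise_sigma_a=0.0),
                      duration_s=0.5)
        run = run_rp_only(cfg, seed=2)
        res = analysis.ratio_distribution(run["rp_events"], cfg.geometry, BEAD)
        np.testing.assert_allclose(res["ratios"], res["predicted"], atol=1e-3)

    def test_straight_channel_events_rejected(self, transition_run):
        geom_cavity = studies.cavity_geometry("20/50")
        with pytest.raises(ValueError):
            analysis.ratio_distribution(transition_run["rp_events"],
                                        geom_cavity, BEAD)

    def test_entrance_convention_close_to_mean(self, cavity_run):
        cfg = cavity_run["dataset"].config
        mean_conv = analysis.ratio_distribution(cavity_run["rp_events"],
                                                cfg.geometry, BEAD, convention="mean")
        ent_conv = analysis.ratio_distribution(cavity_run["rp_events"],
                                               cfg.geometry, BEAD, convention="entrance")
        assert ent_conv["ratios"].mean() == pytest.approx(mean_conv["ratios"].mean(),
                                                          rel=0.05)

    def test_suppressed_near_wall_inverts_cavity_correlation(self):
        """With the near-wall suppression mode on, amplitude and duration
        anti-correlate in the cavity while staying positively correlated in
        the narrow sections."""
        from dataclasses import replace

        cfg = studies.lateral_config(alpha=6.0, n_events=60)
        geom = studies.cavity_geometry("20/50")
        cfg = replace(cfg, geometry=geom,
                      transition=TransitionModel(cavity_radial_mode="suppressed-near-wall",
                                                 cavity_radial_magnitude=0.5),
                      duration_s=1.2)
        run = run_hybrid(cfg, seed=30)
        fit_narrow = analysis.amp_duration_fit(run["matches"], "narrow", geom=geom)
        fit_cavity = analysis.amp_duration_fit(run["matches"], "cavity", geom=geom)
        assert fit_narrow.slope > 0
        assert fit_cavity.slope < 0
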