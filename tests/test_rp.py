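"""Resistive-pulse extraction: preprocessing, detection, characterization."""

import numpy as np
import pytest

from pulsemap.rp import (
    ConfigError,
    CurrentTrace,
    detect_and_characterize,
    detect_events,
    gate_events,
    noise_sigma,
    preprocess,
)

I0 = 100e-9
DT = 4e-6


def _trace(current, lowpass=10e3, window=50e-3):
    return preprocess(CurrentTrace(sample_period_s=DT, current_a=current),
                      lowpass_hz=lowpass, detrend_window_s=window)


def _with_pulses(n, depth, width, positions, noise=0.0, rng=None, base=I0):
    x = np.full(n, base)
    for p in positions:
        x[p:p + width] -= depth
    if noise:
        x = x + (rng or np.random.default_rng(0)).normal(0, noise, n)
    return x


class TestPreprocess:
    def test_filter_reduces_variance(self):
        rng = np.random.default_rng(1)
        tr = _trace(I0 + rng.normal(0, 1e-11, 100_000))
        assert tr.filtered_a.var() < tr.current_a.var()

    def test_constant_trace_baseline(self):
        tr = _trace(np.full(20_000, I0))
        np.testing.assert_allclose(tr.baseline_a, I0, rtol=1e-12)

    def test_linear_drift_removed(self):
        """1 %/s drift with no events: residual mean well below the noise."""
        rng = np.random.default_rng(2)
        n = 250_000
        t = np.arange(n) * DT
        sigma = 2e-11
        x = I0 * (1 + 0.01 * t) + rng.normal(0, sigma, n)
        tr = _trace(x)
        resid = tr.filtered_a - tr.baseline_a
        assert abs(resid.mean()) < 0.1 * sigma

    def test_short_window_rejected(self):
        with pytest.raises(ConfigError):
            _trace(np.full(1000, I0), window=5 * DT)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            _trace(np.full(1000, I0), lowpass=1 / DT)


class TestDetection:
    def test_no_false_positives_on_flat_noise(self):
        """At k=6 the Gaussian tail bound predicts far below one false
        positive per 1e6 samples."""
        rng = np.random.default_rng(3)
        tr = _trace(I0 + rng.normal(0, 2e-11, 1_000_000))
        assert detect_events(tr, k=6.0) == []

    def test_recovers_all_planted_pulses(self):
        rng = np.random.default_rng(4)
        sigma = 2e-11
        positions = [20_000 * i + 10_000 for i in range(10)]
        width = 500
        x = _with_pulses(210_000, 10 * 6 * sigma, width, positions, noise=sigma, rng=rng)
        tr = _trace(x)
        events = detect_and_characterize(tr, k=6.0, min_duration_s=1e-4)
        assert len(events) == 10
        for ev, p in zip(events, positions):
            # detected span covers at least the FWHM of each planted pulse
            assert ev.core_start <= p + width // 4
            assert ev.core_end >= p + 3 * width // 4

    def test_detection_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        x = _with_pulses(100_000, 2e-9, 400, [30_000, 60_000], noise=2e-11, rng=rng)
        spans = [(e.core_start, e.core_end) for e in detect_events(_trace(x))]
        spans_shifted = [(e.core_start, e.core_end)
                         for e in detect_events(_trace(x + 5e-9))]
        assert spans == spans_shifted

    def test_hysteresis_merges_close_pulses(self):
        """Two pulses bridged by a shallow ledge above the closing threshold
        form a single event; without the bridge they stay separate."""
        sigma = 2e-11
        rng = np.random.default_rng(6)

        def build(with_ledge):
            x = np.full(60_000, I0)
            x[20_000:20_400] -= 30 * sigma
            if with_ledge:
                x[20_400:20_700] -= 5 * sigma  # above 0.5 * 6 sigma_hat closing level
            x[20_700:21_100] -= 30 * sigma
            return x + rng.normal(0, sigma, x.size)

        assert len(detect_events(_trace(build(True)), k=6.0, hysteresis=0.5)) == 1
        assert len(detect_events(_trace(build(False)), k=6.0, hysteresis=0.5)) == 2

    def test_duration_gates(self):
        rng = np.random.default_rng(10)
        x = _with_pulses(60_000, 2e-9, 50, [30_000], noise=2e-11, rng=rng)  # 0.2 ms pulse
        assert detect_events(_trace(x), min_duration_s=1e-3) == []
        assert len(detect_events(_trace(x), min_duration_s=1e-5)) == 1


class TestCharacterization:
    def test_rectangular_pulse(self):
        depth = 2e-9
        x = _with_pulses(60_000, depth, 1000, [30_000])
        tr = _trace(x, lowpass=100e3)
        ev = detect_and_characterize(tr, min_duration_s=1e-4)[0]
        a_expected = depth / (I0 - depth)  # blockade normalizes by I_p
        assert ev.amplitude == pytest.approx(a_expected, rel=1e-2)
        assert ev.fwhm_s == pytest.approx(1000 * DT, rel=0.02)
        assert ev.threshold_duration_s >= ev.fwhm_s * 0.9

    def test_triangular_pulse_fwhm_is_half_base(self):
        n, base_w, depth = 60_000, 2000, 2e-9
        x = np.full(n, I0)
        ramp = np.linspace(0, depth, base_w // 2)
        x[30_000:30_000 + base_w // 2] -= ramp
        x[30_000 + base_w // 2:30_000 + base_w] -= ramp[::-1]
        tr = _trace(x, lowpass=100e3)
        ev = detect_and_characterize(tr, min_duration_s=1e-4)[0]
        assert ev.fwhm_s == pytest.approx(base_w / 2 * DT, rel=0.03)

    def test_amplitude_bias_below_one_percent(self):
        """Plateau amplitude estimator at sigma = depth/20."""
        rng = np.random.default_rng(7)
        depth = 2e-9
        positions = [15_000 * i + 8_000 for i in range(30)]
        x = _with_pulses(470_000, depth, 750, positions, noise=depth / 20, rng=rng)
        events = detect_and_characterize(_trace(x), min_duration_s=1e-3)
        amps = np.array([e.amplitude for e in events])
        assert len(amps) == 30
        assert abs(amps.mean() / (depth / (I0 - depth)) - 1) < 0.01

    def test_boundary_event_flagged_truncated(self):
        x = np.full(30_000, I0)
        x[:600] -= 2e-9  # pulse cut by the recording start
        tr = _trace(x)
        events = detect_and_characterize(tr, min_duration_s=1e-4)
        assert any(ev.truncated for ev in events)


class TestGating:
    @staticmethod
    def _events():
        rng = np.random.default_rng(8)
        positions = [12_000 * i + 6_000 for i in range(8)]
        # last two pulses are doublets: twice the depth (co-located particles)
        x = np.full(110_000, I0)
        for i, p in enumerate(positions):
            depth = 2e-9 if i < 6 else 4e-9
            x[p:p + 500] -= depth
        x += rng.normal(0, 2e-11, x.size)
        return detect_and_characterize(_trace(x), min_duration_s=1e-4)

    def test_empty_gate_is_identity(self):
        events = self._events()
        assert gate_events(events) == events

    def test_amplitude_gate_removes_doublets(self):
        events = self._events()
        singleton = 2e-9 / (I0 - 2e-9)
        kept = gate_events(events, amplitude_range=(0, 1.5 * singleton))
        assert len(kept) == 6

    def test_all_excluding_polygon(self):
        events = self._events()
        poly = [(-2, -2), (-1, -2), (-1, -1), (-2, -1)]
        assert gate_events(events, polygon=poly) == []

    def test_polygon_keeps_inside(self):
        events = self._events()
        singleton = 2e-9 / (I0 - 2e-9)
        poly = [(0.5 * singleton, 1e-3), (1.5 * singleton, 1e-3),
                (1.5 * singleton, 3e-3), (0.5 * singleton, 3e-3)]
        assert len(gate_events(events, polygon=poly)) == 6


def test_noise_sigma_matches_gaussian_scale():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 3.0, 200_000)
    assert noise_sigma(x) == pytest.approx(3.0, rel=0.02)
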