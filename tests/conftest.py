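"""Shared fixtures: small synthetic recordings reused across test modules.

Heavy hybrid (current + imaging) runs are session-scoped so each study
condition is simulated and processed once.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from pulsemap import pipeline, studies, sync
from pulsemap.io import DetectionParams
from pulsemap.simulate import generate_dataset

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def run_hybrid(config, seed, min_duration_s=2e-4, det=None):
    """Full pipeline on an in-memory dataset; returns a results namespace."""
    dataset = generate_dataset(config, seed)
    if det is None:
        det = DetectionParams(min_duration_s=min_duration_s)
    trace, rp_events = pipeline.detect_rp_events(dataset.trace, det)
    rp_events = [ev for ev in rp_events if not ev.truncated]
    im_events = pipeline.detect_im_events(dataset, det)
    matches = sync.match_events(rp_events, im_events, config.geometry, trace)
    return {"dataset": dataset, "trace": trace, "rp_events": rp_events,
            "im_events": im_events, "matches": matches}


def run_rp_only(config, seed, min_duration_s=1e-3):
    dataset = generate_dataset(config, seed)
    trace, rp_events = pipeline.detect_rp_events(
        dataset.trace, DetectionParams(min_duration_s=min_duration_s))
    rp_events = [ev for ev in rp_events if not ev.truncated]
    return {"dataset": dataset, "trace": trace, "rp_events": rp_events}


@pytest.fixture(scope="session")
def sync_run():
    """100 events / 1 s with clock skew 1e-5 and a 0.5 s stream offset."""
    return run_hybrid(studies.sync_config(), seed=3)


@pytest.fixture(scope="session")
def lateral_run_alpha6():
    """300 uniform-lateral events in the 25 um channel, off-axis alpha=6."""
    return run_hybrid(studies.lateral_config(alpha=6.0), seed=5)


@pytest.fixture(scope="session")
def lateral_run_alpha0():
    """300 uniform-lateral events with the off-axis effect switched off."""
    return run_hybrid(studies.lateral_config(alpha=0.0), seed=6)


@pytest.fixture(scope="session")
def transition_run():
    """Noiseless on-axis run with a 15 um entrance/exit transition zone."""
    return run_hybrid(studies.transition_config(), seed=2)


@pytest.fixture(scope="session")
def onaxis_run():
    """100 on-axis events in the 150 x 30 um channel at pulse SNR 20."""
    return run_rp_only(studies.onaxis_amplitude_config(), seed=11)


@pytest.fixture(scope="session")
def cavity_run():
    """100 on-axis cavity (20/50 um) events at noise sigma = a_narrow/20."""
    return run_rp_only(studies.cavity_ratio_config("20/50"), seed=7)
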