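"""Shared fixtures: small synthetic recordings and cohorts.

Everything is generated programmatically at collection time; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from movesyll.preprocess import RawRecording
from movesyll.simulate import CohortConfig, simulate_cohort


def make_recording(
    n: int = 1000,
    rate_hz: float = 25.0,
    wrist_side: str = "left",
    seed: int = 0,
    session_id: str = "s1",
) -> RawRecording:
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate_hz
    accel = rng.normal(0.0, 0.3, size=(n, 3))
    return RawRecording(
        participant_id="p1", session_id=session_id, t=t, accel=accel,
        rate_hz=rate_hz, wrist_side=wrist_side,
    )


def sinusoid_recording(
    freq_hz: float, rate_hz: float, duration_s: float = 30.0,
    amplitude: float = 1.0, wrist_side: str = "left",
) -> RawRecording:
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return RawRecording(
        participant_id="p1", session_id="sine", t=t,
        accel=np.stack([x, x, x], axis=1), rate_hz=rate_hz,
        wrist_side=wrist_side,
    )


@pytest.fixture(scope="session")
def noise_recording() -> RawRecording:
    return make_recording()


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small in-clinic cohort reused by pipeline-level tests (~1 s)."""
    cfg = CohortConfig(
        n_participants=10, n_healthy=4, n_adls=4, adl_duration_s=20.0,
        device_rate_hz=250.0, seed=11,
    )
    return simulate_cohort(cfg)
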