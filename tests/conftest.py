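"""Shared fixtures: small synthetic studies and hand-built sessions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvtvuln import synthetic as syn


def make_session(rts_ms, participant_id="P000", day=4, time_since_wake=10.0,
                 duration=10.0, isi_s=5.0, scheduled=None, actual=None,
                 button_ok=None, timeout=None):
    """Session with a prescribed RT sequence and regular stimulus spacing."""
    rts = np.asarray(rts_ms, dtype=float)
    n = rts.size
    onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        onsets[i] = t + isi_s
        rt = 0.0 if np.isnan(rts[i]) else rts[i]
        t = onsets[i] + rt / 1000.0
    trials = pd.DataFrame({
        "onset_s": onsets,
        "rt_ms": rts,
        "button_ok": np.ones(n, dtype=bool) if button_ok is None
            else np.asarray(button_ok, dtype=bool),
        "timeout": np.isnan(rts) if timeout is None
            else np.asarray(timeout, dtype=bool),
    })
    tsw = time_since_wake
    return syn.Session(
        participant_id=participant_id, day=day, time_since_wake=tsw,
        scheduled_time=tsw if scheduled is None else scheduled,
        actual_time=tsw if actual is None else actual,
        duration=duration, trials=trials,
    )


def lapse_session(n_lapses, n_trials=100, **kw):
    """Session with exactly ``n_lapses`` RTs above 500 ms."""
    rts = np.full(n_trials, 300.0)
    rts[:n_lapses] = 700.0
    return make_session(rts, **kw)


@pytest.fixture(scope="session")
def protocol():
    return syn.ProtocolConfig(seed=42)


@pytest.fixture(scope="session")
def small_study(protocol):
    """16 participants, clean protocol (no corrupted sessions)."""
    return syn.simulate_study(16, protocol)


@pytest.fixture(scope="session")
def study160():
    """Full-size cohort at the default stated protocol."""
    return syn.simulate_study(160, syn.ProtocolConfig(seed=7))
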