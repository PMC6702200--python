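"""Synthetic trial-level PVT study generator.

Emulates the hierarchical structure of an inpatient total-sleep-deprivation
(TSD) protocol: each participant performs a 10-min Psychomotor Vigilance Test
(PVT) every 2 h while awake on days 2-4, with day 4 extending through one
night of continuous wakefulness (sessions 16-24 h after wake).

Reaction times are drawn from a two-state mixture: an attentive state
(lognormal RT around ~300 ms) and a lapse state (shifted-Pareto RT >= 500 ms,
heavy right tail). The per-trial lapse probability follows a logistic model

    logit p = lapse_propensity
            + homeo_gain * max(0, t_awake - 16)        # homeostatic pressure
            + circ_amp * cos(2*pi*(t_awake - circ_phase)/24)  # circadian
            + tot_gain * minute_in_session             # time on task

with trait parameters constant within participant (trait-like stability).
A shared latent vulnerability factor couples baseline speed/propensity traits
to the homeostatic gain, so that baseline performance explains a tunable
share of between-participant variance during sleep deprivation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantTraits",
    "ProtocolConfig",
    "Session",
    "StudyDataset",
    "sample_cohort",
    "simulate_session",
    "simulate_study",
    "write_trials_csv",
    "read_trials_csv",
    "write_traits_csv",
    "vulnerable_tail_traits",
]

#: Day-4 sessions at 16-24 h after wake constitute the sleep-deprivation block.
TSD_TIMES = (16.0, 18.0, 20.0, 22.0, 24.0)
#: Day-4 baseline sessions (first 16 h of wakefulness).
BASELINE_TIMES = (4.0, 6.0, 8.0, 10.0, 12.0, 14.0)

DEFAULT_SCHEDULE = {
    2: list(BASELINE_TIMES),
    3: list(BASELINE_TIMES),
    4: list(BASELINE_TIMES) + list(TSD_TIMES),
}


@dataclass(frozen=True)
class ParticipantTraits:
    """Per-participant generative parameters, constant across sessions."""

    participant_id: str
    base_speed: float        # mean log attentive RT (log-ms)
    base_sd: float           # attentive log-RT dispersion (log-ms), > 0
    lapse_propensity: float  # baseline log-odds of a lapse-state trial
    homeo_gain: float        # lapse log-odds increase per hour awake past 16 h
    circ_amp: float          # circadian modulation amplitude (log-odds), >= 0
    circ_phase: float        # hours after wake of the circadian alertness minimum
    tot_gain: float          # within-session lapse log-odds increase per minute

    def __post_init__(self) -> None:
        if self.base_sd <= 0:
            raise ValueError("base_sd must be > 0")
        if self.circ_amp < 0:
            raise ValueError("circ_amp must be >= 0")


@dataclass
class ProtocolConfig:
    """Study protocol and trait-population parameters.

    Defaults encode the stated protocol (10-min sessions every 2 h, ISI
    uniform on 1-9 s, day-4 TSD block at 16-24 h) and a trait population
    calibrated once against the published group statistics: vulnerable /
    intermediate / resilient quartile ranges of mean TSD lapses, ~50 % of
    TSD variance explained by baseline lapses, and ~37 % of participants
    at <= 2 baseline lapses per session.
    """

    session_times_by_day: dict = field(
        default_factory=lambda: {d: list(t) for d, t in DEFAULT_SCHEDULE.items()})
    session_duration: float = 10.0          # minutes
    isi_range: tuple = (1.0, 9.0)           # seconds
    trait_correlation: float = 0.45         # corr(baseline factor, vulnerability factor)
    invalid_session_rate: float = 0.0       # probability a session is corrupted
    seed: int = 0

    # trait population (see module docstring; calibrated once, then frozen)
    base_speed_mean: float = math.log(285.0)  # log-ms, ~285 ms attentive median
    base_speed_sd: float = 0.055
    base_sd_mean: float = 0.16              # attentive log-RT sigma
    lapse_propensity_mean: float = -3.72
    lapse_propensity_sd: float = 0.50
    homeo_gain_mean: float = 0.33           # 1/h
    homeo_gain_sd: float = 0.075
    circ_amp_mean: float = 0.55
    circ_amp_sd: float = 0.20
    circ_phase_mean: float = 22.0           # h after wake (early-morning nadir)
    circ_phase_sd: float = 1.0
    tot_gain_mean: float = 0.05             # 1/min
    tot_gain_sd: float = 0.02
    attentive_tot_drift: float = 0.004      # log-ms per minute (attentive slowing)

    # error-trial injection
    false_start_rate: float = 0.02          # anticipations, RT < 100 ms
    wrong_button_rate: float = 0.01
    lapse_pareto_alpha: float = 1.6         # shape of lapse RT tail (mean finite)
    lapse_floor_ms: float = 500.0
    rt_cap_ms: float = 30000.0              # no response within cap -> timeout

    def validate(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        lo, hi = self.isi_range
        if not (0 < lo <= hi):
            raise ValueError("isi_range must satisfy 0 < min <= max")
        if not -1.0 <= self.trait_correlation <= 1.0:
            raise ValueError("trait_correlation must lie in [-1, 1]")
        if not 0.0 <= self.invalid_session_rate <= 1.0:
            raise ValueError("invalid_session_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        cfg = cls(**d)
        cfg.session_times_by_day = {
            int(k): [float(t) for t in v] for k, v in cfg.session_times_by_day.items()}
        return cfg


@dataclass
class Session:
    """One PVT administration: metadata plus an ordered trial table.

    ``trials`` columns: onset_s, rt_ms (NaN when timeout), button_ok (bool),
    timeout (bool); rows ordered by onset.
    """

    participant_id: str
    day: int
    time_since_wake: float   # nominal slot, hours after wake
    scheduled_time: float    # hours after wake
    actual_time: float       # hours after wake (differs when administered late)
    duration: float          # minutes
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("session duration must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class StudyDataset:
    """Simulated study: sessions plus ground-truth traits (testing only).

    Analysis stages must never consume ``traits``; they exist so tests can
    compare recovered structure against the generating parameters.
    """

    sessions: list
    traits: list

    def participant_ids(self) -> list:
        return sorted({s.participant_id for s in self.sessions})

    def sessions_of(self, participant_id: str) -> list:
        return [s for s in self.sessions if s.participant_id == participant_id]

    def get_session(self, participant_id: str, day: int, time_since_wake: float):
        for s in self.sessions:
            if (s.participant_id == participant_id and s.day == day
                    and abs(s.time_since_wake - time_since_wake) < 1e-9):
                return s
        return None


# ---------------------------------------------------------------------------
# seeding: every stream derives from (master seed, tags...) so that any
# session is reproducible in isolation and the full study is bit-stable.

def _pid_hash(participant_id: str) -> int:
    return zlib.crc32(participant_id.encode("utf-8"))


def _session_rng(config: ProtocolConfig, participant_id: str, day: int,
                 time_since_wake: float) -> np.random.Generator:
    key = (config.seed, _pid_hash(participant_id), day, int(round(time_since_wake * 10)))
    return np.random.default_rng(np.random.SeedSequence(key))


_COHORT_TAG = 0xC0FFEE  # stream tag separating trait draws from session draws


def sample_cohort(n: int, config: ProtocolConfig) -> list:
    """Draw ``n`` participants' trait vectors from the population model.

    A latent vulnerability factor ``v`` and a baseline factor
    ``u = rho*v + sqrt(1-rho^2)*e`` (``rho = config.trait_correlation``)
    couple baseline traits (speed, dispersion, lapse propensity; driven by
    ``u``) to the homeostatic gain (driven by ``v``).
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _COHORT_TAG)))
    rho = config.trait_correlation
    v = rng.standard_normal(n)
    e = rng.standard_normal(n)
    u = rho * v + math.sqrt(max(0.0, 1.0 - rho * rho)) * e
    width = max(3, len(str(n)))
    traits = []
    for i in range(n):
        noise = rng.standard_normal(4)
        traits.append(ParticipantTraits(
            participant_id=f"P{i:0{width}d}",
            base_speed=config.base_speed_mean + config.base_speed_sd * u[i],
            base_sd=config.base_sd_mean
                * math.exp(0.25 * u[i] + 0.15 * noise[1]),
            lapse_propensity=config.lapse_propensity_mean
                + config.lapse_propensity_sd * u[i],
            homeo_gain=max(0.0, config.homeo_gain_mean
                           + config.homeo_gain_sd * v[i]),
            circ_amp=abs(config.circ_amp_mean + config.circ_amp_sd * noise[2]),
            circ_phase=config.circ_phase_mean + config.circ_phase_sd * noise[3],
            tot_gain=max(0.0, rng.normal(config.tot_gain_mean, config.tot_gain_sd)),
        ))
    return traits


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def simulate_session(traits: ParticipantTraits, day: int, time_since_wake: float,
                     config: ProtocolConfig,
                     rng: np.random.Generator | None = None) -> Session:
    """Simulate one 10-min PVT session for a participant.

    Trials are generated sequentially: after each response an inter-stimulus
    interval ~ Uniform(isi_range) elapses before the next stimulus, until the
    session duration is reached. Each trial is attentive or a lapse per the
    logistic trait model; a configured fraction are anticipations (false
    starts, RT < 100 ms) or wrong-button presses. Lapse RTs beyond
    ``rt_cap_ms`` are recorded as timeouts (no RT).
    """
    if config.session_duration <= 0:
        raise ValueError("session duration must be positive")
    if rng is None:
        rng = _session_rng(config, traits.participant_id, day, time_since_wake)

    dur_s = config.session_duration * 60.0
    circ = traits.circ_amp * math.cos(
        2.0 * math.pi * (time_since_wake - traits.circ_phase) / 24.0)
    eta0 = (traits.lapse_propensity
            + traits.homeo_gain * max(0.0, time_since_wake - 16.0)
            + circ)

    # batch stochastic draws; the sequential loop itself is rng-free
    cap = max(16, int(dur_s / (0.5 * (config.isi_range[0] + config.isi_range[1]))) + 64)
    isi = rng.uniform(config.isi_range[0], config.isi_range[1], size=cap)
    u_state = rng.uniform(size=cap)
    z_att = rng.standard_normal(cap)
    u_lapse = rng.uniform(size=cap)
    u_fs = rng.uniform(size=cap)
    fs_rt = rng.uniform(15.0, 95.0, size=cap)
    u_btn = rng.uniform(size=cap)

    onsets, rts, oks, touts = [], [], [], []
    t = 0.0
    for i in range(cap):
        onset = t + isi[i]
        if onset >= dur_s:
            break
        minute = onset / 60.0
        if u_fs[i] < config.false_start_rate:
            rt = fs_rt[i]
            timeout = False
        else:
            p_lapse = _logistic(eta0 + traits.tot_gain * minute)
            if u_state[i] < p_lapse:
                # shifted Pareto: floor * U^(-1/alpha), heavy right tail
                rt = config.lapse_floor_ms * u_lapse[i] ** (-1.0 / config.lapse_pareto_alpha)
                timeout = rt > config.rt_cap_ms
            else:
                rt = math.exp(traits.base_speed
                              + config.attentive_tot_drift * minute
                              + traits.base_sd * z_att[i])
                timeout = False
        onsets.append(onset)
        rts.append(math.nan if timeout else rt)
        touts.append(timeout)
        oks.append(not (u_btn[i] < config.wrong_button_rate))
        t = onset + (config.rt_cap_ms if timeout else rt) / 1000.0

    trials = pd.DataFrame({
        "onset_s": np.asarray(onsets, dtype=float),
        "rt_ms": np.asarray(rts, dtype=float),
        "button_ok": np.asarray(oks, dtype=bool),
        "timeout": np.asarray(touts, dtype=bool),
    })
    return Session(
        participant_id=traits.participant_id, day=day,
        time_since_wake=time_since_wake, scheduled_time=time_since_wake,
        actual_time=time_since_wake, duration=config.session_duration,
        trials=trials,
    )


_CORRUPTIONS = ("late", "wrong_button_heavy", "response_gap", "truncated")


def _corrupt(session: Session, mode: str, rng: np.random.Generator) -> Session:
    """Corrupt a session in one of the four QC-triggering ways."""
    s = session
    if mode == "late":
        s.actual_time = s.scheduled_time + float(rng.uniform(1.1, 2.0))
    elif mode == "wrong_button_heavy":
        n = len(s.trials)
        bad = rng.uniform(size=n) < 0.15
        s.trials["button_ok"] = ~bad & s.trials["button_ok"].to_numpy()
    elif mode == "response_gap":
        start = float(rng.uniform(60.0, s.duration * 60.0 - 140.0))
        keep = ~s.trials["onset_s"].between(start, start + 75.0)
        s.trials = s.trials.loc[keep].reset_index(drop=True)
    elif mode == "truncated":
        new_dur = float(rng.uniform(5.0, 7.9))
        s.trials = s.trials.loc[s.trials["onset_s"] < new_dur * 60.0].reset_index(drop=True)
        s.duration = new_dur
    else:  # pragma: no cover
        raise ValueError(f"unknown corruption {mode!r}")
    return s


def simulate_study(n: int, config: ProtocolConfig) -> StudyDataset:
    """Simulate the full session grid (days 2-4, incl. the TSD block).

    With probability ``config.invalid_session_rate`` a session is corrupted
    in one of four ways that the QC stage must catch: administered late,
    wrong-button-heavy, a >60 s response gap, or truncation below 8 min.
    """
    config.validate()
    traits = sample_cohort(n, config)
    sessions = []
    for tr in traits:
        for day, times in sorted(config.session_times_by_day.items()):
            for tsw in times:
                s = simulate_session(tr, day, tsw, config)
                if config.invalid_session_rate > 0.0:
                    crng = np.random.default_rng(np.random.SeedSequence(
                        (config.seed, _pid_hash(tr.participant_id), day,
                         int(round(tsw * 10)), 0xBAD)))
                    if crng.uniform() < config.invalid_session_rate:
                        mode = _CORRUPTIONS[crng.integers(len(_CORRUPTIONS))]
                        s = _corrupt(s, mode, crng)
                sessions.append(s)
    return StudyDataset(sessions=sessions, traits=traits)


def vulnerable_tail_traits(config: ProtocolConfig) -> ParticipantTraits:
    """Representative traits for the centre of the vulnerable quartile.

    Sets the shared latent factors at the 87.5th population percentile
    (midpoint of the top quartile) and all nuisance traits at their means.
    """
    q = 1.1503  # Phi^{-1}(0.875)
    rho = config.trait_correlation
    return ParticipantTraits(
        participant_id="VTAIL",
        base_speed=config.base_speed_mean + config.base_speed_sd * 0.8 * rho * q,
        base_sd=config.base_sd_mean * math.exp(0.25 * rho * q),
        lapse_propensity=config.lapse_propensity_mean
            + config.lapse_propensity_sd * rho * q,
        homeo_gain=max(0.0, config.homeo_gain_mean + config.homeo_gain_sd * q),
        circ_amp=config.circ_amp_mean,
        circ_phase=config.circ_phase_mean,
        tot_gain=config.tot_gain_mean,
    )


# ---------------------------------------------------------------------------
# CSV interfaces

TRIALS_COLUMNS = ["participant_id", "day", "time_since_wake_h", "scheduled_time_h",
                  "actual_time_h", "duration_min", "trial_index", "onset_s",
                  "rt_ms", "button_ok", "timeout"]


def write_trials_csv(study: StudyDataset, path) -> None:
    """Write all sessions as one long trial-level CSV (documented dialect)."""
    rows = []
    for s in study.sessions:
        for j, tr in enumerate(s.trials.itertuples(index=False)):
            rows.append((s.participant_id, s.day, s.time_since_wake,
                         s.scheduled_time, s.actual_time, s.duration, j,
                         tr.onset_s, tr.rt_ms, int(tr.button_ok), int(tr.timeout)))
    pd.DataFrame(rows, columns=TRIALS_COLUMNS).to_csv(path, index=False)


def read_trials_csv(path) -> StudyDataset:
    """Read a trial-level CSV back into sessions (ground truth absent)."""
    df = pd.read_csv(path)
    sessions = []
    keys = ["participant_id", "day", "time_since_wake_h"]
    for (pid, day, tsw), g in df.groupby(keys, sort=True):
        g = g.sort_values("trial_index")
        sessions.append(Session(
            participant_id=str(pid), day=int(day), time_since_wake=float(tsw),
            scheduled_time=float(g["scheduled_time_h"].iloc[0]),
            actual_time=float(g["actual_time_h"].iloc[0]),
            duration=float(g["duration_min"].iloc[0]),
            trials=pd.DataFrame({
                "onset_s": g["onset_s"].to_numpy(dtype=float),
                "rt_ms": g["rt_ms"].to_numpy(dtype=float),
                "button_ok": g["button_ok"].to_numpy(dtype=bool),
                "timeout": g["timeout"].to_numpy(dtype=bool),
            }),
        ))
    return StudyDataset(sessions=sessions, traits=[])


def write_traits_csv(study: StudyDataset, path) -> None:
    """Ground-truth traits, for test/diagnostic use only (never analysed)."""
    pd.DataFrame([asdict(t) for t in study.traits]).to_csv(path, index=False)
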