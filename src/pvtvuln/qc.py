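"""Session-validity and participant-inclusion rules.

A PVT session is invalid when any of the following holds:

* ``late_admin`` — administered more than 1 h after the scheduled time;
* ``wrong_button_excess`` — wrong response button on > 10 % of trials;
* ``response_gap`` — no reaction time recorded for > 1 min (any gap between
  consecutive recorded responses, or between session start/end and the
  nearest response, exceeding 60 s);
* ``truncated`` — session cut short to < 8 min;
* ``missing`` — no trials recorded at all.

A participant is excluded from the study iff any of the five sessions of the
sleep-deprivation block (16, 18, 20, 22, 24 h after wake) is missing or
invalid; invalid *baseline* sessions never exclude a participant — they only
drop that participant from the per-time-point model concerned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import Session, StudyDataset, TSD_TIMES

__all__ = [
    "ValidityReport",
    "validate_session",
    "validate_study",
    "select_participants",
    "write_validity_csv",
]

LATE_ADMIN_HOURS = 1.0
WRONG_BUTTON_MAX_FRACTION = 0.10
RESPONSE_GAP_SECONDS = 60.0
MIN_DURATION_MINUTES = 8.0


@dataclass(frozen=True)
class ValidityReport:
    participant_id: str
    day: int
    time_since_wake: float
    is_valid: bool
    reasons: frozenset

    def __post_init__(self) -> None:
        assert self.is_valid == (len(self.reasons) == 0)


def validate_session(s: Session,
                     late_hours: float = LATE_ADMIN_HOURS,
                     wrong_button_max: float = WRONG_BUTTON_MAX_FRACTION,
                     gap_seconds: float = RESPONSE_GAP_SECONDS,
                     min_duration: float = MIN_DURATION_MINUTES) -> ValidityReport:
    """Apply the four invalidity rules (plus ``missing``) to one session."""
    reasons = set()
    if len(s.trials) == 0:
        reasons.add("missing")
    else:
        if s.actual_time - s.scheduled_time > late_hours:
            reasons.add("late_admin")
        # denominator: all recorded trials, timeouts included
        wrong_frac = 1.0 - s.trials["button_ok"].mean()
        if wrong_frac > wrong_button_max:
            reasons.add("wrong_button_excess")
        if s.duration < min_duration:
            reasons.add("truncated")
        responded = s.trials.loc[~s.trials["timeout"]]
        resp_times = (responded["onset_s"] + responded["rt_ms"] / 1000.0).to_numpy()
        end_s = s.duration * 60.0
        marks = np.concatenate(([0.0], np.sort(resp_times), [end_s]))
        if len(resp_times) == 0 or np.max(np.diff(marks)) > gap_seconds:
            reasons.add("response_gap")
    return ValidityReport(
        participant_id=s.participant_id, day=s.day,
        time_since_wake=s.time_since_wake,
        is_valid=not reasons, reasons=frozenset(reasons),
    )


def validate_study(study: StudyDataset) -> dict:
    """Validate every session; keys are (participant_id, day, time_since_wake)."""
    return {
        (s.participant_id, s.day, s.time_since_wake): validate_session(s)
        for s in study.sessions
    }


def select_participants(study: StudyDataset, reports: dict | None = None):
    """Split participants into (included, excluded-with-reasons).

    Exclusion conditions only on the five TSD sessions: a participant is out
    iff any of those is missing from the dataset or fails validation.
    """
    if reports is None:
        reports = validate_study(study)
    included, excluded = [], {}
    for pid in study.participant_ids():
        problems = []
        for tsw in TSD_TIMES:
            rep = reports.get((pid, 4, tsw))
            if rep is None:
                problems.append((tsw, "missing"))
            elif not rep.is_valid:
                problems.append((tsw, ",".join(sorted(rep.reasons))))
        if problems:
            excluded[pid] = problems
        else:
            included.append(pid)
    return included, excluded


def write_validity_csv(reports: dict, path) -> None:
    rows = [
        (r.participant_id, r.day, r.time_since_wake, int(r.is_valid),
         ";".join(sorted(r.reasons)))
        for r in reports.values()
    ]
    pd.DataFrame(rows, columns=["participant_id", "day", "time_since_wake_h",
                                "is_valid", "reasons"]).to_csv(path, index=False)
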