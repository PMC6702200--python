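"""Vulnerability labels from sleep-deprivation performance.

Participants are ranked by their mean number of PVT lapses (RT > 500 ms)
over the five sleep-deprivation sessions (16-24 h awake): the quartile with
the fewest lapses is *resilient*, the quartile with the most is *vulnerable*,
and the middle half is *intermediate* (1:2:1 split; 40/80/40 at n = 160).

The high-performer subgroup comprises participants averaging <= 2 lapses per
session over the six day-4 baseline sessions; re-stratification applies the
same quartile rule within the subgroup (15/30/15 at n = 60).
"""

from __future__ import annotations

import pandas as pd

from .features import lapse_count
from .synthetic import BASELINE_TIMES, StudyDataset, TSD_TIMES

__all__ = [
    "CLASSES",
    "tsd_score",
    "tsd_scores",
    "assign_labels",
    "baseline_lapse_mean",
    "select_high_performers",
    "write_labels_csv",
]

#: Fixed class order used for tie-breaking throughout the package.
CLASSES = ("resilient", "intermediate", "vulnerable")
LAPSE_THRESHOLD_MS = 500.0


def _session_lapses(session) -> int:
    tr = session.trials
    responded = ~tr["timeout"].to_numpy()
    rts = tr.loc[responded, "rt_ms"].to_numpy()
    rts = rts[rts >= 100.0]  # false starts are not lapses
    return lapse_count(rts, LAPSE_THRESHOLD_MS, n_timeouts=int((~responded).sum()))


def tsd_score(study: StudyDataset, participant_id: str) -> float:
    """Mean 500-ms lapse count over the five TSD sessions (16-24 h awake)."""
    counts = []
    for tsw in TSD_TIMES:
        s = study.get_session(participant_id, 4, tsw)
        if s is None:
            raise ValueError(
                f"participant {participant_id} lacks the {tsw} h TSD session "
                "(should have been excluded upstream)")
        counts.append(_session_lapses(s))
    return float(sum(counts)) / len(counts)


def tsd_scores(study: StudyDataset, participant_ids) -> pd.Series:
    return pd.Series({pid: tsd_score(study, pid) for pid in participant_ids},
                     name="tsd_mean_lapses")


def assign_labels(scores: pd.Series) -> pd.Series:
    """Quartile-split labels from per-participant TSD scores.

    Lowest floor(n/4) scores -> resilient, highest floor(n/4) -> vulnerable,
    remainder -> intermediate. Ties are broken by participant id (stable,
    documented); permutation of input order cannot change the result.
    """
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 participants to form quartiles")
    q = n // 4
    order = scores.sort_index().sort_values(kind="stable").index
    labels = pd.Series("intermediate", index=scores.index, name="label")
    labels.loc[order[:q]] = "resilient"
    labels.loc[order[n - q:]] = "vulnerable"
    return labels


def baseline_lapse_mean(study: StudyDataset, participant_id: str) -> float:
    """Mean 500-ms lapse count over the six day-4 baseline sessions."""
    counts = []
    for tsw in BASELINE_TIMES:
        s = study.get_session(participant_id, 4, tsw)
        if s is not None:
            counts.append(_session_lapses(s))
    if not counts:
        return float("nan")
    return float(sum(counts)) / len(counts)


def select_high_performers(study: StudyDataset, participant_ids,
                           max_lapses: float = 2.0) -> list:
    """Participants averaging <= ``max_lapses`` per baseline session (inclusive)."""
    return [pid for pid in participant_ids
            if baseline_lapse_mean(study, pid) <= max_lapses]


def write_labels_csv(scores: pd.Series, labels: pd.Series, path,
                     cohort: str = "full") -> None:
    df = pd.DataFrame({"participant_id": scores.index,
                       "tsd_mean_lapses": scores.values,
                       "label": labels.loc[scores.index].values,
                       "cohort": cohort})
    df.to_csv(path, index=False)
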