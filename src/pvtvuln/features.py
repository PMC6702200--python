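"""Per-session summary measures of PVT performance.

Each 10-min session is condensed into an ordered vector of summary measures
(the feature row vector fed to the discriminant models). Families:

* central tendency of RT and reciprocal RT (1000/RT, units 1/s);
* RT percentiles on a 5..95 grid, plus fastest/slowest-10 % tail means;
* differences of percentile RTs for every ordered grid pair (the
  distribution-width measures that dominate the selected models);
* lapse counts at multiple RT thresholds (500 ms is the canonical lapse);
* error counts: false starts (RT < 100 ms), timeouts, wrong-button presses;
* variability: SD of RT, SD of reciprocal RT, interquartile range;
* counts of large consecutive-RT jumps and the mean absolute jump;
* time-on-task trends: per-minute OLS slopes of RT, reciprocal RT and
  lapse counts, and the first-two-minutes minus last-two-minutes mean RT.

Conventions: false starts and timeouts are excluded from RT-distribution
statistics; timeouts count as lapses at every threshold below the response
cap; quantiles use linear interpolation (numpy default, type-7 style).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Session, StudyDataset

__all__ = [
    "FeatureSpec",
    "FeatureCatalog",
    "FeatureVector",
    "build_catalog",
    "lapse_count",
    "percentile_difference",
    "consecutive_diff_count",
    "time_on_task_slope",
    "compute_features",
    "feature_matrix",
]

FALSE_START_MS = 100.0  # anticipation threshold (standard PVT convention)

DEFAULT_PERCENTILE_GRID = tuple(range(5, 100, 5))          # 19 values
DEFAULT_LAPSE_THRESHOLDS = (355.0, 500.0, 1000.0, 2000.0, 5000.0)
DEFAULT_DIFF_THRESHOLDS = (100.0, 250.0, 500.0, 1000.0)
FAMILIES = ("central_tendency", "percentile", "percentile_difference",
            "lapse_count", "reciprocal_rt", "variability",
            "consecutive_difference", "error_count", "time_on_task")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str
    params: tuple = ()   # ordered (key, value) pairs, hashable

    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, versioned list of feature specs; order is the vector layout."""

    specs: tuple
    version: str = "1"

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list:
        return [s.name for s in self.specs]

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "specs": [{"name": s.name, "family": s.family,
                       "params": s.param_dict()} for s in self.specs],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FeatureCatalog":
        d = json.loads(text)
        specs = tuple(
            FeatureSpec(e["name"], e["family"], tuple(sorted(e["params"].items())))
            for e in d["specs"])
        return cls(specs=specs, version=d.get("version", "1"))


@dataclass
class FeatureVector:
    """One session's evaluation of the catalog (NaN marks missing)."""

    participant_id: str
    day: int
    time_since_wake: float
    values: np.ndarray
    valid: bool = True


def build_catalog(percentile_grid=DEFAULT_PERCENTILE_GRID,
                  lapse_thresholds=DEFAULT_LAPSE_THRESHOLDS,
                  diff_thresholds=DEFAULT_DIFF_THRESHOLDS,
                  families=None) -> FeatureCatalog:
    """Enumerate the default catalog (216 features with default grids).

    ``percentile_grid`` drives both the percentile family and all ordered
    percentile-difference pairs, so catalog size grows quadratically in it.
    ``families`` optionally restricts the catalog to a subset of families.
    """
    pgrid = tuple(percentile_grid)
    lthr = tuple(lapse_thresholds)
    dthr = tuple(diff_thresholds)
    if not pgrid or not lthr or not dthr:
        raise ValueError("empty parameter grid")
    specs = [
        FeatureSpec("rt_mean", "central_tendency"),
        FeatureSpec("rt_median", "central_tendency"),
        FeatureSpec("recip_mean", "reciprocal_rt"),
        FeatureSpec("recip_median", "reciprocal_rt"),
    ]
    for p in pgrid:
        specs.append(FeatureSpec(f"rt_p{p:02d}", "percentile", (("p", p),)))
    for i, lo in enumerate(pgrid):
        for hi in pgrid[i + 1:]:
            specs.append(FeatureSpec(
                f"rt_p{hi:02d}_minus_p{lo:02d}", "percentile_difference",
                (("p_hi", hi), ("p_lo", lo))))
    for thr in lthr:
        specs.append(FeatureSpec(
            f"lapses_gt{int(thr)}", "lapse_count", (("threshold_ms", thr),)))
    specs += [
        FeatureSpec("n_false_starts", "error_count"),
        FeatureSpec("n_timeouts", "error_count"),
        FeatureSpec("n_wrong_button", "error_count"),
        FeatureSpec("rt_sd", "variability"),
        FeatureSpec("recip_sd", "variability"),
        FeatureSpec("rt_iqr", "variability"),
    ]
    for thr in dthr:
        specs.append(FeatureSpec(
            f"consec_diff_gt{int(thr)}", "consecutive_difference",
            (("threshold_ms", thr),)))
    specs += [
        FeatureSpec("consec_absdiff_mean", "consecutive_difference"),
        FeatureSpec("rt_slope_per_min", "time_on_task"),
        FeatureSpec("recip_slope_per_min", "time_on_task"),
        FeatureSpec("rt_first2_minus_last2", "time_on_task"),
        FeatureSpec("lapse_slope_per_min", "time_on_task"),
        FeatureSpec("rt_fastest10_mean", "percentile", (("tail", "fastest"),)),
        FeatureSpec("rt_slowest10_mean", "percentile", (("tail", "slowest"),)),
    ]
    if families is not None:
        bad = set(families) - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown families: {sorted(bad)}")
        specs = [s for s in specs if s.family in families]
    return FeatureCatalog(specs=tuple(specs))


# ---------------------------------------------------------------------------
# elementary measures

def lapse_count(rts, threshold: float, n_timeouts: int = 0) -> int:
    """Count RTs strictly above ``threshold`` ms; timeouts always count."""
    rts = np.asarray(rts, dtype=float)
    return int(np.count_nonzero(rts > threshold)) + int(n_timeouts)


def percentile_difference(rts, p_lo: float, p_hi: float) -> float:
    """P(p_hi) - P(p_lo) of the RT distribution (linear interpolation)."""
    if not p_lo < p_hi:
        raise ValueError("need p_lo < p_hi")
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        return float("nan")
    lo, hi = np.percentile(rts, [p_lo, p_hi])
    return float(hi - lo)


def consecutive_diff_count(rts, threshold: float) -> int:
    """Count adjacent-trial RT jumps |rt[i+1]-rt[i]| strictly above threshold."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        return 0
    return int(np.count_nonzero(np.abs(np.diff(rts)) > threshold))


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    denom = float(xm @ xm)
    if denom == 0.0:
        return float("nan")
    return float(xm @ (y - y.mean()) / denom)


def time_on_task_slope(onsets_s, rts, min_span_min: float = 1.0) -> float:
    """OLS slope of RT (ms) against elapsed minutes within the session."""
    onsets = np.asarray(onsets_s, dtype=float) / 60.0
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2 or onsets.max() - onsets.min() <= min_span_min:
        return float("nan")
    return _ols_slope(onsets, rts)


# ---------------------------------------------------------------------------
# catalog evaluation

def _session_context(s: Session) -> dict:
    tr = s.trials
    responded = ~tr["timeout"].to_numpy()
    rt = tr["rt_ms"].to_numpy(dtype=float)
    onset = tr["onset_s"].to_numpy(dtype=float)
    false_start = responded & (rt < FALSE_START_MS)
    clean = responded & ~false_start
    return {
        "rt": rt[clean],                 # RT-distribution sample, trial order
        "onset": onset[clean],
        "n_false_starts": int(false_start.sum()),
        "n_timeouts": int((~responded).sum()),
        "n_wrong_button": int((~tr["button_ok"].to_numpy()).sum()),
        "all_onset": onset,
        "all_responded": responded,
        "all_rt": rt,
        "duration_min": s.duration,
    }


def _lapse_per_minute_slope(ctx: dict, threshold: float = 500.0) -> float:
    """OLS slope of per-minute lapse counts (timeouts included) vs minute."""
    n_min = int(np.ceil(ctx["duration_min"]))
    if n_min < 2:
        return float("nan")
    onset = ctx["all_onset"]
    is_lapse = np.where(ctx["all_responded"], ctx["all_rt"] > threshold, True)
    minutes = np.clip((onset / 60.0).astype(int), 0, n_min - 1)
    counts = np.bincount(minutes[is_lapse], minlength=n_min).astype(float)
    return _ols_slope(np.arange(n_min, dtype=float), counts)


def _evaluate(spec: FeatureSpec, ctx: dict, pctl: dict) -> float:
    rt = ctx["rt"]
    n = rt.size
    name, fam, prm = spec.name, spec.family, spec.param_dict()
    if fam == "lapse_count":
        return float(lapse_count(rt, prm["threshold_ms"], ctx["n_timeouts"]))
    if fam == "error_count":
        return float(ctx[name])
    if fam == "consecutive_difference":
        if name == "consec_absdiff_mean":
            return float(np.mean(np.abs(np.diff(rt)))) if n >= 2 else float("nan")
        return float(consecutive_diff_count(rt, prm["threshold_ms"]))
    if n == 0:
        return float("nan")
    if fam == "central_tendency":
        return float(np.mean(rt)) if name == "rt_mean" else float(np.median(rt))
    if fam == "reciprocal_rt":
        recip = 1000.0 / rt
        return float(np.mean(recip)) if name == "recip_mean" else float(np.median(recip))
    if fam == "percentile":
        if "tail" in prm:
            k = max(1, int(np.ceil(0.10 * n)))
            srt = np.sort(rt)
            return float(srt[:k].mean() if prm["tail"] == "fastest" else srt[-k:].mean())
        return pctl[prm["p"]]
    if fam == "percentile_difference":
        if n < 2:
            return float("nan")
        return pctl[prm["p_hi"]] - pctl[prm["p_lo"]]
    if fam == "variability":
        if name == "rt_iqr":
            return float(np.percentile(rt, 75) - np.percentile(rt, 25)) if n >= 2 else float("nan")
        if n < 2:
            return float("nan")
        sample = 1000.0 / rt if name == "recip_sd" else rt
        return float(np.std(sample, ddof=1))
    if fam == "time_on_task":
        if name == "rt_slope_per_min":
            return time_on_task_slope(ctx["onset"], rt)
        if name == "recip_slope_per_min":
            if n < 2:
                return float("nan")
            mins = ctx["onset"] / 60.0
            if mins.max() - mins.min() <= 1.0:
                return float("nan")
            return _ols_slope(mins, 1000.0 / rt)
        if name == "rt_first2_minus_last2":
            mins = ctx["onset"] / 60.0
            first = rt[mins < 2.0]
            last = rt[mins >= ctx["duration_min"] - 2.0]
            if first.size == 0 or last.size == 0:
                return float("nan")
            return float(first.mean() - last.mean())
        return _lapse_per_minute_slope(ctx)
    raise ValueError(f"unknown family {fam!r}")  # pragma: no cover


def compute_features(s: Session, catalog: FeatureCatalog,
                     valid: bool = True) -> FeatureVector:
    """Evaluate the catalog on one session (all-NaN when ``valid=False``)."""
    if not valid:
        return FeatureVector(s.participant_id, s.day, s.time_since_wake,
                             np.full(len(catalog), np.nan), valid=False)
    ctx = _session_context(s)
    grid = sorted({p for spec in catalog.specs
                   for k, p in spec.params if k in ("p", "p_lo", "p_hi")})
    if ctx["rt"].size:
        pctl = dict(zip(grid, np.percentile(ctx["rt"], grid))) if grid else {}
    else:
        pctl = {p: float("nan") for p in grid}
    values = np.array([_evaluate(spec, ctx, pctl) for spec in catalog.specs])
    return FeatureVector(s.participant_id, s.day, s.time_since_wake, values)


def feature_matrix(study: StudyDataset, catalog: FeatureCatalog,
                   reports: dict | None = None) -> pd.DataFrame:
    """Evaluate the catalog over all sessions.

    Returns a wide DataFrame indexed by (participant_id, day, time_since_wake)
    with one column per feature; sessions failing QC (per ``reports``) yield
    all-NaN rows.
    """
    rows, index = [], []
    for s in study.sessions:
        key = (s.participant_id, s.day, s.time_since_wake)
        valid = True
        if reports is not None:
            rep = reports.get(key)
            valid = rep is not None and rep.is_valid
        fv = compute_features(s, catalog, valid=valid)
        rows.append(fv.values)
        index.append(key)
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(catalog))),
        index=pd.MultiIndex.from_tuples(
            index, names=["participant_id", "day", "time_since_wake"]),
        columns=catalog.names,
    )


def write_feature_csvs(matrix: pd.DataFrame, wide_path, long_path=None) -> None:
    """Persist the feature matrix (wide; optionally tidy long format)."""
    matrix.to_csv(wide_path)
    if long_path is not None:
        long = matrix.stack().rename("value").reset_index()
        long.columns = ["participant_id", "day", "time_since_wake",
                        "feature_name", "value"]
        long.to_csv(long_path, index=False)
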