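"""Intraclass-correlation screening of candidate features.

A feature is a useful trait marker only if it is stable across repeated
rested days. For each feature at each baseline time-since-wake, values from
days 2, 3 and 4 enter a linear mixed model with day as a fixed effect (to
absorb protocol order effects) and a Gaussian random intercept per
participant. The ICC is

    ICC = var_between / (var_between + var_within)

with variance components estimated by REML. Features with ICC strictly
above the threshold (default 0.60, the conventional bar for 'good'
agreement) become candidates for the discriminant model; the rest are
discarded and never revisited.

For complete balanced tables the REML solution has a closed form (two-way
mean decomposition); unbalanced tables fall back to statsmodels MixedLM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICCResult",
    "fit_variance_components",
    "icc_value",
    "screen_features",
    "per_time_table",
    "write_icc_csv",
]

log = logging.getLogger(__name__)

DEFAULT_ICC_THRESHOLD = 0.60


@dataclass(frozen=True)
class ICCResult:
    feature: str
    time_since_wake: float
    var_between: float
    var_within: float
    icc: float
    n_participants: int
    n_days: int

    @property
    def passed(self) -> bool:  # at the default threshold
        return self.icc > DEFAULT_ICC_THRESHOLD


def _balanced_reml(values: np.ndarray, fixed_effect: str | None = "day") -> tuple:
    """Closed-form REML for a complete participant x day table.

    With a day fixed effect and participant random intercept, REML equals the
    classic two-way decomposition: sigma2_W is the interaction mean square,
    sigma2_B = (MS_participant - sigma2_W) / n_days, truncated at zero.
    Without the fixed effect it reduces to the one-way ANOVA estimator.
    """
    n, d = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    if fixed_effect == "day":
        col_means = values.mean(axis=0)
        resid = values - row_means[:, None] - col_means[None, :] + grand
        sigma_w = float((resid ** 2).sum() / ((n - 1) * (d - 1)))
    else:
        resid = values - row_means[:, None]
        sigma_w = float((resid ** 2).sum() / (n * (d - 1)))
    ms_p = float(d * ((row_means - grand) ** 2).sum() / (n - 1))
    sigma_b = max(0.0, (ms_p - sigma_w) / d)
    return sigma_b, sigma_w


def _mixedlm_reml(table: pd.DataFrame, fixed_effect: str | None = "day") -> tuple:
    import statsmodels.formula.api as smf

    long = (table.stack().rename("value").reset_index())
    long.columns = ["participant", "day", "value"]
    formula = "value ~ C(day)" if fixed_effect == "day" else "value ~ 1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=long, groups=long["participant"])
        # powell converges tightly here; lbfgs stalls ~1e-6 from the optimum
        fit = model.fit(reml=True, method=["powell", "lbfgs"], maxiter=2000)
    return max(0.0, float(fit.cov_re.iloc[0, 0])), max(0.0, float(fit.scale))


def fit_variance_components(table: pd.DataFrame,
                            fixed_effect: str | None = "day") -> tuple:
    """(sigma2_between, sigma2_within) for a participant x day value table.

    ``table``: rows = participants, columns = days, NaN = missing cell.
    ``fixed_effect="day"`` (default) absorbs systematic day-order effects;
    ``None`` fits the plain one-way random-intercept model.
    Requires >= 2 participants contributing >= 2 days each (in total).
    """
    tab = table.dropna(how="all")
    tab = tab.loc[tab.notna().sum(axis=1) >= 2]
    if tab.shape[0] < 2 or tab.notna().sum(axis=1).max() < 2:
        raise ValueError("need >= 2 participants with >= 2 days each")
    values = tab.to_numpy(dtype=float)
    if np.allclose(values[np.isfinite(values)],
                   values[np.isfinite(values)].flat[0], equal_nan=True):
        return 0.0, 0.0
    if not np.isnan(values).any() and tab.shape[1] >= 2:
        return _balanced_reml(values, fixed_effect)
    return _mixedlm_reml(tab, fixed_effect)


def icc_value(var_between: float, var_within: float) -> float:
    total = var_between + var_within
    if total <= 0.0:
        return 0.0
    return var_between / total


def per_time_table(matrix: pd.DataFrame, time_since_wake: float) -> pd.DataFrame:
    """Slice a feature matrix to one time-since-wake across days.

    ``matrix`` is the wide output of :func:`pvtvuln.features.feature_matrix`
    (index participant_id, day, time_since_wake). Returns the same columns
    indexed by (participant_id, day).
    """
    sel = matrix.xs(time_since_wake, level="time_since_wake")
    return sel.sort_index()


def screen_features(by_day: pd.DataFrame, time_since_wake: float,
                    threshold: float = DEFAULT_ICC_THRESHOLD,
                    min_participant_fraction: float = 0.5):
    """ICC-screen every feature column of a (participant, day)-indexed table.

    Returns ``(candidates, results)``: the feature names with ICC strictly
    above ``threshold``, and the full list of :class:`ICCResult`. A feature
    observed (on >= 2 days) for at most ``min_participant_fraction`` of
    participants is skipped with a warning.
    """
    participants = by_day.index.get_level_values("participant_id").unique()
    n_total = len(participants)
    candidates, results = [], []
    for feat in by_day.columns:
        table = by_day[feat].unstack("day")
        enough = (table.notna().sum(axis=1) >= 2).sum()
        if enough <= min_participant_fraction * n_total:
            log.warning("feature %s at %g h: only %d/%d participants with >=2 "
                        "days; skipped", feat, time_since_wake, enough, n_total)
            continue
        sigma_b, sigma_w = fit_variance_components(table)
        icc = icc_value(sigma_b, sigma_w)
        results.append(ICCResult(
            feature=feat, time_since_wake=time_since_wake,
            var_between=sigma_b, var_within=sigma_w, icc=icc,
            n_participants=int(enough), n_days=int(table.shape[1])))
        if icc > threshold:
            candidates.append(feat)
    return candidates, results


def write_icc_csv(results, path, threshold: float = DEFAULT_ICC_THRESHOLD) -> None:
    rows = [(r.feature, r.time_since_wake, r.var_between, r.var_within,
             r.icc, int(r.icc > threshold)) for r in results]
    pd.DataFrame(rows, columns=["feature", "time_since_wake_h", "var_between",
                                "var_within", "icc", "passed"]).to_csv(path, index=False)
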