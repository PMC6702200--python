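"""End-to-end orchestration: simulate -> QC -> features -> stratify ->
ICC screen -> wrapper search -> final models -> evaluation.

One discriminant model is developed per baseline time point (4, 6, 8, 10,
12, 14 h after wake), for the full cohort or for the high-performer
subgroup (<= 2 baseline lapses, re-stratified within). All stage outputs
are flat CSV/JSON files so each stage is independently inspectable and
re-runnable; all randomness flows from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluate as ev
from . import features as ft
from . import lda
from . import icc as icc_mod
from . import qc as qc_mod
from . import stratify as st
from . import wrapper as wr
from .synthetic import BASELINE_TIMES, ProtocolConfig, StudyDataset, simulate_study, \
    write_traits_csv, write_trials_csv

__all__ = ["RunConfig", "fast_config", "run_pipeline", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serialised alongside outputs."""

    n_participants: int = 160
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    percentile_grid: tuple = ft.DEFAULT_PERCENTILE_GRID
    lapse_thresholds: tuple = ft.DEFAULT_LAPSE_THRESHOLDS
    diff_thresholds: tuple = ft.DEFAULT_DIFF_THRESHOLDS
    icc_threshold: float = 0.60
    cost_grid: tuple = field(default_factory=lambda: tuple(lda.cost_grid()))
    cv: wr.CVConfig = field(default_factory=wr.CVConfig)
    cohort: str = "full"                      # "full" | "high_performer"
    baseline_times: tuple = BASELINE_TIMES
    patience: int = 5
    beam_width: int | None = None
    max_subset_size: int | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in ("full", "high_performer"):
            raise ValueError("cohort must be 'full' or 'high_performer'")
        # master seed drives both the simulator and the CV fold streams
        self.protocol.seed = self.seed
        self.cv.seed = self.seed

    def catalog(self) -> ft.FeatureCatalog:
        return ft.build_catalog(self.percentile_grid, self.lapse_thresholds,
                                self.diff_thresholds)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "protocol" in d:
            d["protocol"] = ProtocolConfig.from_dict(d["protocol"])
        if "cv" in d:
            d["cv"] = wr.CVConfig(**d["cv"])
        for key in ("percentile_grid", "lapse_thresholds", "diff_thresholds",
                    "cost_grid", "baseline_times"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def fast_config(seed: int = 0, n: int = 60, repeats: int = 10,
                beam_width: int = 5, times=(10.0,)) -> RunConfig:
    """Reduced-scale settings for tests and smoke runs.

    Coarser percentile grid (~71 features), 10 CV repeats, beam width 5,
    and a subset of baseline time points.
    """
    return RunConfig(
        n_participants=n,
        percentile_grid=tuple(range(10, 100, 10)),
        cv=wr.CVConfig(repeats=repeats),
        beam_width=beam_width,
        baseline_times=tuple(times),
        seed=seed,
    )


@dataclass
class PipelineResult:
    config: RunConfig
    study: StudyDataset
    included: list
    excluded: dict
    scores: pd.Series
    labels: pd.Series
    per_time: dict      # time -> dict(candidates, search, model, metrics, ...)

    def metrics_table(self) -> pd.DataFrame:
        """Table-1-shaped frame: metric rows x baseline-time columns."""
        cols = {}
        for t, res in self.per_time.items():
            frame = res["metrics"].as_frame()
            cols[f"{t:g}h"] = frame.apply(
                lambda r: f"{r['mean']:.3f} +/- {r['sd']:.3f}", axis=1)
        return pd.DataFrame(cols)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; returns in-memory results, writing artifacts
    to ``config.out_dir`` when set."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())

    log.info("simulating study: n=%d seed=%d", config.n_participants, config.seed)
    study = simulate_study(config.n_participants, config.protocol)

    reports = qc_mod.validate_study(study)
    included, excluded = qc_mod.select_participants(study, reports)
    log.info("QC: %d included, %d excluded", len(included), len(excluded))

    scores = st.tsd_scores(study, included)
    if config.cohort == "high_performer":
        cohort_ids = st.select_high_performers(study, included)
        log.info("high-performer subgroup: %d of %d", len(cohort_ids), len(included))
        scores = scores.loc[cohort_ids]
    labels = st.assign_labels(scores)

    catalog = config.catalog()
    matrix = ft.feature_matrix(study, catalog, reports)
    cohort_index = scores.index

    if out:
        write_trials_csv(study, out / "trials.csv")
        write_traits_csv(study, out / "traits_ground_truth.csv")
        qc_mod.write_validity_csv(reports, out / "validity.csv")
        st.write_labels_csv(scores, labels, out / "labels.csv", cohort=config.cohort)
        (out / "catalog.json").write_text(catalog.to_json())

    per_time = {}
    for t in config.baseline_times:
        log.info("time point %g h: ICC screening", t)
        by_day = icc_mod.per_time_table(matrix, t)
        by_day = by_day.loc[by_day.index.get_level_values("participant_id")
                            .isin(cohort_index)]
        candidates, icc_results = icc_mod.screen_features(
            by_day, t, threshold=config.icc_threshold)
        log.info("time point %g h: %d/%d candidates pass ICC > %.2f",
                 t, len(candidates), len(catalog), config.icc_threshold)

        X = by_day.xs(4, level="day").loc[lambda d: d.index.isin(cohort_index),
                                          candidates]
        usable = X.dropna().index
        X = X.loc[usable]
        y = labels.loc[usable]
        if not candidates or y.value_counts().min() < config.cv.folds:
            log.warning("time point %g h: not enough data to search; skipped", t)
            continue

        search = wr.best_first_search(
            X, y, candidates, cost_scalars=config.cost_grid, cv=config.cv,
            patience=config.patience, beam_width=config.beam_width,
            max_subset_size=config.max_subset_size)
        log.info("time point %g h: best subset %s at cost %.1f (CV acc %.3f)",
                 t, search.subset, search.cost_scalar, search.score)

        model = wr.fit_final(X, y, search.subset, search.cost_scalar)
        preds = wr.cross_validate(X, y, search.subset, search.cost_scalar, config.cv)
        metrics = ev.summarize_cv(y, preds)
        modal = ev.modal_assignment(preds)
        timecourse = ev.group_time_course(study, modal)

        per_time[t] = {
            "candidates": candidates,
            "icc": icc_results,
            "search": search,
            "model": model,
            "predictions": preds,
            "metrics": metrics,
            "modal": modal,
            "timecourse": timecourse,
            "n_used": len(usable),
        }
        if out:
            tag = f"t{t:g}h"
            icc_mod.write_icc_csv(icc_results, out / f"icc_{tag}.csv",
                                  threshold=config.icc_threshold)
            search.trace.to_csv(out / f"search_trace_{tag}.csv", index=False)
            (out / f"model_{tag}.json").write_text(model.to_json())
            metrics.as_frame().to_csv(out / f"metrics_{tag}.csv")
            preds.to_csv(out / f"cv_predictions_{tag}.csv")
            timecourse.to_csv(out / f"timecourse_{tag}.csv", index=False)

    result = PipelineResult(config=config, study=study, included=included,
                            excluded=excluded, scores=scores, labels=labels,
                            per_time=per_time)
    if out and per_time:
        result.metrics_table().to_csv(out / "metrics_summary.csv")
    return result
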