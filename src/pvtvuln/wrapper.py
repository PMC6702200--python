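"""Wrapper feature-subset search with repeated stratified cross-validation.

A forward-selection best-first search grows feature subsets one feature at a
time, scoring every candidate subset by its mean three-class accuracy under
repeated stratified 5-fold cross-validation, jointly over a grid of cost
scalars (a subset's score is its best accuracy over the grid). The search
always expands the highest-scoring unexpanded subset and terminates after
five consecutive expansions without strict improvement of the global best.
The final model refits the winning (subset, cost) pair on all participants.

Fold assignment is stratified: within each class, participants are shuffled
and dealt round-robin, so per-fold class counts differ by at most one (and
are exact at n = 160: 8/16/8 per fold). Fold draws for repeat r derive from
(master seed, r) only, so every subset is scored on identical folds and the
whole search is a pure function of (data, config, seed). Z-scoring and model
fitting use training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lda
from .stratify import CLASSES

__all__ = [
    "CVConfig",
    "stratified_folds",
    "evaluate_subset",
    "evaluate_subset_costs",
    "best_first_search",
    "cross_validate",
    "fit_final",
    "SearchResult",
]

log = logging.getLogger(__name__)

_FOLD_TAG = 0xF01D
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 100
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def stratified_folds(labels, k: int, seed) -> np.ndarray:
    """Fold assignment (0..k-1 per participant), stratified by class.

    ``seed`` may be an int, SeedSequence-compatible key, or Generator.
    Within each class members are shuffled then dealt round-robin.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(np.random.SeedSequence(seed))
    y = np.array([_CLASS_INDEX[l] if isinstance(l, str) else int(l)
                  for l in labels])
    folds = np.full(y.size, -1, dtype=int)
    for cls in range(3):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            continue
        if idx.size < k:
            raise ValueError(
                f"class {CLASSES[cls]} has {idx.size} members, fewer than {k} folds")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _prepare(X: pd.DataFrame, labels, subset):
    subset = tuple(subset)
    M = X[list(subset)].to_numpy(dtype=float) if subset \
        else np.empty((len(X), 0))
    ok = ~np.isnan(M).any(axis=1)
    if not ok.all():
        log.info("dropping %d participant(s) with missing values on subset %s",
                 int((~ok).sum()), subset)
    y = np.array([_CLASS_INDEX[l] for l in
                  (labels.loc[X.index] if isinstance(labels, pd.Series) else labels)])
    return M[ok], y[ok], np.asarray(X.index)[ok], subset


def _cv_posteriors(M: np.ndarray, y: np.ndarray, cv: CVConfig) -> np.ndarray:
    """Held-out posteriors, shape (repeats, n, 3); folds shared across subsets."""
    n = y.size
    labels_str = np.array(CLASSES, dtype=object)[y]
    out = np.empty((cv.repeats, n, 3))
    for r in range(cv.repeats):
        folds = stratified_folds(y, cv.folds, (cv.seed, _FOLD_TAG, r))
        for f in range(cv.folds):
            test = folds == f
            model = lda.fit(M[~test], labels_str[~test],
                            subset=tuple(f"f{i}" for i in range(M.shape[1])),
                            warn=False)
            out[r, test] = lda.posterior(model, M[test])
    return out


def _accuracy_by_cost(post: np.ndarray, y: np.ndarray, cost_matrices) -> dict:
    """Per-cost (mean, sd over repeats) pooled 3-class accuracy."""
    res = {}
    for cm in cost_matrices:
        pred = np.argmin(post @ cm.matrix, axis=2)   # (repeats, n)
        acc = (pred == y[None, :]).mean(axis=1)
        res[cm.scalar if cm.scalar is not None else cm] = (
            float(acc.mean()), float(acc.std(ddof=1)) if acc.size > 1 else 0.0)
    return res


def evaluate_subset_costs(X: pd.DataFrame, labels, subset, cost_scalars,
                          cv: CVConfig) -> dict:
    """Mean/SD CV accuracy of one subset at every cost scalar (shared folds)."""
    M, y, _, subset = _prepare(X, labels, subset)
    post = _cv_posteriors(M, y, cv)
    return _accuracy_by_cost(post, y, [lda.make_cost_matrix(c) for c in cost_scalars])


def evaluate_subset(X: pd.DataFrame, labels, subset, cost_scalar: float,
                    cv: CVConfig) -> tuple:
    """(mean, sd) three-class CV accuracy of ``subset`` at one cost scalar."""
    return evaluate_subset_costs(X, labels, subset, [cost_scalar], cv)[cost_scalar]


@dataclass
class SearchResult:
    subset: tuple
    cost_scalar: float
    score: float
    trace: pd.DataFrame          # iteration, subset, cost, mean_acc, sd_acc
    n_expansions: int


def _subset_key(subset) -> tuple:
    return tuple(sorted(subset))


def best_first_search(X: pd.DataFrame, labels, candidates,
                      cost_scalars=None, cv: CVConfig | None = None,
                      patience: int = 5, beam_width: int | None = None,
                      max_subset_size: int | None = None) -> SearchResult:
    """Forward-selection best-first search over (subset, cost scalar).

    Starts from the empty set; each iteration expands the highest-scoring
    unexpanded subset by every single-feature addition, scoring children at
    every cost in the grid (a child's score is its best over costs).
    Terminates after ``patience`` consecutive expansions with no strict
    improvement of the global best, when candidates are exhausted, or when
    ``beam_width`` prunes the frontier empty.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    if cost_scalars is None:
        cost_scalars = lda.cost_grid()
    cv = cv or CVConfig()

    trace_rows = []
    evaluated = {}           # key -> (best_score, best_cost)

    def score_subset(subset, iteration):
        key = _subset_key(subset)
        if key in evaluated:
            return evaluated[key]
        by_cost = evaluate_subset_costs(X, labels, key, cost_scalars, cv)
        best_cost = min(by_cost, key=lambda c: (-by_cost[c][0], c))
        best = (by_cost[best_cost][0], best_cost)
        for c in cost_scalars:
            m, s = by_cost[c]
            trace_rows.append((iteration, "+".join(key) or "<empty>", c, m, s))
        evaluated[key] = best
        return best

    root_score, root_cost = score_subset((), 0)
    best_global = (root_score, root_cost, ())
    frontier = {(): root_score}          # unexpanded subsets
    stall = 0
    n_exp = 0

    while frontier and stall < patience:
        node = min(frontier, key=lambda s: (-frontier[s], len(s), s))
        del frontier[node]
        if max_subset_size is not None and len(node) >= max_subset_size:
            continue
        n_exp += 1
        improved = False
        for feat in candidates:
            if feat in node:
                continue
            child = _subset_key(node + (feat,))
            if child in evaluated:
                continue
            sc, cost = score_subset(child, n_exp)
            frontier[child] = sc
            if sc > best_global[0]:
                best_global = (sc, cost, child)
                improved = True
        stall = 0 if improved else stall + 1
        if beam_width is not None and len(frontier) > beam_width:
            keep = sorted(frontier, key=lambda s: (-frontier[s], len(s), s))[:beam_width]
            frontier = {s: frontier[s] for s in keep}

    trace = pd.DataFrame(trace_rows,
                         columns=["iteration", "subset", "cost", "mean_acc", "sd_acc"])
    score, cost, subset = best_global[0], best_global[1], best_global[2]
    return SearchResult(subset=subset, cost_scalar=cost, score=score,
                        trace=trace, n_expansions=n_exp)


def cross_validate(X: pd.DataFrame, labels, subset, cost_scalar: float,
                   cv: CVConfig) -> pd.DataFrame:
    """Held-out predictions for every repeat (participants x repeats).

    Cells hold predicted class labels under the expected-cost rule; the
    per-participant mode of each row gives the modal group assignment.
    """
    M, y, ids, subset = _prepare(X, labels, subset)
    post = _cv_posteriors(M, y, cv)
    cm = lda.make_cost_matrix(cost_scalar)
    pred_idx = np.argmin(post @ cm.matrix, axis=2)          # (repeats, n)
    pred = np.array(CLASSES, dtype=object)[pred_idx]
    return pd.DataFrame(pred.T, index=ids,
                        columns=[f"run{r:03d}" for r in range(cv.repeats)])


def fit_final(X: pd.DataFrame, labels, subset, cost_scalar: float,
              shrinkage: float = 0.0) -> lda.DiscriminantModel:
    """Refit the chosen (subset, cost) on the entire dataset."""
    M, y, _, subset = _prepare(X, labels, subset)
    labels_str = np.array(CLASSES, dtype=object)[y]
    return lda.fit(M, labels_str, subset=subset,
                   cost=lda.make_cost_matrix(cost_scalar), shrinkage=shrinkage)
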