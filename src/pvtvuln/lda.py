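"""Cost-sensitive three-class linear discriminant model.

Features are z-scored with training-set parameters, z = (d - mu)/sigma.
With class means m_k on the z scale, pooled within-class covariance S and
empirical priors pi_k, the discriminant functions are

    g_k(z) = w_k . z + c_k,   w_k = S^-1 m_k,
    c_k = -1/2 m_k . S^-1 m_k + log pi_k,

so softmax(g) is the Gaussian-Bayes posterior (the quadratic term is shared
across classes and cancels). Decisions minimise expected cost under a 3x3
cost matrix C[true, predicted]; at uniform cost this reduces to the
highest-posterior (equivalently highest-discriminant) assignment.

The cost-matrix family is generated by one scalar c in [1, 5]: misclassifying
an extreme class (resilient or vulnerable) costs c, misclassifying an
intermediate participant costs 1. Any full 3x3 matrix is also accepted.
Singular pooled covariances are handled by a shrinkage ladder toward the
diagonal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stratify import CLASSES

__all__ = [
    "CostMatrix",
    "DiscriminantModel",
    "make_cost_matrix",
    "cost_grid",
    "fit",
    "posterior",
    "decide",
    "predict",
]

log = logging.getLogger(__name__)

SHRINKAGE_LADDER = (0.0, 0.1, 0.5, 1.0)
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class CostMatrix:
    """C[true, predicted] misclassification costs, zero diagonal."""

    matrix: np.ndarray
    scalar: float | None = None   # generator c when built by make_cost_matrix

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("cost matrix must be 3x3")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("cost matrix diagonal must be zero")
        if np.any(m < 0.0):
            raise ValueError("costs must be nonnegative")
        object.__setattr__(self, "matrix", m)


def make_cost_matrix(c: float) -> CostMatrix:
    """Scalar-generated family: extreme-class errors cost ``c``, others 1."""
    if c < 1.0:
        raise ValueError("cost scalar must be >= 1")
    m = np.zeros((3, 3))
    for i, true in enumerate(CLASSES):
        for j in range(3):
            if i != j:
                m[i, j] = c if true in ("resilient", "vulnerable") else 1.0
    return CostMatrix(matrix=m, scalar=float(c))


def cost_grid(lo: float = 1.0, hi: float = 5.0, step: float = 0.5) -> list:
    """The swept scalar grid, default 1.0 .. 5.0 in 0.5 steps (9 values)."""
    n = int(round((hi - lo) / step)) + 1
    return [round(lo + i * step, 10) for i in range(n)]


@dataclass
class DiscriminantModel:
    feature_subset: tuple
    z_mu: np.ndarray
    z_sigma: np.ndarray
    weights: np.ndarray       # 3 x p, rows in CLASSES order
    constants: np.ndarray     # 3
    priors: np.ndarray        # 3, sums to 1
    cost: CostMatrix
    shrinkage: float = 0.0

    def to_json(self) -> str:
        return json.dumps({
            "feature_subset": list(self.feature_subset),
            "z_mu": self.z_mu.tolist(),
            "z_sigma": self.z_sigma.tolist(),
            "weights": self.weights.tolist(),
            "constants": self.constants.tolist(),
            "priors": self.priors.tolist(),
            "cost_matrix": self.cost.matrix.tolist(),
            "cost_scalar": self.cost.scalar,
            "shrinkage": self.shrinkage,
            "classes": list(CLASSES),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        return cls(
            feature_subset=tuple(d["feature_subset"]),
            z_mu=np.asarray(d["z_mu"], dtype=float),
            z_sigma=np.asarray(d["z_sigma"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            constants=np.asarray(d["constants"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            cost=CostMatrix(np.asarray(d["cost_matrix"], dtype=float),
                            d.get("cost_scalar")),
            shrinkage=float(d["shrinkage"]),
        )


def _as_matrix(X, subset) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[list(subset)].to_numpy(dtype=float) if subset else np.empty((len(X), 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X


def _label_indices(labels) -> np.ndarray:
    return np.array([_CLASS_INDEX[l] for l in labels], dtype=int)


def fit(X, labels, subset=None, cost: CostMatrix | None = None,
        shrinkage: float = 0.0, warn: bool = True) -> DiscriminantModel:
    """Fit the discriminant model on training rows.

    ``X`` is a DataFrame (``subset`` names its columns) or an array already
    restricted to the subset. Rows with missing values are rejected; drop
    them upstream. ``shrinkage`` blends the pooled covariance toward its
    diagonal; if inversion fails the ladder {0, 0.1, 0.5, 1} is climbed with
    a warning.
    """
    if subset is None:
        subset = tuple(X.columns) if isinstance(X, pd.DataFrame) else \
            tuple(f"f{i}" for i in range(np.asarray(X).shape[1]))
    subset = tuple(subset)
    M = _as_matrix(X, subset)
    if np.isnan(M).any():
        raise ValueError("training matrix contains missing values")
    y = _label_indices(labels)
    if M.shape[0] != y.size:
        raise ValueError("X and labels disagree on n")
    counts = np.bincount(y, minlength=3)
    if np.any(counts < 2):
        raise ValueError("need >= 2 training participants per class")
    if cost is None:
        cost = make_cost_matrix(1.0)

    mu = M.mean(axis=0)
    sigma = M.std(axis=0)          # population SD (ddof=0), documented
    degenerate = sigma <= 0.0
    if degenerate.any():
        log.log(logging.WARNING if warn else logging.DEBUG,
                "%d constant feature(s) in training data; z set to 0",
                int(degenerate.sum()))
        sigma = np.where(degenerate, 1.0, sigma)
    Z = (M - mu) / sigma

    p = Z.shape[1]
    means = np.vstack([Z[y == k].mean(axis=0) for k in range(3)]) \
        if p else np.empty((3, 0))
    pooled = np.zeros((p, p))
    for k in range(3):
        R = Z[y == k] - means[k]
        pooled += R.T @ R
    pooled /= max(1, M.shape[0] - 3)

    ladder = [s for s in SHRINKAGE_LADDER if s >= shrinkage] or [1.0]
    inv = None
    for gamma in ladder:
        S = (1.0 - gamma) * pooled + gamma * np.diag(np.diag(pooled))
        if p and gamma == 1.0 and np.any(np.diag(S) <= 0):
            S = S + np.eye(p) * 1e-12
        try:
            if p:
                cond = np.linalg.cond(S)
                if not np.isfinite(cond) or cond > 1e10:
                    raise np.linalg.LinAlgError("ill-conditioned")
            inv = np.linalg.inv(S) if p else np.empty((0, 0))
        except np.linalg.LinAlgError:
            continue
        if gamma > shrinkage:
            log.log(logging.WARNING if warn else logging.DEBUG,
                    "pooled covariance singular at shrinkage %.2f; "
                    "increased to %.2f", shrinkage, gamma)
        shrinkage = gamma
        break
    if inv is None:
        raise np.linalg.LinAlgError("pooled covariance singular even at full shrinkage")

    priors = counts / counts.sum()
    W = means @ inv                                 # 3 x p
    const = -0.5 * np.einsum("kp,kp->k", W, means) + np.log(priors)
    return DiscriminantModel(
        feature_subset=subset, z_mu=mu, z_sigma=sigma, weights=W,
        constants=const, priors=priors, cost=cost, shrinkage=shrinkage,
    )


def discriminants(model: DiscriminantModel, X) -> np.ndarray:
    """g_k for each row of raw-feature input (n x 3; NaN rows -> NaN)."""
    M = _as_matrix(X, model.feature_subset)
    Z = (M - model.z_mu) / model.z_sigma
    G = Z @ model.weights.T + model.constants
    bad = np.isnan(M).any(axis=1)
    G[bad] = np.nan
    return G


def posterior(model: DiscriminantModel, X) -> np.ndarray:
    """Class posteriors, softmax of the discriminants (rows sum to 1)."""
    G = discriminants(model, X)
    shift = np.max(np.where(np.isnan(G), -np.inf, G), axis=1, keepdims=True)
    P = np.exp(G - shift)
    P /= P.sum(axis=1, keepdims=True)
    return P


def decide(posteriors, cost: CostMatrix) -> str:
    """Expected-cost-minimising class for one posterior vector.

    Expected cost of predicting class j is sum_i C[i, j] * posterior_i; at
    uniform cost this is argmax posterior. Ties break to the lowest class in
    the fixed order (resilient < intermediate < vulnerable).
    """
    p = np.asarray(posteriors, dtype=float)
    exp_cost = cost.matrix.T @ p
    return CLASSES[int(np.argmin(exp_cost))]   # argmin takes first on ties


def predict(model: DiscriminantModel, X) -> np.ndarray:
    """Expected-cost-minimising labels (object array; None when undefined)."""
    P = posterior(model, X)
    out = np.empty(P.shape[0], dtype=object)
    for r in range(P.shape[0]):
        out[r] = None if np.isnan(P[r]).any() else decide(P[r], model.cost)
    return out
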