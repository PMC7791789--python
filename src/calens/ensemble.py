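"""Combining base-model probability outputs.

Three combiners over m base models' score vectors:

* simple averaging (every weight 1/m; 0.2 for the five-model setup),
* weighted averaging with weights proportional to the reciprocal of each
  model's calibration error (ECE or MCE) measured on its out-of-fold
  predictions, and
* stacking: a logistic meta-learner regressing the outcome on the m score
  columns, trained on out-of-fold predictions so that the meta-learner never
  sees resubstitution scores. A tiny ridge penalty (1e-6) on the slopes
  keeps the fit stable when the base outputs are nearly collinear, which
  five correlated probability columns routinely are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .errors import ConfigError, DegenerateTrainingError
from .learners import ScoreSet
from .metrics import calibration_errors

__all__ = [
    "EnsembleWeights",
    "StackingModel",
    "combine_average",
    "compute_error_weights",
    "fit_stacking",
    "predict_stacking",
]

_ERROR_FLOOR = 1e-6


@dataclass
class EnsembleWeights:
    """Nonnegative per-model weights summing to 1."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ConfigError("weights must be nonnegative and sum to 1")

    @classmethod
    def uniform(cls, m: int) -> "EnsembleWeights":
        return cls(np.full(m, 1.0 / m))

    def to_dict(self) -> dict:
        return {"weights": [float(w) for w in self.weights]}


@dataclass
class StackingModel:
    """Logistic meta-learner: sigmoid(intercept + coefficients . scores)."""

    intercept: float
    coefficients: np.ndarray
    ridge: float = _ERROR_FLOOR

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not (np.isfinite(self.intercept) and np.isfinite(self.coefficients).all()):
            raise ConfigError("stacking parameters must be finite")

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": [float(c) for c in self.coefficients],
            "ridge": float(self.ridge),
        }


def _score_matrix(score_sets: list[ScoreSet]) -> np.ndarray:
    if not score_sets:
        raise ConfigError("need at least one score set")
    lengths = {len(s) for s in score_sets}
    if len(lengths) != 1:
        raise ConfigError(f"score sets have mismatched lengths {sorted(lengths)}")
    return np.column_stack([s.scores for s in score_sets])


def combine_average(
    score_sets: list[ScoreSet], weights: EnsembleWeights | None = None,
    producer: str = "ensemble", split: str = "test",
) -> ScoreSet:
    """Elementwise weighted average of score sets (uniform if no weights)."""
    M = _score_matrix(score_sets)
    if weights is None:
        weights = EnsembleWeights.uniform(M.shape[1])
    if len(weights.weights) != M.shape[1]:
        raise ConfigError(
            f"{len(weights.weights)} weights for {M.shape[1]} score sets"
        )
    combined = M @ weights.weights
    labels = score_sets[0].labels
    return ScoreSet(scores=combined, producer=producer, split=split, labels=labels)


def compute_error_weights(
    oof_sets: list[ScoreSet], metric: str = "ECE", n_bins: int = 10
) -> EnsembleWeights:
    """Weights proportional to 1 / calibration error on out-of-fold scores.

    ``metric`` is 'ECE' or 'MCE'; errors below 1e-6 are floored there so a
    perfectly calibrated model cannot swallow the whole ensemble.
    """
    if len(oof_sets) < 2:
        raise ConfigError("reciprocal-error weighting needs at least 2 models")
    metric = metric.upper()
    if metric not in ("ECE", "MCE"):
        raise ConfigError(f"metric must be 'ECE' or 'MCE', got {metric!r}")
    errors = []
    for ss in oof_sets:
        if ss.labels is None:
            raise ConfigError(f"score set {ss.producer!r} has no labels")
        ece, mce, _ = calibration_errors(ss.scores, ss.labels, n_bins)
        errors.append(ece if metric == "ECE" else mce)
    recip = 1.0 / np.maximum(np.asarray(errors), _ERROR_FLOOR)
    return EnsembleWeights(recip / recip.sum())


def fit_stacking(
    oof_matrix: np.ndarray, labels: np.ndarray, ridge: float = _ERROR_FLOOR
) -> StackingModel:
    """Ridge-stabilized logistic regression of labels on score columns.

    Deterministic L-BFGS minimization of the negative log-likelihood plus
    0.5 * ridge * ||slopes||^2 (the intercept is unpenalized).
    """
    X = np.asarray(oof_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(float)
    if len(y) != X.shape[0]:
        raise ConfigError("label length does not match score matrix rows")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("stacking labels contain a single class")
    n, m = X.shape
    Z = np.hstack([np.ones((n, 1)), X])

    def nll(w):
        eta = Z @ w
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta)) + 0.5 * ridge * float(
            w[1:] @ w[1:]
        )

    def grad(w):
        p = expit(Z @ w)
        g = Z.T @ (p - y)
        g[1:] += ridge * w[1:]
        return g

    result = minimize(
        nll,
        np.zeros(m + 1),
        jac=grad,
        method="L-BFGS-B",
        options={"gtol": 1e-10, "ftol": 1e-15, "maxiter": 2000},
    )
    w = result.x
    return StackingModel(intercept=float(w[0]), coefficients=w[1:], ridge=ridge)


def predict_stacking(
    model: StackingModel, score_matrix: np.ndarray,
    producer: str = "stacking", split: str = "test",
    labels: np.ndarray | None = None,
) -> ScoreSet:
    """Sigmoid of the meta-learner's linear combination; outputs in (0, 1)."""
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(model.coefficients):
        raise ConfigError(
            f"score matrix has {X.shape[1]} columns, model expects "
            f"{len(model.coefficients)}"
        )
    p = expit(model.intercept + X @ model.coefficients)
    return ScoreSet(scores=p, producer=producer, split=split, labels=labels)
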