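"""Post-hoc probability calibration.

Three monotone maps from a classifier's raw score s to a calibrated event
probability:

* **Shape-restricted polynomial regression (RPR).** A degree-k polynomial
  f(s) = a_0 + a_1 s + ... + a_k s^k fitted by constrained least squares:
  minimize the mean squared error to the binary labels subject to
  (a) f(s_min) >= 0 and f(s_max) <= 1, (b) f'(s) >= 0 on a 201-point grid
  over [s_min, s_max] (monotonicity), and (c) an l1 bound sum|a_l| <= lambda
  against overfitting. Together (a) and (b) keep f inside [0, 1] on the
  training score range. The program is a convex QP, solved here after the
  variable split a = u - v (u, v >= 0), which turns the l1 bound into a
  linear constraint.

* **Platt scaling.** f(s) = 1 / (1 + exp(A s + B)) with (A, B) the maximum-
  likelihood fit against the usual smoothed targets
  t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2), which keep the MLE finite on
  separable calibration sets. Newton iterations with backtracking.

* **Isotonic regression.** The least-squares non-decreasing fit to the
  labels sorted by score, computed by the pair-adjacent-violators (PAV)
  algorithm; tied scores are pooled into a single block (with the block's
  mean label) before pooling. Prediction is piecewise-constant: the fitted
  value of the largest breakpoint at or below the query, clamped at the
  range ends.

All calibrators expose ``predict(scores)`` returning probabilities in
[0, 1], non-decreasing in the input score, and serialize to plain dicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, minimize
from scipy.special import expit

from .errors import CalibrationFailure, ConfigError, DegenerateTrainingError, NotFittedError

__all__ = [
    "CalibrationTrainingSet",
    "RprCalibrator",
    "PlattCalibrator",
    "IsotonicCalibrator",
    "fit_rpr",
    "select_rpr_hyperparams",
    "fit_platt",
    "fit_isotonic",
    "fit_calibrator",
    "apply_calibrator",
    "calibrator_from_dict",
    "RPR_DEGREE_GRID",
    "RPR_LAMBDA_GRID",
]

#: Default hyperparameter grids for RPR model selection.
RPR_DEGREE_GRID: tuple[int, ...] = tuple(range(4, 21))
RPR_LAMBDA_GRID: tuple[float, ...] = tuple(4.0**i for i in range(-1, 6))

_MAX_DEGREE = 25  # conditioning guard for the raw monomial basis
_N_MONOTONE_GRID = 201


@dataclass
class CalibrationTrainingSet:
    """Raw scores and calibration targets.

    Targets are usually the binary outcomes, but any values in [0, 1] are
    accepted by the least-squares calibrators (RPR, isotonic); Platt scaling
    requires genuinely binary targets.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.scores.ndim != 1 or self.scores.shape != self.labels.shape:
            raise ConfigError("scores and labels must be 1-d and equal length")
        if len(self.labels) and not (
            np.isfinite(self.labels).all()
            and self.labels.min() >= 0.0
            and self.labels.max() <= 1.0
        ):
            raise ConfigError("calibration targets must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.labels, (0.0, 1.0)).all())

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise DegenerateTrainingError(
                "calibration training set has a single target value"
            )


# ---------------------------------------------------------------------------
# Shape-restricted polynomial regression
# ---------------------------------------------------------------------------


@dataclass
class RprCalibrator:
    """Fitted shape-restricted polynomial a_0..a_k on score range [lo, hi]."""

    coefficients: np.ndarray
    degree: int
    l1_bound: float
    score_range: tuple[float, float]

    def predict(self, scores) -> np.ndarray:
        s = np.clip(np.asarray(scores, dtype=float), *self.score_range)
        out = np.polyval(self.coefficients[::-1], s)
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "family": "rpr",
            "coefficients": [float(c) for c in self.coefficients],
            "degree": int(self.degree),
            "l1_bound": float(self.l1_bound),
            "score_range": [float(x) for x in self.score_range],
        }


def fit_rpr(
    data: CalibrationTrainingSet, k: int, lam: float
) -> RprCalibrator:
    """Fit the degree-k polynomial calibrator with l1 bound ``lam``.

    The convex QP is solved with a trust-region interior-point method after
    splitting a = u - v; the monotonicity constraint is enforced on a
    201-point uniform grid over the training score range (predictions are
    additionally clipped to [0, 1], which covers gaps between grid points).
    """
    if k < 1:
        raise ConfigError("polynomial degree k must be >= 1")
    if k > _MAX_DEGREE:
        raise ConfigError(f"degree k={k} exceeds the conditioning cap {_MAX_DEGREE}")
    if lam < 0:
        raise ConfigError("l1 bound lambda must be nonnegative")
    data.require_both_classes()

    s = data.scores
    y = data.labels.astype(float)
    lo, hi = float(s.min()), float(s.max())
    N = len(s)
    m = k + 1

    X = np.vander(s, m, increasing=True)
    P = (2.0 / N) * (X.T @ X)
    q = (-2.0 / N) * (X.T @ y)
    H = np.block([[P, -P], [-P, P]])

    def objective(z):
        a = z[:m] - z[m:]
        r = X @ a - y
        return float(r @ r) / N

    def gradient(z):
        a = z[:m] - z[m:]
        ga = P @ a + q
        return np.concatenate([ga, -ga])

    # linear constraints in a-space (A a >= b), lifted to z = [u; v]
    powers = np.arange(m)
    grid = np.linspace(lo, hi, _N_MONOTONE_GRID)
    deriv = grid[:, None] ** np.clip(powers - 1, 0, None)[None, :] * powers[None, :]
    A = np.vstack([lo**powers, -(hi**powers), deriv])
    b = np.concatenate([[0.0, -1.0], np.zeros(len(grid))])
    constraints = [
        LinearConstraint(np.hstack([A, -A]), b, np.inf),
        LinearConstraint(np.ones(2 * m), -np.inf, lam),
    ]

    result = minimize(
        objective,
        np.zeros(2 * m),
        jac=gradient,
        hess=lambda z: H,
        method="trust-constr",
        bounds=[(0.0, None)] * (2 * m),
        constraints=constraints,
        options={"gtol": 1e-9, "xtol": 1e-10, "maxiter": 1000},
    )
    if result.status not in (1, 2) or result.constr_violation > 1e-6:
        raise CalibrationFailure(
            f"RPR solver failed (status {result.status}, "
            f"violation {result.constr_violation:.2e})",
            status=result.status,
        )
    a = _polish(result.x[:m] - result.x[m:], X, P, q, y, N, A, b, lam)
    return RprCalibrator(
        coefficients=a, degree=k, l1_bound=float(lam), score_range=(lo, hi)
    )


def _polish(a0, X, P, q, y, N, A, b, lam):
    """Active-set refinement of the interior-point solution.

    The u - v split leaves a flat direction that stalls trust-constr about
    1e-3 short of vertex optima; a warm-started SLSQP pass in a-space
    sharpens it. The polished point is kept only if it stays feasible and
    does not worsen the objective.
    """

    def obj(a):
        r = X @ a - y
        return float(r @ r) / N

    res = minimize(
        obj,
        a0,
        jac=lambda a: P @ a + q,
        method="SLSQP",
        constraints=[
            {"type": "ineq", "fun": lambda a: A @ a - b, "jac": lambda a: A},
            {
                "type": "ineq",
                "fun": lambda a: lam - np.abs(a).sum(),
                "jac": lambda a: -np.sign(a),
            },
        ],
        options={"ftol": 1e-14, "maxiter": 200},
    )
    a1 = res.x
    violation = max(
        float(np.maximum(b - A @ a1, 0.0).max()),
        float(np.abs(a1).sum() - lam),
        0.0,
    )
    if res.status == 0 and violation <= 1e-8 and obj(a1) <= obj(a0) + 1e-12:
        return a1
    return a0


def _stratified_cv_folds(labels: np.ndarray, n_folds: int, seed: int):
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def select_rpr_hyperparams(
    data: CalibrationTrainingSet,
    n_folds: int = 3,
    seed: int = 0,
    degrees=RPR_DEGREE_GRID,
    lambdas=RPR_LAMBDA_GRID,
) -> tuple[int, float]:
    """Choose (k, lambda) by stratified CV, minimizing validation MSE.

    Ties are broken toward smaller k, then smaller lambda (the iteration
    order, with strict improvement required to switch). Grid points whose
    fits fail are skipped; an entirely infeasible grid raises.
    """
    if len(data) < 3 * n_folds:
        raise ConfigError(
            f"need at least {3 * n_folds} samples for {n_folds}-fold selection"
        )
    data.require_both_classes()
    folds = _stratified_cv_folds(data.labels, n_folds, seed)
    n = len(data)
    best = None
    best_err = np.inf
    for k in sorted(degrees):
        for lam in sorted(lambdas):
            errs = []
            try:
                for val_idx in folds:
                    mask = np.ones(n, dtype=bool)
                    mask[val_idx] = False
                    cal = fit_rpr(
                        CalibrationTrainingSet(
                            data.scores[mask], data.labels[mask]
                        ),
                        k,
                        lam,
                    )
                    pred = cal.predict(data.scores[val_idx])
                    errs.append(np.mean((pred - data.labels[val_idx]) ** 2))
            except (CalibrationFailure, DegenerateTrainingError):
                continue
            err = float(np.mean(errs))
            if err < best_err - 1e-12:
                best_err = err
                best = (k, float(lam))
    if best is None:
        raise CalibrationFailure("every (k, lambda) grid point was infeasible")
    return best


# ---------------------------------------------------------------------------
# Platt scaling
# ---------------------------------------------------------------------------


@dataclass
class PlattCalibrator:
    """Fitted sigmoid map f(s) = 1 / (1 + exp(A s + B))."""

    A: float
    B: float

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return expit(-(self.A * s + self.B))

    def to_dict(self) -> dict:
        return {"family": "platt", "A": float(self.A), "B": float(self.B)}


def fit_platt(
    data: CalibrationTrainingSet, max_iter: int = 200, gtol: float = 1e-9
) -> PlattCalibrator:
    """Maximum-likelihood sigmoid fit with smoothed targets.

    Newton's method with backtracking on the convex cross-entropy of the
    targets t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2); converged when the
    gradient norm drops below 1e-9.
    """
    data.require_both_classes()
    if not data.is_binary:
        raise ConfigError("Platt scaling requires binary targets")
    s = data.scores
    y = data.labels.astype(np.int64)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(A, B):
        f = A * s + B
        # -sum[t log p + (1-t) log(1-p)] with p = sigmoid(-f), stably:
        return float(np.sum(t * f + np.logaddexp(0.0, -f)))

    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    value = nll(A, B)
    for _ in range(max_iter):
        f = A * s + B
        p = expit(-f)
        d = t - p  # dF/df
        g = np.array([np.sum(d * s), np.sum(d)])
        if np.linalg.norm(g) < gtol:
            return PlattCalibrator(A=A, B=B)
        w = p * (1.0 - p)
        h11 = np.sum(w * s * s) + 1e-12
        h12 = np.sum(w * s)
        h22 = np.sum(w) + 1e-12
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g[0] - h12 * g[1]) / det
        dB = -(h11 * g[1] - h12 * g[0]) / det
        step = 1.0
        while step > 1e-10:
            cand = nll(A + step * dA, B + step * dB)
            if cand < value + 1e-12:
                A, B, value = A + step * dA, B + step * dB, cand
                break
            step /= 2.0
        else:
            break
    f = A * s + B
    g = np.array([np.sum((t - expit(-f)) * s), np.sum(t - expit(-f))])
    if np.linalg.norm(g) < 1e-6:  # flat optimum reached before gtol
        return PlattCalibrator(A=A, B=B)
    raise CalibrationFailure(
        f"Platt Newton iterations did not converge (|g| = {np.linalg.norm(g):.2e})"
    )


# ---------------------------------------------------------------------------
# Isotonic regression via pair-adjacent violators
# ---------------------------------------------------------------------------


@dataclass
class IsotonicCalibrator:
    """Fitted non-decreasing step function: ``values[i]`` at ``breakpoints[i]``."""

    breakpoints: np.ndarray
    values: np.ndarray

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        idx = np.searchsorted(self.breakpoints, s, side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        return self.values[idx]

    def to_dict(self) -> dict:
        return {
            "family": "isotonic",
            "breakpoints": [float(x) for x in self.breakpoints],
            "values": [float(x) for x in self.values],
        }


def _pav(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pair-adjacent-violators: the least-squares non-decreasing fit."""
    n = len(values)
    # blocks as (mean, weight, count), merged while decreasing
    means = np.empty(n)
    wts = np.empty(n)
    counts = np.empty(n, dtype=np.int64)
    top = 0
    for i in range(n):
        means[top], wts[top], counts[top] = values[i], weights[i], 1
        top += 1
        while top > 1 and means[top - 2] >= means[top - 1]:
            w = wts[top - 2] + wts[top - 1]
            means[top - 2] = (
                wts[top - 2] * means[top - 2] + wts[top - 1] * means[top - 1]
            ) / w
            wts[top - 2] = w
            counts[top - 2] += counts[top - 1]
            top -= 1
    return np.repeat(means[:top], counts[:top])


def fit_isotonic(data: CalibrationTrainingSet) -> IsotonicCalibrator:
    """Least-squares monotone fit of labels sorted by score (PAV).

    Tied scores are pooled into one block, carrying the block's mean label
    and its size as weight, before the violator-pooling pass; the result is
    exactly the monotone least-squares fit of the original samples.
    """
    if len(data) < 2:
        raise ConfigError("isotonic regression needs at least 2 samples")
    order = np.argsort(data.scores, kind="stable")
    s_sorted = data.scores[order]
    y_sorted = data.labels[order].astype(float)
    uniq, start = np.unique(s_sorted, return_index=True)
    block_means = np.add.reduceat(y_sorted, start) / np.diff(
        np.append(start, len(y_sorted))
    )
    block_weights = np.diff(np.append(start, len(y_sorted))).astype(float)
    fitted = _pav(block_means, block_weights)
    return IsotonicCalibrator(breakpoints=uniq, values=fitted)


# ---------------------------------------------------------------------------
# Uniform application / serialization
# ---------------------------------------------------------------------------

_FAMILY_FITTERS = {
    "rpr": None,  # needs (k, lam); handled in fit_calibrator
    "platt": fit_platt,
    "isotonic": fit_isotonic,
}


def fit_calibrator(
    method: str,
    data: CalibrationTrainingSet,
    rpr_degrees=RPR_DEGREE_GRID,
    rpr_lambdas=RPR_LAMBDA_GRID,
    n_folds: int = 3,
    seed: int = 0,
):
    """Fit a calibrator by family name ('rpr' | 'platt' | 'isotonic').

    For RPR, (k, lambda) are chosen by stratified CV over the supplied grids
    (a single-point grid skips the CV and fits directly).
    """
    method = method.lower()
    if method == "rpr":
        degrees = tuple(rpr_degrees)
        lambdas = tuple(rpr_lambdas)
        if len(degrees) == 1 and len(lambdas) == 1:
            k, lam = degrees[0], lambdas[0]
        else:
            k, lam = select_rpr_hyperparams(
                data, n_folds=n_folds, seed=seed, degrees=degrees, lambdas=lambdas
            )
        return fit_rpr(data, k, lam)
    if method in _FAMILY_FITTERS and _FAMILY_FITTERS[method] is not None:
        return _FAMILY_FITTERS[method](data)
    raise ConfigError(f"unknown calibration method {method!r}")


def apply_calibrator(calibrator, scores) -> np.ndarray:
    """Apply a fitted calibrator; probabilities are always within [0, 1]."""
    if calibrator is None or not hasattr(calibrator, "predict"):
        raise NotFittedError("calibrator is not fitted")
    return np.clip(calibrator.predict(scores), 0.0, 1.0)


def calibrator_from_dict(d: dict):
    family = d.get("family")
    if family == "rpr":
        return RprCalibrator(
            coefficients=np.asarray(d["coefficients"], float),
            degree=int(d["degree"]),
            l1_bound=float(d["l1_bound"]),
            score_range=tuple(d["score_range"]),
        )
    if family == "platt":
        return PlattCalibrator(A=float(d["A"]), B=float(d["B"]))
    if family == "isotonic":
        return IsotonicCalibrator(
            breakpoints=np.asarray(d["breakpoints"], float),
            values=np.asarray(d["values"], float),
        )
    raise ConfigError(f"unknown calibrator family {family!r}")
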