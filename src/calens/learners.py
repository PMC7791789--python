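"""Base classifiers behind a single fit/predict interface.

Five families produce raw probability scores for the two-year death outcome:
naive Bayes (categorical likelihoods, add-one smoothing), logistic
regression, random forest (score = fraction of trees voting for the event),
support vector machine (decision values min-max mapped to [0, 1] over the
training set), and a feedforward network with one 500-unit hidden layer.
An additional oracle family returns the generating probability of each
patient (optionally distorted) and is the workhorse of the test suite: it
plugs into the exact same interface, so the evaluation harness can be
exercised with a learner whose calibration properties are known a priori.

Categorical covariates are dummy-coded against each declared reference level
for the linear/margin/network families and passed as integer level codes to
the forest and naive Bayes. All stochastic families are deterministic given
(spec.seed, cohort).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import CategoricalNB
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort import Cohort, CovariateSpec, DistortionSpec, GeneratorConfig, validate_levels, distort_probabilities
from .errors import ConfigError, DegenerateTrainingError
from .metrics import auc

__all__ = [
    "FAMILIES",
    "LearnerSpec",
    "FittedLearner",
    "ScoreSet",
    "default_grid",
    "fit_base_learner",
    "predict_scores",
    "tune_hyperparameters",
]

FAMILIES = ("NB", "LOGIT", "RF", "SVM", "FNN", "ORACLE")

#: Hyperparameter grids searched by 3-fold CV. NB and LOGIT have none.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {
        "max_features": [2, 3],
        "n_estimators": list(range(500, 1501, 100)),
    },
    "SVM": {
        "kernel": ["linear", "rbf"],
        "C": [10.0**i for i in range(-4, 5)],
        "gamma": [10.0**i for i in range(-4, 5)],
    },
}

#: Fixed network architecture: 3 layers total, one hidden layer of 500 units.
FNN_DEFAULTS: dict[str, Any] = {
    "hidden_layer_sizes": (500,),
    "activation": "relu",
    "solver": "adam",
    "early_stopping": True,
    "validation_fraction": 0.1,
    "n_iter_no_change": 20,
    "max_iter": 500,
}


def default_grid(family: str) -> dict[str, list]:
    return {k: list(v) for k, v in DEFAULT_GRIDS.get(family, {}).items()}


@dataclass(frozen=True)
class LearnerSpec:
    """A base-model family plus its hyperparameters.

    ``params`` values that are lists are grid axes to be resolved by
    :func:`tune_hyperparameters`; scalar values are fixed.
    """

    family: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    name: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown learner family {self.family!r}")

    @property
    def label(self) -> str:
        return self.name or self.family

    @property
    def grid_axes(self) -> dict[str, list]:
        return {k: v for k, v in self.params.items() if isinstance(v, list)}

    @property
    def is_resolved(self) -> bool:
        return not self.grid_axes

    def grid_points(self) -> list[dict[str, Any]]:
        """All grid combinations, in axis insertion order (first wins ties)."""
        axes = self.grid_axes
        fixed = {k: v for k, v in self.params.items() if not isinstance(v, list)}
        if not axes:
            return [dict(fixed)]
        keys = list(axes)
        return [
            {**fixed, **dict(zip(keys, combo))}
            for combo in itertools.product(*(axes[k] for k in keys))
        ]

    def resolved(self, params: dict[str, Any]) -> "LearnerSpec":
        return replace(self, params=dict(params))

    @classmethod
    def with_default_grid(cls, family: str, seed: int = 0, name: str | None = None) -> "LearnerSpec":
        return cls(family=family, params=default_grid(family), seed=seed, name=name)


@dataclass
class ScoreSet:
    """Per-sample probability scores in [0, 1], tagged by producing model and
    data split (train / oof / test)."""

    scores: np.ndarray
    producer: str
    split: str = "test"
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and not (
            np.isfinite(self.scores).all()
            and self.scores.min() >= 0.0
            and self.scores.max() <= 1.0
        ):
            raise ConfigError("scores must be finite and in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(np.int64)
            if len(self.labels) != len(self.scores):
                raise ConfigError("labels length does not match scores")

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def _dummy_encode(covariates: pd.DataFrame, schema) -> np.ndarray:
    """Dummy coding against each covariate's reference (first) level."""
    cols = []
    for spec in schema:
        values = covariates[spec.name]
        for level in spec.levels[1:]:
            cols.append((values == level).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(covariates), 0))
    return np.column_stack(cols)


def _ordinal_encode(covariates: pd.DataFrame, schema) -> np.ndarray:
    cols = []
    for spec in schema:
        mapping = {lvl: i for i, lvl in enumerate(spec.levels)}
        cols.append(covariates[spec.name].map(mapping).to_numpy(dtype=np.int64))
    return np.column_stack(cols)


@dataclass
class FittedLearner:
    """A trained base model plus everything needed to score new patients."""

    family: str
    model: Any
    schema: tuple[CovariateSpec, ...]
    encoding: str  # "dummy" | "ordinal" | "none"
    label: str
    seed: int
    params: dict[str, Any]
    # SVM only: training decision-value range for the min-max score map
    decision_range: tuple[float, float] | None = None

    def encode(self, covariates: pd.DataFrame) -> np.ndarray:
        validate_levels(covariates, self.schema)
        if self.encoding == "dummy":
            return _dummy_encode(covariates, self.schema)
        if self.encoding == "ordinal":
            return _ordinal_encode(covariates, self.schema)
        return np.empty((len(covariates), 0))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _require_two_classes(outcome: np.ndarray, context: str) -> None:
    if len(np.unique(outcome)) < 2:
        raise DegenerateTrainingError(f"{context}: outcome has a single class")


def fit_base_learner(spec: LearnerSpec, cohort: Cohort) -> FittedLearner:
    """Fit one base model on a cohort; hyperparameters must be resolved."""
    if not spec.is_resolved:
        raise ConfigError(
            f"{spec.label}: unresolved hyperparameter grid; run "
            f"tune_hyperparameters first"
        )
    if spec.family != "ORACLE":
        _require_two_classes(cohort.outcome, spec.label)
    y = cohort.outcome
    p = dict(spec.params)
    decision_range = None

    if spec.family == "ORACLE":
        config = p.get("config")
        if not isinstance(config, GeneratorConfig):
            raise ConfigError("ORACLE learner requires a 'config' parameter")
        # noise_sd > 0 emulates a misestimated model: every covariate cell's
        # log-odds gets a fixed seed-determined Gaussian perturbation, the
        # way a model fitted on finite data misestimates each risk stratum
        noise_sd = float(p.get("noise_sd", 0.0))
        cell_noise = None
        if noise_sd > 0:
            n_cells = int(np.prod([len(c.levels) for c in config.covariates]))
            cell_noise = np.random.default_rng(spec.seed).normal(
                0.0, noise_sd, n_cells
            )
        model = (config, p.get("distortion"), cell_noise)
        encoding = "none"
    elif spec.family == "NB":
        n_levels = [len(s.levels) for s in cohort.schema]
        model = CategoricalNB(alpha=1.0, min_categories=np.array(n_levels))
        model.fit(_ordinal_encode(cohort.covariates, cohort.schema), y)
        encoding = "ordinal"
    elif spec.family == "LOGIT":
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        model.fit(_dummy_encode(cohort.covariates, cohort.schema), y)
        encoding = "dummy"
    elif spec.family == "RF":
        model = RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 500)),
            max_features=int(p.get("max_features", 2)),
            random_state=spec.seed,
        )
        model.fit(_ordinal_encode(cohort.covariates, cohort.schema), y)
        encoding = "ordinal"
    elif spec.family == "SVM":
        kwargs = {"kernel": p.get("kernel", "rbf"), "C": float(p.get("C", 1.0))}
        if kwargs["kernel"] == "rbf":
            kwargs["gamma"] = float(p.get("gamma", 1.0))
        model = SVC(**kwargs)
        X = _dummy_encode(cohort.covariates, cohort.schema)
        model.fit(X, y)
        d = model.decision_function(X)
        lo, hi = float(d.min()), float(d.max())
        if hi - lo < 1e-12:
            hi = lo + 1e-12  # flat decision surface: score everything 0
        decision_range = (lo, hi)
        encoding = "dummy"
    elif spec.family == "FNN":
        kwargs = dict(FNN_DEFAULTS)
        kwargs.update({k: v for k, v in p.items() if k in kwargs})
        model = MLPClassifier(random_state=spec.seed, **kwargs)
        model.fit(_dummy_encode(cohort.covariates, cohort.schema), y)
        encoding = "dummy"
    else:  # pragma: no cover
        raise ConfigError(f"unknown family {spec.family!r}")

    return FittedLearner(
        family=spec.family,
        model=model,
        schema=cohort.schema,
        encoding=encoding,
        label=spec.label,
        seed=spec.seed,
        params=p,
        decision_range=decision_range,
    )


def _oracle_scores(learner: FittedLearner, covariates: pd.DataFrame) -> np.ndarray:
    config, distortion, cell_noise = learner.model
    validate_levels(covariates, config.covariates)
    eta = np.full(len(covariates), config.intercept)
    cell_index = np.zeros(len(covariates), dtype=np.int64)
    for spec in config.covariates:
        coefs = covariates[spec.name].map(
            {lvl: config.coefficient(spec.name, lvl) for lvl in spec.levels}
        )
        eta += coefs.to_numpy(dtype=float)
        codes = covariates[spec.name].map(
            {lvl: i for i, lvl in enumerate(spec.levels)}
        )
        cell_index = cell_index * len(spec.levels) + codes.to_numpy(np.int64)
    if cell_noise is not None:
        eta = eta + cell_noise[cell_index]
    p = expit(eta)
    if distortion is not None:
        p = distort_probabilities(p, distortion)
    return p


def predict_scores(
    learner: FittedLearner, covariates: pd.DataFrame, split: str = "test",
    labels: np.ndarray | None = None,
) -> ScoreSet:
    """Score new patients; row order is preserved, scores are in [0, 1]."""
    if learner.family == "ORACLE":
        scores = _oracle_scores(learner, covariates)
    else:
        X = learner.encode(covariates)
        if learner.family == "SVM":
            d = learner.model.decision_function(X)
            lo, hi = learner.decision_range
            scores = np.clip((d - lo) / (hi - lo), 0.0, 1.0)
        else:
            proba = learner.model.predict_proba(X)
            pos = list(learner.model.classes_).index(1)
            scores = proba[:, pos]
    scores = np.clip(scores, 0.0, 1.0)
    return ScoreSet(scores=scores, producer=learner.label, split=split, labels=labels)


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def stratified_fold_indices(
    outcome: np.ndarray, n_folds: int, seed: int, max_attempts: int = 10
):
    """Seed-determined stratified folds whose training parts contain both
    classes; refolds with a derived sub-seed on degeneracy, then errors."""
    n = len(outcome)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        folds = [[] for _ in range(n_folds)]
        for cls in np.unique(outcome):
            idx = np.flatnonzero(outcome == cls)
            rng.shuffle(idx)
            for i, chunk in enumerate(np.array_split(idx, n_folds)):
                folds[i].extend(chunk.tolist())
        folds = [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]
        ok = True
        for f in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[f] = False
            if len(np.unique(outcome[train_mask])) < 2 or len(f) == 0:
                ok = False
                break
        if ok:
            return folds
    raise DegenerateTrainingError(
        f"could not build {n_folds} non-degenerate stratified folds in "
        f"{max_attempts} attempts"
    )


def tune_hyperparameters(
    spec: LearnerSpec, cohort: Cohort, n_folds: int = 3, seed: int = 0
) -> LearnerSpec:
    """Resolve a grid by stratified CV, maximizing mean validation AUC.

    Ties are broken by grid order (first wins). Families without a grid go
    through the same CV loop — the protocol treats every family alike — but
    return the spec unchanged.
    """
    if n_folds < 2:
        raise ConfigError("n_folds must be at least 2")
    points = spec.grid_points()
    if not points:
        raise ConfigError("empty hyperparameter grid")
    folds = stratified_fold_indices(cohort.outcome, n_folds, seed)
    n = len(cohort)
    best_auc, best_params = -np.inf, None
    for params in points:
        candidate = spec.resolved(params)
        fold_aucs = []
        for val_idx in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[val_idx] = False
            fitted = fit_base_learner(candidate, cohort.subset(np.flatnonzero(train_mask)))
            val = cohort.subset(val_idx)
            scores = predict_scores(fitted, val.covariates, split="oof")
            fold_aucs.append(auc(scores.scores, val.outcome))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    return spec.resolved(best_params)
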