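"""Repeated stratified hold-out evaluation with nested 3-fold CV.

One repeat of the protocol:

1. stratified split of the cohort into training and test sets (default
   320/86 of 406, matching the study's printed counts — note 0.8 * 406 is
   not an integer, so the split is defined by counts, not a fraction);
2. hyperparameter tuning of the grid-bearing base models (random forest,
   SVM) by stratified 3-fold CV inside the training set; gridless families
   run the same CV loop for protocol parity;
3. fitting every base model on the full training set;
4. out-of-fold (OOF) score collection: each training patient is scored by a
   model fitted on the other folds, yielding an unbiased calibration
   training set;
5. calibrator fitting on the OOF scores (RPR's k and lambda chosen by a
   further 3-fold CV within the OOF set);
6. ensemble construction — reciprocal-error weights and the stacking
   meta-learner are fitted on OOF scores (calibrated OOF scores for the
   calibrated variants), never on resubstitution or test data;
7. scoring of the held-out test set, raw and calibrated, for every single
   model and every ensemble variant;
8. metric computation (AUC, ECE, MCE, Hosmer-Lemeshow).

Per-repeat seeds are derived counter-style from the master seed, so results
do not depend on execution order and repeats are independently
reproducible. Aggregation reports medians and quartiles over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import calibration as cal
from . import ensemble as ens
from .cohort import Cohort
from .errors import CalensError, ConfigError, StratificationError
from .learners import (
    LearnerSpec,
    ScoreSet,
    fit_base_learner,
    predict_scores,
    stratified_fold_indices,
    tune_hyperparameters,
)
from .metrics import MetricRecord, compute_metrics

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "stratified_split",
    "collect_oof_predictions",
    "run_experiment",
    "summarize_results",
]

ENSEMBLE_VARIANTS = ("SA", "ECE", "MCE", "STACK")
_VARIANT_LABEL = {"SA": "SA-EN", "ECE": "ECE-EN", "MCE": "MCE-EN", "STACK": "Stacking-EN"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that defines one experiment besides the cohort itself."""

    learners: tuple[LearnerSpec, ...]
    calibration: dict[str, str | None] = field(default_factory=dict)
    n_repeats: int = 300
    test_size: int = 86
    n_folds: int = 3
    ensembles: tuple[str, ...] = ENSEMBLE_VARIANTS
    calibrated_ensembles: bool = True
    rpr_degrees: tuple[int, ...] = cal.RPR_DEGREE_GRID
    rpr_lambdas: tuple[float, ...] = cal.RPR_LAMBDA_GRID
    n_bins: int = 10
    n_groups: int = 10
    master_seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        labels = [s.label for s in self.learners]
        if len(set(labels)) != len(labels):
            raise ConfigError("learner labels must be unique")
        for name in self.calibration:
            if name not in labels:
                raise ConfigError(f"calibration assigned to unknown learner {name!r}")
        for v in self.ensembles:
            if v not in ENSEMBLE_VARIANTS:
                raise ConfigError(f"unknown ensemble variant {v!r}")

    @classmethod
    def default_five_model(cls, master_seed: int = 0, **overrides) -> "ExperimentConfig":
        """The study's five-model setup: NB/LOGIT/RF/SVM/FNN with RPR
        calibration of NB, RF and SVM (logistic and FNN scores are already
        well calibrated and are left untouched)."""
        learners = tuple(
            LearnerSpec.with_default_grid(f) for f in ("NB", "LOGIT", "RF", "SVM", "FNN")
        )
        return cls(
            learners=learners,
            calibration={"NB": "rpr", "RF": "rpr", "SVM": "rpr"},
            master_seed=master_seed,
            **overrides,
        )


@dataclass
class ExperimentResult:
    """Per-repeat, per-model-variant metrics plus chosen hyperparameters."""

    records: pd.DataFrame  # model, repeat, auc, ece, mce, hl_stat, hl_p
    hyperparameters: list[dict[str, Any]]
    config: ExperimentConfig

    def summarize(self) -> pd.DataFrame:
        return summarize_results(self)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def _per_class_test_counts(outcome: np.ndarray, test_size: int) -> dict:
    classes, counts = np.unique(outcome, return_counts=True)
    n = len(outcome)
    exact = counts * test_size / n
    base = np.floor(exact).astype(int)
    remainder = test_size - base.sum()
    # largest fractional remainders get the leftover slots
    frac_order = np.argsort(-(exact - base), kind="stable")
    for i in range(remainder):
        base[frac_order[i]] += 1
    return dict(zip(classes.tolist(), base.tolist()))


def stratified_split(
    cohort: Cohort, test_size: int, seed: int
) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive train/test split with per-class test counts set
    by largest-remainder rounding of test_size * class_count / n."""
    n = len(cohort)
    if not (0 < test_size < n):
        raise ConfigError(f"test_size must be in (0, {n}), got {test_size}")
    classes, class_counts = np.unique(cohort.outcome, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("cohort has a single outcome class")
    take = _per_class_test_counts(cohort.outcome, test_size)
    for cls, total in zip(classes, class_counts):
        k = take[int(cls)]
        if k == 0 or k == total:
            raise StratificationError(
                f"class {cls} would get {k} of its {total} samples in the test set"
            )
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in classes:
        idx = np.flatnonzero(cohort.outcome == cls)
        rng.shuffle(idx)
        test_idx.extend(idx[: take[int(cls)]].tolist())
    test_idx = np.sort(np.asarray(test_idx, dtype=np.int64))
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    return cohort.subset(np.flatnonzero(mask)), cohort.subset(test_idx)


# ---------------------------------------------------------------------------
# Out-of-fold score collection
# ---------------------------------------------------------------------------


def collect_oof_predictions(
    spec: LearnerSpec, train: Cohort, n_folds: int = 3, seed: int = 0
) -> ScoreSet:
    """Score every training sample with a model fitted on the other folds.

    Hyperparameters must already be resolved; folds are stratified and
    seed-determined. The result is the calibration / stacking training set.
    """
    folds = stratified_fold_indices(train.outcome, n_folds, seed)
    scores = np.empty(len(train))
    scores.fill(np.nan)
    for val_idx in folds:
        mask = np.ones(len(train), dtype=bool)
        mask[val_idx] = False
        fitted = fit_base_learner(spec, train.subset(np.flatnonzero(mask)))
        val = train.subset(val_idx)
        scores[val_idx] = predict_scores(fitted, val.covariates).scores
    assert not np.isnan(scores).any()
    return ScoreSet(
        scores=scores, producer=spec.label, split="oof", labels=train.outcome
    )


# ---------------------------------------------------------------------------
# The experiment
# ---------------------------------------------------------------------------


def _derive_seed(master_seed: int, *key) -> int:
    """Counter-based child seed; schedule-independent."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_repeat(
    cohort: Cohort, config: ExperimentConfig, repeat: int
) -> tuple[list[dict], dict[str, Any]]:
    seed = lambda *key: _derive_seed(config.master_seed, repeat, *key)
    train, test = stratified_split(cohort, config.test_size, seed(0))

    # 1) tune + fit base models, collect OOF and test scores
    oof_sets: dict[str, ScoreSet] = {}
    test_sets: dict[str, ScoreSet] = {}
    chosen: dict[str, Any] = {}
    for i, spec in enumerate(config.learners):
        spec = replace(spec, seed=seed(1, i))
        resolved = tune_hyperparameters(
            spec, train, n_folds=config.n_folds, seed=seed(2, i)
        )
        chosen[spec.label] = {
            k: v for k, v in resolved.params.items()
            if not hasattr(v, "covariates")  # omit embedded generator configs
        }
        fitted = fit_base_learner(resolved, train)
        oof_sets[spec.label] = collect_oof_predictions(
            resolved, train, n_folds=config.n_folds, seed=seed(3, i)
        )
        test_sets[spec.label] = predict_scores(
            fitted, test.covariates, split="test", labels=test.outcome
        )

    # 2) calibrators on OOF scores
    calibrators: dict[str, Any] = {}
    for i, spec in enumerate(config.learners):
        method = config.calibration.get(spec.label)
        if method is None:
            continue
        data = cal.CalibrationTrainingSet(
            oof_sets[spec.label].scores, oof_sets[spec.label].labels
        )
        calibrators[spec.label] = cal.fit_calibrator(
            method,
            data,
            rpr_degrees=config.rpr_degrees,
            rpr_lambdas=config.rpr_lambdas,
            n_folds=config.n_folds,
            seed=seed(4, i),
        )

    def calibrated(sets: dict[str, ScoreSet]) -> dict[str, ScoreSet]:
        out = {}
        for label, ss in sets.items():
            if label in calibrators:
                method = config.calibration[label].upper()
                out[f"{label}-{method}"] = ScoreSet(
                    scores=cal.apply_calibrator(calibrators[label], ss.scores),
                    producer=f"{label}-{method}",
                    split=ss.split,
                    labels=ss.labels,
                )
            else:
                out[label] = ss
        return out

    oof_cal = calibrated(oof_sets)
    test_cal = calibrated(test_sets)

    # 3) ensembles: raw and calibrated variants share the combiner code
    variant_scores: dict[str, ScoreSet] = {}
    variant_scores.update(test_sets)
    for label, ss in test_cal.items():
        variant_scores.setdefault(label, ss)

    def build_ensembles(oof: dict, tst: dict, suffix: str) -> None:
        oof_list = list(oof.values())
        tst_list = list(tst.values())
        tst_matrix = np.column_stack([s.scores for s in tst_list])
        labels = tst_list[0].labels
        for variant in config.ensembles:
            name = _VARIANT_LABEL[variant] + suffix
            if variant == "SA":
                variant_scores[name] = ens.combine_average(
                    tst_list, producer=name
                )
            elif variant in ("ECE", "MCE"):
                w = ens.compute_error_weights(
                    oof_list, metric=variant, n_bins=config.n_bins
                )
                variant_scores[name] = ens.combine_average(
                    tst_list, w, producer=name
                )
            else:  # STACK
                oof_matrix = np.column_stack([s.scores for s in oof_list])
                model = ens.fit_stacking(oof_matrix, oof_list[0].labels)
                variant_scores[name] = ens.predict_stacking(
                    model, tst_matrix, producer=name, labels=labels
                )

    if len(config.learners) >= 2 and config.ensembles:
        build_ensembles(oof_sets, test_sets, "")
        if config.calibrated_ensembles and calibrators:
            build_ensembles(oof_cal, test_cal, "-C")

    # 4) metrics on the held-out test set
    records = []
    for name, ss in variant_scores.items():
        m = compute_metrics(
            ss.scores, test.outcome, n_bins=config.n_bins, n_groups=config.n_groups
        )
        records.append(
            {
                "model": name,
                "repeat": repeat,
                "auc": m.auc,
                "ece": m.ece,
                "mce": m.mce,
                "hl_stat": m.hl_statistic,
                "hl_p": m.hl_p,
            }
        )
    return records, chosen


def run_experiment(cohort: Cohort, config: ExperimentConfig) -> ExperimentResult:
    """Run the full repeated hold-out protocol.

    A failing repeat aborts the run with a diagnostic naming the repeat; no
    repeat is silently skipped.
    """
    all_records: list[dict] = []
    all_params: list[dict] = []
    for repeat in range(config.n_repeats):
        try:
            records, chosen = _run_repeat(cohort, config, repeat)
        except CalensError as exc:
            raise type(exc)(f"repeat {repeat} failed: {exc}") from exc
        all_records.extend(records)
        all_params.append(chosen)
    return ExperimentResult(
        records=pd.DataFrame(all_records),
        hyperparameters=all_params,
        config=config,
    )


def summarize_results(result: ExperimentResult) -> pd.DataFrame:
    """Median and quartiles per metric and variant, plus the count of
    repeats with Hosmer-Lemeshow p > 0.05, with per-metric ranks (1 = best:
    highest median AUC, lowest median ECE/MCE)."""
    if result.records.empty:
        raise ConfigError("no records to summarize")
    rows = []
    for model, grp in result.records.groupby("model", sort=False):
        row = {"model": model, "n_repeats": len(grp)}
        for metric in ("auc", "ece", "mce", "hl_p"):
            q25, med, q75 = grp[metric].quantile([0.25, 0.5, 0.75])
            row[f"{metric}_median"] = med
            row[f"{metric}_p25"] = q25
            row[f"{metric}_p75"] = q75
        row["good_calibration_count"] = int((grp["hl_p"] > 0.05).sum())
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary["auc_rank"] = summary["auc_median"].rank(ascending=False, method="min").astype(int)
    for metric in ("ece", "mce"):
        summary[f"{metric}_rank"] = (
            summary[f"{metric}_median"].rank(ascending=True, method="min").astype(int)
        )
    return summary
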