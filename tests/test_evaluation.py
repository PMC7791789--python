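"""Repeated hold-out protocol: splitting, OOF collection, the experiment."""

import numpy as np
import pandas as pd
import pytest

import calens.calibration
import calens.ensemble
from calens.cohort import DistortionSpec, default_config, generate_cohort
from calens.errors import ConfigError, StratificationError
from calens.evaluation import (
    ExperimentConfig,
    collect_oof_predictions,
    run_experiment,
    stratified_split,
    summarize_results,
)
from calens.learners import LearnerSpec


def _oracle_spec(config, distortion=None, name=None):
    params = {"config": config}
    if distortion is not None:
        params["distortion"] = distortion
    return LearnerSpec("ORACLE", params, name=name)


@pytest.fixture(scope="module")
def study_cohort():
    return generate_cohort(default_config(), 406, seed=17)


class TestStratifiedSplit:
    def test_study_counts(self, study_cohort):
        train, test = stratified_split(study_cohort, 86, seed=0)
        assert len(train) == 320 and len(test) == 86

    def test_largest_remainder_class_allocation(self, study_config):
        # force exactly 116 events to check the published 25/91 allocation
        cohort = generate_cohort(study_config, 406, seed=17)
        outcome = np.zeros(406, dtype=int)
        outcome[:116] = 1
        cohort = type(cohort)(
            cohort.covariates, outcome, cohort.schema, cohort.true_probability
        )
        train, test = stratified_split(cohort, 86, seed=1)
        assert test.n_events == round(86 * 116 / 406) == 25
        assert train.n_events == 91

    def test_disjoint_and_exhaustive(self, study_cohort):
        train, test = stratified_split(study_cohort, 86, seed=4)
        combined = pd.concat(
            [train.to_frame(), test.to_frame()], ignore_index=True
        ).sort_values(list(train.to_frame().columns)).reset_index(drop=True)
        original = (
            study_cohort.to_frame()
            .sort_values(list(train.to_frame().columns))
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(combined, original)

    def test_same_seed_identical(self, study_cohort):
        a = stratified_split(study_cohort, 86, seed=9)[1]
        b = stratified_split(study_cohort, 86, seed=9)[1]
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_empty_class_rejected(self, study_config):
        cohort = generate_cohort(study_config, 50, seed=3)
        outcome = np.zeros(50, dtype=int)
        outcome[0] = 1  # a single event cannot be split
        cohort = type(cohort)(cohort.covariates, outcome, cohort.schema)
        with pytest.raises(StratificationError):
            stratified_split(cohort, 10, seed=0)

    def test_bad_test_size_rejected(self, study_cohort):
        with pytest.raises(ConfigError):
            stratified_split(study_cohort, 406, seed=0)


class TestCollectOof:
    def test_every_index_scored_once_with_balanced_folds(self, study_config, cohort_small):
        spec = _oracle_spec(study_config)
        oof = collect_oof_predictions(spec, cohort_small, n_folds=3, seed=2)
        assert len(oof) == len(cohort_small)
        assert oof.split == "oof"
        assert np.isfinite(oof.scores).all()

    def test_oracle_oof_equals_true_probability(self, study_config, cohort_small):
        oof = collect_oof_predictions(
            _oracle_spec(study_config), cohort_small, n_folds=3, seed=2
        )
        assert np.allclose(oof.scores, cohort_small.true_probability, atol=1e-12)


def _oracle_experiment_config(config, n_repeats=2, **kw):
    kw.setdefault("rpr_degrees", (5,))
    kw.setdefault("rpr_lambdas", (4.0,))
    return ExperimentConfig(
        learners=(
            _oracle_spec(config, DistortionSpec(2.0), name="NB-like"),
            _oracle_spec(config, DistortionSpec(0.5), name="RF-like"),
            _oracle_spec(config, DistortionSpec(0.7, 0.3), name="SVM-like"),
        ),
        calibration={"NB-like": "rpr", "RF-like": "rpr", "SVM-like": "rpr"},
        n_repeats=n_repeats,
        test_size=86,
        master_seed=33,
        **kw,
    )


class TestRunExperiment:
    def test_bit_identical_reruns(self, study_cohort, study_config):
        cfg = _oracle_experiment_config(study_config, n_repeats=1)
        r1 = run_experiment(study_cohort, cfg)
        r2 = run_experiment(study_cohort, cfg)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        assert r1.hyperparameters == r2.hyperparameters

    def test_distortion_worsens_oracle_ece(self, study_config):
        # the undistorted oracle must beat its own distorted scores
        cohort = generate_cohort(study_config, 2000, seed=29)
        cfg = ExperimentConfig(
            learners=(
                _oracle_spec(study_config, name="oracle"),
                _oracle_spec(study_config, DistortionSpec(2.0), name="distorted"),
            ),
            calibration={},
            ensembles=(),
            n_repeats=20,
            test_size=400,
            master_seed=5,
        )
        res = run_experiment(cohort, cfg)
        med = res.records.groupby("model")["ece"].median()
        assert med["oracle"] < med["distorted"]

    def test_all_variants_present(self, study_cohort, study_config):
        cfg = _oracle_experiment_config(study_config, n_repeats=1)
        res = run_experiment(study_cohort, cfg)
        models = set(res.records["model"])
        expected = {
            "NB-like", "RF-like", "SVM-like",
            "NB-like-RPR", "RF-like-RPR", "SVM-like-RPR",
            "SA-EN", "ECE-EN", "MCE-EN", "Stacking-EN",
            "SA-EN-C", "ECE-EN-C", "MCE-EN-C", "Stacking-EN-C",
        }
        assert models == expected

    def test_no_test_data_reaches_fitting(
        self, study_cohort, study_config, monkeypatch
    ):
        # instrumentation: calibrators and the meta-learner may only ever
        # see training-set-sized inputs (320), never the full cohort (406)
        sizes = {"calibration": [], "stacking": []}
        orig_fit_cal = calens.calibration.fit_calibrator
        orig_fit_stack = calens.ensemble.fit_stacking

        def spy_cal(method, data, **kw):
            sizes["calibration"].append(len(data))
            return orig_fit_cal(method, data, **kw)

        def spy_stack(X, y, **kw):
            sizes["stacking"].append(np.asarray(X).shape[0])
            return orig_fit_stack(X, y, **kw)

        monkeypatch.setattr("calens.evaluation.cal.fit_calibrator", spy_cal)
        monkeypatch.setattr("calens.evaluation.ens.fit_stacking", spy_stack)
        cfg = _oracle_experiment_config(study_config, n_repeats=1)
        run_experiment(study_cohort, cfg)
        assert sizes["calibration"] and sizes["stacking"]
        assert all(s == 320 for s in sizes["calibration"])
        assert all(s == 320 for s in sizes["stacking"])


class TestSummarize:
    def test_single_repeat_quartiles_collapse(self, study_cohort, study_config):
        cfg = _oracle_experiment_config(study_config, n_repeats=1)
        summary = run_experiment(study_cohort, cfg).summarize()
        for metric in ("auc", "ece", "mce"):
            assert (summary[f"{metric}_median"] == summary[f"{metric}_p25"]).all()
            assert (summary[f"{metric}_median"] == summary[f"{metric}_p75"]).all()

    def test_good_calibration_count(self):
        from calens.evaluation import ExperimentResult

        records = pd.DataFrame(
            {
                "model": ["m"] * 3,
                "repeat": [0, 1, 2],
                "auc": [0.7, 0.8, 0.9],
                "ece": [10, 11, 12],
                "mce": [20, 21, 22],
                "hl_stat": [1, 2, 3],
                "hl_p": [0.01, 0.2, 0.6],
            }
        )
        cfg = ExperimentConfig(
            learners=(LearnerSpec("LOGIT"),), n_repeats=3
        )
        summary = summarize_results(
            ExperimentResult(records, [], cfg)
        )
        assert summary["good_calibration_count"].iloc[0] == 2

    def test_quartile_ordering_invariant(self, study_config, rng):
        from calens.evaluation import ExperimentResult

        n = 50
        records = pd.DataFrame(
            {
                "model": ["m"] * n,
                "repeat": range(n),
                "auc": rng.uniform(0.5, 1.0, n),
                "ece": rng.uniform(0, 30, n),
                "mce": rng.uniform(0, 60, n),
                "hl_stat": rng.uniform(0, 20, n),
                "hl_p": rng.uniform(0, 1, n),
            }
        )
        cfg = ExperimentConfig(learners=(LearnerSpec("LOGIT"),), n_repeats=n)
        summary = summarize_results(ExperimentResult(records, [], cfg))
        for metric in ("auc", "ece", "mce", "hl_p"):
            assert (
                summary[f"{metric}_p25"]
                <= summary[f"{metric}_median"]
            ).all()
            assert (
                summary[f"{metric}_median"]
                <= summary[f"{metric}_p75"]
            ).all()
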