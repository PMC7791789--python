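"""Cohort CSV readers/writers, result serialization, and run manifests.

Cohorts are stored as plain CSV with one string-labelled column per
covariate, a binary ``death2y`` outcome column, and an optional
``true_prob`` column carrying the generating probability of synthetic
patients. Results directories contain the per-repeat metric records
(``records.csv``), an aggregated ``summary.json``, and a ``manifest.json``
recording the configuration hash, package version, and master seed so that
a run can be reproduced exactly. All writes are atomic (temp file +
rename).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    OUTCOME_COLUMN,
    TRUE_PROB_COLUMN,
    Cohort,
    CovariateSpec,
    GeneratorConfig,
)
from .errors import DataError
from .evaluation import ExperimentResult, summarize_results

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_results",
    "RunManifest",
    "config_hash",
]


def write_cohort(cohort: Cohort, path) -> None:
    _atomic_write_text(path, cohort.to_frame().to_csv(index=False))


def read_cohort(path, schema: tuple[CovariateSpec, ...] | None = None,
                config: GeneratorConfig | None = None) -> Cohort:
    """Read a cohort CSV.

    The covariate schema is taken from ``schema``/``config`` when given;
    otherwise every non-outcome column is treated as a covariate and its
    level set inferred from the observed values (sorted for determinism).
    Outcome values other than 0/1 and undeclared levels are parse errors
    naming the offending row and column.
    """
    path = Path(path)
    if schema is None and config is not None:
        schema = config.covariates
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty cohort file") from exc
    if df.empty and len(df.columns) == 0:
        raise DataError(f"{path}: empty cohort file")
    if OUTCOME_COLUMN not in df.columns:
        raise DataError(f"{path}: missing outcome column {OUTCOME_COLUMN!r}")

    outcome_raw = df[OUTCOME_COLUMN]
    bad = ~outcome_raw.isin(["0", "1"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(
            f"{path}: row {row}: outcome {outcome_raw.iloc[row]!r} is not 0/1"
        )
    outcome = outcome_raw.astype(np.int64).to_numpy()

    true_prob = None
    if TRUE_PROB_COLUMN in df.columns:
        true_prob = pd.to_numeric(df[TRUE_PROB_COLUMN], errors="coerce").to_numpy()
        if np.isnan(true_prob).any():
            row = int(np.flatnonzero(np.isnan(true_prob))[0])
            raise DataError(f"{path}: row {row}: non-numeric {TRUE_PROB_COLUMN}")

    cov_cols = [c for c in df.columns if c not in (OUTCOME_COLUMN, TRUE_PROB_COLUMN)]
    covariates = df[cov_cols].copy()
    if schema is None:
        schema = tuple(
            CovariateSpec(
                name,
                tuple(sorted(covariates[name].dropna().unique())),
                _uniform(len(covariates[name].dropna().unique())),
            )
            for name in cov_cols
        )
    try:
        return Cohort(
            covariates=covariates,
            outcome=outcome,
            schema=schema,
            true_probability=true_prob,
        )
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def _uniform(k: int) -> tuple[float, ...]:
    return tuple([1.0 / k] * k)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of a results directory: enough to reproduce the run."""

    config_hash: str
    package_version: str
    master_seed: int
    created: str
    arguments: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_results(result: ExperimentResult, directory, arguments: dict | None = None) -> dict:
    """Write records.csv, summary.json and manifest.json into ``directory``.

    Returns the paths written. Rewrites are atomic, so a results directory
    is never observed half-updated.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": directory / "records.csv",
        "summary": directory / "summary.json",
        "manifest": directory / "manifest.json",
    }
    _atomic_write_text(paths["records"], result.records.to_csv(index=False))
    summary = summarize_results(result)
    _atomic_write_text(
        paths["summary"],
        json.dumps(
            {
                "models": summary.to_dict(orient="records"),
                "n_repeats": int(result.config.n_repeats),
            },
            indent=2,
        ),
    )
    manifest = RunManifest(
        config_hash=config_hash(result.config),
        package_version=__version__,
        master_seed=int(result.config.master_seed),
        created=datetime.now(timezone.utc).isoformat(),
        arguments=_jsonable(arguments or {}),
    )
    _atomic_write_text(paths["manifest"], json.dumps(manifest.to_dict(), indent=2))
    return paths
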