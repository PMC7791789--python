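"""Synthetic DLBCL-like cohort generation.

The real study cohort (406 lymphoma patients, 116 deaths within two years of
treatment) is not publicly available, so this module generates cohorts with
the same published statistical structure: categorical covariates drawn
independently with the published marginal frequencies, and a binary two-year
death outcome drawn from a logistic model with the published coefficients.
The intercept is calibrated by exact enumeration over the (finite) covariate
support so that the marginal event rate matches the study's 116/406.

Because the generating probability of every synthetic patient is known, the
module can also produce deliberately miscalibrated probability scores — an
affine distortion on the log-odds scale — which emulate the classifier
pathologies that post-hoc calibration is meant to repair: scores pushed
toward 0/1 (naive-Bayes-like, slope > 1), pushed away from 0/1 (random-
forest-like, slope < 1), and sigmoid-shaped shifts (SVM-like, slope != 1
with a nonzero offset).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigError, SchemaError

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "Cohort",
    "DistortionSpec",
    "default_config",
    "calibrate_intercept",
    "generate_cohort",
    "distort_probabilities",
]

OUTCOME_COLUMN = "death2y"
TRUE_PROB_COLUMN = "true_prob"

#: Marginal event rate of the study cohort: 116 deaths among 406 patients.
DEFAULT_EVENT_RATE = 116 / 406


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate: its name, declared levels, and marginal
    level probabilities. The first level is the reference level."""

    name: str
    levels: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) != len(self.probabilities):
            raise ConfigError(
                f"covariate {self.name!r}: {len(self.levels)} levels but "
                f"{len(self.probabilities)} probabilities"
            )
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ConfigError(
                f"covariate {self.name!r}: probabilities must be nonnegative "
                f"and sum to 1 (got sum {p.sum()!r})"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``coefficients`` maps ``(covariate, level)`` to a log-odds contribution;
    the reference (first) level of every covariate implicitly contributes 0.
    """

    covariates: tuple[CovariateSpec, ...]
    coefficients: dict[tuple[str, str], float]
    intercept: float
    n_default: int = 406
    seed: int = 0

    def __post_init__(self):
        by_name = {c.name: c for c in self.covariates}
        for (name, level), value in self.coefficients.items():
            if name not in by_name:
                raise ConfigError(f"coefficient for unknown covariate {name!r}")
            spec = by_name[name]
            if level not in spec.levels:
                raise ConfigError(
                    f"coefficient for unknown level {level!r} of {name!r}"
                )
            if level == spec.levels[0] and value != 0.0:
                raise ConfigError(
                    f"reference level {level!r} of {name!r} must carry "
                    f"coefficient 0"
                )
            if not np.isfinite(value):
                raise ConfigError(f"non-finite coefficient for {name}={level}")
        if not np.isfinite(self.intercept):
            raise ConfigError("non-finite intercept")

    def coefficient(self, name: str, level: str) -> float:
        return self.coefficients.get((name, level), 0.0)

    def with_intercept(self, intercept: float) -> "GeneratorConfig":
        return replace(self, intercept=intercept)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {
                    "name": c.name,
                    "levels": list(c.levels),
                    "probabilities": [float(p) for p in c.probabilities],
                }
                for c in self.covariates
            ],
            "coefficients": [
                {"covariate": n, "level": l, "value": float(v)}
                for (n, l), v in sorted(self.coefficients.items())
            ],
            "intercept": float(self.intercept),
            "n_default": int(self.n_default),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        try:
            covs = tuple(
                CovariateSpec(
                    c["name"], tuple(c["levels"]), tuple(c["probabilities"])
                )
                for c in d["covariates"]
            )
            coefs = {
                (e["covariate"], e["level"]): float(e["value"])
                for e in d["coefficients"]
            }
            return cls(
                covariates=covs,
                coefficients=coefs,
                intercept=float(d["intercept"]),
                n_default=int(d.get("n_default", 406)),
                seed=int(d.get("seed", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed generator config: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class Cohort:
    """A patient cohort: categorical covariates, binary outcome, and (for
    synthetic cohorts) the generating event probability of each patient."""

    covariates: pd.DataFrame
    outcome: np.ndarray
    schema: tuple[CovariateSpec, ...]
    true_probability: np.ndarray | None = None

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome)
        if not np.isin(self.outcome, (0, 1)).all():
            raise ConfigError("outcome values must be 0 or 1")
        self.outcome = self.outcome.astype(np.int64)
        if len(self.outcome) != len(self.covariates):
            raise ConfigError("outcome length does not match covariate rows")
        if self.true_probability is not None:
            self.true_probability = np.asarray(self.true_probability, float)
            if len(self.true_probability) != len(self.covariates):
                raise ConfigError("true_probability length mismatch")
            if len(self.true_probability) and (
                self.true_probability.min() < 0 or self.true_probability.max() > 1
            ):
                raise ConfigError("true_probability outside [0, 1]")
        validate_levels(self.covariates, self.schema)

    def __len__(self) -> int:
        return len(self.covariates)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    def subset(self, indices) -> "Cohort":
        idx = np.asarray(indices)
        return Cohort(
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            outcome=self.outcome[idx],
            schema=self.schema,
            true_probability=(
                None
                if self.true_probability is None
                else self.true_probability[idx]
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df[OUTCOME_COLUMN] = self.outcome
        if self.true_probability is not None:
            df[TRUE_PROB_COLUMN] = self.true_probability
        return df


def validate_levels(covariates: pd.DataFrame, schema) -> None:
    """Raise :class:`SchemaError` if any value is not a declared level."""
    for spec in schema:
        if spec.name not in covariates.columns:
            raise SchemaError(f"missing covariate column {spec.name!r}")
        bad = ~covariates[spec.name].isin(spec.levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {spec.name!r}, row {row}: value "
                f"{covariates[spec.name].iloc[row]!r} is not a declared level"
            )


@dataclass(frozen=True)
class DistortionSpec:
    """Affine distortion on the log-odds scale: s -> sigmoid(a*logit(p) + b).

    ``a`` must be positive, so the distortion is strictly increasing and a
    perfect calibrator can invert it (the inverse is the spec (1/a, -b/a)).
    """

    a: float
    b: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.a) and self.a > 0):
            raise ConfigError("distortion slope a must be positive and finite")
        if not np.isfinite(self.b):
            raise ConfigError("distortion offset b must be finite")

    def inverse(self) -> "DistortionSpec":
        return DistortionSpec(1.0 / self.a, -self.b / self.a)


def distort_probabilities(p, spec: DistortionSpec) -> np.ndarray:
    """Apply a monotone log-odds distortion to probabilities in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() <= 0.0 or p.max() >= 1.0):
        raise ConfigError("probabilities must lie strictly inside (0, 1)")
    return expit(spec.a * logit(p) + spec.b)


# ---------------------------------------------------------------------------
# Default configuration: the published cohort structure.
# ---------------------------------------------------------------------------

_N_STUDY = 406

# Marginal level counts of the 406-patient cohort, reference level first.
_DEFAULT_COUNTS: list[tuple[str, list[tuple[str, int]]]] = [
    ("Age", [("<=60", 219), (">60", 187)]),
    ("Gender", [("Male", 209), ("Female", 197)]),
    ("Stage", [("I-II", 176), ("III-IV", 230)]),
    (
        "IPI",
        [
            ("Low", 195),
            ("Low-intermediate", 79),
            ("High-intermediate", 83),
            ("High", 49),
        ],
    ),
    ("KPS", [(">=80", 335), ("<80", 71)]),
    ("LDH", [("Normal", 312), ("High", 94)]),
    ("B2MG", [("Normal", 296), ("High", 110)]),
    ("Rituximab", [("Not use", 241), ("Use", 165)]),
]

# Logistic-model log-odds contributions of the non-reference levels.
_DEFAULT_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("Age", ">60"): 0.488,
    ("Gender", "Female"): -0.509,
    ("Stage", "III-IV"): 0.961,
    ("IPI", "Low-intermediate"): 0.946,
    ("IPI", "High-intermediate"): 0.909,
    ("IPI", "High"): 0.807,
    ("KPS", "<80"): 1.350,
    ("LDH", "High"): 0.597,
    ("B2MG", "High"): 0.562,
    ("Rituximab", "Use"): -0.931,
}


def default_config(
    seed: int = 0, calibrate: bool = True, target_rate: float = DEFAULT_EVENT_RATE
) -> GeneratorConfig:
    """The published cohort structure as a generator configuration.

    Level probabilities are the published counts divided by 406; outcome
    coefficients are the published logistic-model estimates. When
    ``calibrate`` is true (default) the intercept is set by exact enumeration
    so the marginal event rate equals ``target_rate`` (default 116/406).
    """
    covs = tuple(
        CovariateSpec(
            name,
            tuple(level for level, _ in counts),
            tuple(c / _N_STUDY for _, c in counts),
        )
        for name, counts in _DEFAULT_COUNTS
    )
    config = GeneratorConfig(
        covariates=covs,
        coefficients=dict(_DEFAULT_COEFFICIENTS),
        intercept=0.0,
        n_default=_N_STUDY,
        seed=seed,
    )
    if calibrate:
        config = config.with_intercept(calibrate_intercept(config, target_rate))
    return config


# ---------------------------------------------------------------------------
# Intercept calibration by exact enumeration.
# ---------------------------------------------------------------------------


def _cell_enumeration(config: GeneratorConfig):
    """Weights and linear predictors (without intercept) of every covariate
    cell. The support is finite (512 cells for the default config), so the
    marginal event rate can be computed exactly."""
    per_cov = []
    for spec in config.covariates:
        per_cov.append(
            [
                (p, config.coefficient(spec.name, level))
                for level, p in zip(spec.levels, spec.probabilities)
            ]
        )
    weights = []
    etas = []
    for combo in itertools.product(*per_cov):
        w = 1.0
        eta = 0.0
        for p, c in combo:
            w *= p
            eta += c
        weights.append(w)
        etas.append(eta)
    return np.asarray(weights), np.asarray(etas)


def exact_event_rate(config: GeneratorConfig, intercept: float | None = None) -> float:
    """Exact marginal event probability under the generator, by enumeration."""
    c = config.intercept if intercept is None else intercept
    weights, etas = _cell_enumeration(config)
    return float(weights @ expit(c + etas))


def calibrate_intercept(config: GeneratorConfig, target_rate: float) -> float:
    """Intercept c such that the exact marginal event rate equals target_rate.

    Root-found by bisection (brentq) on the exact enumeration; the marginal
    rate is strictly increasing in c, so the root is unique.
    """
    if not (0.0 < target_rate < 1.0):
        raise ConfigError("target_rate must lie strictly inside (0, 1)")
    weights, etas = _cell_enumeration(config)

    def gap(c):
        return float(weights @ expit(c + etas)) - target_rate

    lo, hi = -40.0, 40.0
    # expit saturates well before +/-40 for any realistic coefficient set
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - defensive
        raise ConfigError("target_rate unreachable for this coefficient set")
    return float(brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# Cohort generation.
# ---------------------------------------------------------------------------


def generate_cohort(
    config: GeneratorConfig, n: int | None = None, seed: int | None = None
) -> Cohort:
    """Draw a synthetic cohort of ``n`` patients.

    Covariates are sampled independently with the configured marginal
    probabilities; the outcome is Bernoulli with probability
    sigmoid(intercept + sum of level coefficients). Identical
    (config, n, seed) always reproduces the cohort bit for bit.
    """
    if n is None:
        n = config.n_default
    if n < 0:
        raise ConfigError(f"cohort size must be nonnegative, got {n}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    columns = {}
    eta = np.full(n, config.intercept, dtype=float)
    for spec in config.covariates:
        idx = rng.choice(len(spec.levels), size=n, p=spec.probabilities)
        columns[spec.name] = pd.Categorical.from_codes(
            idx, categories=list(spec.levels)
        ).astype(str)
        coefs = np.array(
            [config.coefficient(spec.name, lvl) for lvl in spec.levels]
        )
        eta += coefs[idx]
    true_probability = expit(eta)
    outcome = (rng.random(n) < true_probability).astype(np.int64)
    covariates = pd.DataFrame(columns, columns=[c.name for c in config.covariates])
    if n == 0:
        covariates = pd.DataFrame(
            {c.name: pd.Series([], dtype=str) for c in config.covariates}
        )
    return Cohort(
        covariates=covariates,
        outcome=outcome,
        schema=config.covariates,
        true_probability=true_probability,
    )
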