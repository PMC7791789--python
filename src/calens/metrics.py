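"""Discrimination and calibration measures.

Discrimination is summarized by the AUC in its rank-sum form (probability
that a random event patient outscores a random non-event patient, ties
counted half). Calibration is summarized against equal-frequency bins of
the sorted predictions: the expected calibration error (ECE) is the mean
absolute gap between a bin's mean prediction and its observed event
fraction, the maximum calibration error (MCE) is the largest such gap, and
both are reported on the 0-100 scale. The Hosmer-Lemeshow chi-square test
asks whether the per-group gaps between observed and expected event counts
are attributable to chance (p > 0.05 conventionally read as adequate
calibration).

Bins and groups default to 10. Equal-frequency (not equal-width) binning is
used throughout; when n is not a multiple of the bin count the remainder
samples go to the earliest bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .errors import ConfigError, UndefinedMetricError

__all__ = [
    "BinTable",
    "MetricRecord",
    "auc",
    "calibration_errors",
    "reliability_table",
    "hosmer_lemeshow",
    "compute_metrics",
]


@dataclass
class BinTable:
    """Per-bin mean prediction, observed event fraction, and count."""

    predicted: np.ndarray
    observed: np.ndarray
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class MetricRecord:
    """One model variant's metrics on one evaluation set."""

    auc: float
    ece: float
    mce: float
    hl_statistic: float
    hl_p: float


def _as_arrays(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ConfigError("scores and labels must be 1-d and the same length")
    if not np.isin(y, (0, 1)).all():
        raise ConfigError("labels must be binary 0/1")
    return s, y.astype(np.int64)


def auc(scores, labels) -> float:
    """Rank-sum AUC: P(score of random positive > score of random negative),
    with ties counted 0.5."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single outcome class")
    ranks = rankdata(s)  # midranks handle ties
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _equal_frequency_bins(n: int, n_bins: int) -> list[np.ndarray]:
    # np.array_split puts the remainder in the earliest chunks
    return np.array_split(np.arange(n), n_bins)


def reliability_table(scores, labels, n_bins: int = 10) -> BinTable:
    """Equal-frequency reliability table of sorted predictions."""
    s, y = _as_arrays(scores, labels)
    if n_bins < 1:
        raise ConfigError("n_bins must be positive")
    if len(s) < n_bins:
        raise ConfigError(f"need at least n_bins={n_bins} samples, got {len(s)}")
    order = np.argsort(s, kind="stable")  # ties keep original order
    s_sorted, y_sorted = s[order], y[order]
    pred, obs, counts = [], [], []
    for idx in _equal_frequency_bins(len(s), n_bins):
        pred.append(s_sorted[idx].mean())
        obs.append(y_sorted[idx].mean())
        counts.append(len(idx))
    return BinTable(np.asarray(pred), np.asarray(obs), np.asarray(counts))


def calibration_errors(
    scores, labels, n_bins: int = 10
) -> tuple[float, float, BinTable]:
    """(ECE, MCE) on the 0-100 scale, plus the underlying bin table."""
    table = reliability_table(scores, labels, n_bins)
    gaps = np.abs(table.predicted - table.observed)
    return float(gaps.mean() * 100.0), float(gaps.max() * 100.0), table


def hosmer_lemeshow(scores, labels, n_groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square statistic and p-value.

    Groups are equal-frequency by sorted score; the statistic is
    sum_g (O_g - E_g)^2 / (E_g (1 - E_g/n_g)) with E_g the sum of scores in
    group g, referred to chi-square with (groups - 2) degrees of freedom.
    Groups with a vanishing denominator (all scores 0 or all 1) are skipped
    with a warning and the degrees of freedom reduced accordingly.
    """
    s, y = _as_arrays(scores, labels)
    if n_groups < 3:
        raise ConfigError("n_groups must be at least 3")
    if len(s) < n_groups:
        raise ConfigError(f"need at least n_groups={n_groups} samples")
    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    stat = 0.0
    used = 0
    for idx in _equal_frequency_bins(len(s), n_groups):
        n_g = len(idx)
        e_g = float(s_sorted[idx].sum())
        o_g = float(y_sorted[idx].sum())
        denom = e_g * (1.0 - e_g / n_g)
        if denom < 1e-12:
            warnings.warn(
                "Hosmer-Lemeshow: skipping a degenerate group "
                "(expected count 0 or n)",
                stacklevel=2,
            )
            continue
        stat += (o_g - e_g) ** 2 / denom
        used += 1
    df = used - 2
    if df < 1:
        raise UndefinedMetricError(
            "Hosmer-Lemeshow: fewer than 3 usable groups"
        )
    p = float(chi2.sf(stat, df))
    return float(stat), p


def compute_metrics(
    scores, labels, n_bins: int = 10, n_groups: int = 10
) -> MetricRecord:
    """All four measures on one score set."""
    ece, mce, _ = calibration_errors(scores, labels, n_bins)
    hl_stat, hl_p = hosmer_lemeshow(scores, labels, n_groups)
    return MetricRecord(
        auc=auc(scores, labels), ece=ece, mce=mce,
        hl_statistic=hl_stat, hl_p=hl_p,
    )
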