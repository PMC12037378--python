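"""Model validation: ROC/AUC, threshold metrics, calibration.

The outcome of interest is "poor glycemic management", defined as
eHbA1c strictly greater than 7% (equality at 7.0 counts as negative);
the predictor is the corrected HbA1c.  Since the predictor is a percent
value rather than a probability, calibration is assessed both on the raw
score and after mapping scores through a cohort-fit univariate logistic
link.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, DataValidationError, DegenerateDataError

__all__ = [
    "roc_auc",
    "threshold_metrics",
    "calibration_curve",
    "fit_logistic_link",
    "CalibrationResult",
    "ValidationReport",
    "POOR_CONTROL_THRESHOLD",
]

#: eHbA1c threshold (%) defining the positive "poor management" class
POOR_CONTROL_THRESHOLD = 7.0


def _check_binary(label: np.ndarray) -> np.ndarray:
    label = np.asarray(label)
    uniq = np.unique(label)
    if not np.isin(uniq, (0, 1)).all():
        raise DataValidationError("labels must be binary 0/1")
    if uniq.size < 2:
        raise DegenerateDataError("both classes must be present")
    return label.astype(bool)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _auc_from_ranks(score: np.ndarray, positive: np.ndarray) -> float:
    ranks = _midrank(score)
    m = int(positive.sum())
    n = positive.size - m
    return (ranks[positive].sum() - m * (m + 1) / 2.0) / (m * n)


def _delong_variance(score: np.ndarray, positive: np.ndarray) -> Tuple[float, float]:
    """AUC and its DeLong variance via the midrank decomposition."""
    pos = score[positive]
    neg = score[~positive]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # structural components per positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return float(auc), float(var)


def roc_auc(
    score: Sequence[float],
    label: Sequence[int],
    method: str = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> Tuple[float, float, float]:
    """AUC (Mann-Whitney, ties half-credit) with a 95% confidence interval.

    ``method='delong'`` (default) uses DeLong's asymptotic variance;
    ``method='bootstrap'`` uses a seeded stratified percentile bootstrap.
    Degenerate intervals are clipped to [0, 1].
    """
    score = np.asarray(score, dtype=float)
    if not np.isfinite(score).all():
        raise DataValidationError("scores must be finite")
    positive = _check_binary(label)
    if score.shape != positive.shape:
        raise DataValidationError("score and label lengths differ")

    auc, var = _delong_variance(score, positive)
    if method == "delong":
        half = sps.norm.ppf(1 - alpha / 2) * math.sqrt(max(var, 0.0))
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(positive)
        neg_idx = np.flatnonzero(~positive)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate(
                [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
            )
            mask = np.zeros(take.size, dtype=bool)
            mask[: pos_idx.size] = True
            stats[b] = _auc_from_ranks(score[take], mask)
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    else:
        raise ConfigurationError(f"unknown CI method {method!r}")
    return auc, float(max(lo, 0.0)), float(min(hi, 1.0))


def threshold_metrics(
    score: Sequence[float], label: Sequence[int], threshold: float = POOR_CONTROL_THRESHOLD
) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of the rule score > threshold."""
    score = np.asarray(score, dtype=float)
    positive = _check_binary(label)
    predicted = score > threshold
    tp = np.sum(predicted & positive)
    tn = np.sum(~predicted & ~positive)
    fp = np.sum(predicted & ~positive)
    fn = np.sum(~predicted & positive)
    return (
        float((tp + tn) / positive.size),
        float(tp / (tp + fn)),
        float(tn / (tn + fp)),
    )


@dataclass
class CalibrationResult:
    """Quantile-binned calibration with a weighted linear summary."""

    bins: List[dict]  # each: mean_predicted, observed_fraction, n
    slope: float
    intercept: float
    n_bins_effective: int

    def to_dict(self) -> dict:
        return {
            "bins": self.bins,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_bins_effective": self.n_bins_effective,
        }


def calibration_curve(
    predicted: Sequence[float], observed: Sequence[int], n_bins: int = 10
) -> CalibrationResult:
    """Equal-count calibration bins of observed event fraction vs prediction.

    Bin edges are prediction quantiles; indistinguishable edges are merged
    with a warning (constant predictions collapse to one bin, flagged, and
    the summary slope is undefined).  The slope/intercept summarise the
    n-weighted least-squares line of observed fraction on mean prediction.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise DataValidationError("predicted and observed lengths differ")
    if not np.isfinite(predicted).all():
        raise DataValidationError("predictions must be finite")
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")

    edges = np.unique(np.quantile(predicted, np.linspace(0, 1, n_bins + 1)))
    if edges.size - 1 < n_bins:
        warnings.warn(
            f"fewer distinct predictions than bins: merged to {max(edges.size - 1, 1)}",
            stacklevel=2,
        )
    if edges.size < 2:  # constant predictions: one degenerate bin
        bins = [
            {
                "mean_predicted": float(predicted.mean()),
                "observed_fraction": float(observed.mean()),
                "n": int(observed.size),
            }
        ]
        return CalibrationResult(bins=bins, slope=float("nan"), intercept=float("nan"),
                                 n_bins_effective=1)

    idx = np.clip(np.searchsorted(edges, predicted, side="right") - 1, 0, edges.size - 2)
    bins = []
    for b in range(edges.size - 1):
        mask = idx == b
        if not mask.any():
            continue
        bins.append(
            {
                "mean_predicted": float(predicted[mask].mean()),
                "observed_fraction": float(observed[mask].mean()),
                "n": int(mask.sum()),
            }
        )
    xs = np.array([b["mean_predicted"] for b in bins])
    ys = np.array([b["observed_fraction"] for b in bins])
    ws = np.array([b["n"] for b in bins], dtype=float)
    if len(bins) >= 2 and np.ptp(xs) > 0:
        slope, intercept = np.polyfit(xs, ys, 1, w=np.sqrt(ws))
    else:
        slope, intercept = float("nan"), float("nan")
    return CalibrationResult(
        bins=bins, slope=float(slope), intercept=float(intercept),
        n_bins_effective=len(bins),
    )


def fit_logistic_link(score: Sequence[float], label: Sequence[int]) -> np.ndarray:
    """Map a raw score to event probabilities via a univariate logistic fit.

    Near-unregularised (C=1e6) so the fit is effectively maximum
    likelihood yet remains defined under complete separation.
    """
    score = np.asarray(score, dtype=float).reshape(-1, 1)
    positive = _check_binary(label).astype(int)
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
    clf.fit(score, positive)
    return clf.predict_proba(score)[:, 1]


@dataclass
class ValidationReport:
    """Per-cohort evaluation of the corrected-HbA1c score."""

    cohort_label: str
    n: int
    n_positive: int
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold_pct: float
    calibration_raw: CalibrationResult
    calibration_linked: Optional[CalibrationResult] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise DataValidationError("AUC must lie in [0, 1]")
        if not (self.auc_ci_low <= self.auc <= self.auc_ci_high):
            raise DataValidationError("AUC must lie inside its CI")

    def to_dict(self) -> dict:
        out = {
            "cohort_label": self.cohort_label,
            "n": self.n,
            "n_positive": self.n_positive,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold_pct": self.threshold_pct,
            "calibration_raw": self.calibration_raw.to_dict(),
        }
        if self.calibration_linked is not None:
            out["calibration_linked"] = self.calibration_linked.to_dict()
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)

    SUMMARY_FIELDS = (
        "cohort_label", "n", "n_positive", "auc", "auc_ci_low", "auc_ci_high",
        "accuracy", "sensitivity", "specificity", "threshold_pct",
        "calibration_slope",
    )

    def summary_row(self, sep: str = "\t") -> str:
        cal = self.calibration_linked or self.calibration_raw
        values = [
            self.cohort_label, self.n, self.n_positive,
            f"{self.auc:.6g}", f"{self.auc_ci_low:.6g}", f"{self.auc_ci_high:.6g}",
            f"{self.accuracy:.6g}", f"{self.sensitivity:.6g}", f"{self.specificity:.6g}",
            f"{self.threshold_pct:.6g}", f"{cal.slope:.6g}",
        ]
        return sep.join(str(v) for v in values)


def evaluate_scores(
    cohort_label: str,
    corrected_hba1c: Sequence[float],
    ehba1c: Sequence[float],
    threshold_pct: float = POOR_CONTROL_THRESHOLD,
    n_bins: int = 10,
    ci_method: str = "delong",
    seed: Optional[int] = None,
) -> ValidationReport:
    """Build the full per-cohort report from scores and estimated HbA1c.

    The positive class is eHbA1c > 7% (strict).
    """
    score = np.asarray(corrected_hba1c, dtype=float)
    label = (np.asarray(ehba1c, dtype=float) > POOR_CONTROL_THRESHOLD).astype(int)
    auc, lo, hi = roc_auc(score, label, method=ci_method, seed=seed)
    accuracy, sensitivity, specificity = threshold_metrics(score, label, threshold_pct)
    linked = fit_logistic_link(score, label)
    return ValidationReport(
        cohort_label=cohort_label,
        n=int(score.size),
        n_positive=int(label.sum()),
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        threshold_pct=threshold_pct,
        calibration_raw=calibration_curve(score, label, n_bins),
        calibration_linked=calibration_curve(linked, label, n_bins),
    )
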