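"""Classification metrics, the normalized mean absolute error, and the
model-comparison and error-covariate statistics.

nMAE is the primary regression metric:

    nMAE = (1 / (N * r)) * sum_i |y_i - yhat_i|

where N is the number of subjects, r the achievable range of the subscore
(4 for single items, 20 for total chorea/dystonia, 60 for the composite).
It is reported both as a proportion and as a percent of score range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .models import CVRoundResult

__all__ = [
    "EvaluationReport",
    "classification_metrics",
    "nmae",
    "compare_error_models",
    "error_covariate_correlation",
    "feature_stability",
    "error_quartiles",
]

POSITIVE_CLASS = "hd"


@dataclass
class EvaluationReport:
    """Bundle of pipeline evaluation outputs, JSON-serializable."""

    accuracy: float
    sensitivity: float
    specificity: float
    nmae_by_subscore: dict[str, float]
    error_quartiles: dict[str, tuple[float, float, float]]  # (Q1, median, Q3)
    stable_features: list[str]
    test_results: list[tuple[str, float, float]]
    predictions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (
            ("accuracy", self.accuracy),
            ("sensitivity", self.sensitivity),
            ("specificity", self.specificity),
        ):
            if not (math.isnan(value) or 0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")
        for name, (q1, med, q3) in self.error_quartiles.items():
            if not (q1 <= med <= q3):
                raise ValueError(f"quartiles of {name} not ordered: {(q1, med, q3)}")

    def as_percent(self) -> dict[str, str]:
        """Headline numbers formatted the way clinicians read them."""
        out = {
            "accuracy": f"{100 * self.accuracy:.1f}%",
            "sensitivity": f"{100 * self.sensitivity:.1f}%",
            "specificity": f"{100 * self.specificity:.1f}%",
        }
        for name, v in self.nmae_by_subscore.items():
            out[f"nmae.{name}"] = f"{100 * v:.2f}% of score range"
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, allow_nan=True) + "\n")


def classification_metrics(
    predicted: Sequence[str], true: Sequence[str]
) -> tuple[float, float, float]:
    """Accuracy, sensitivity (TP/positives) and specificity (TN/negatives).

    HD is the positive class.  If a class is absent from the truth, the
    corresponding rate is undefined and reported as NaN.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label sequences differ in length")
    correct = predicted == true
    accuracy = float(np.mean(correct))
    pos = true == POSITIVE_CLASS
    neg = ~pos
    sensitivity = float(np.mean(correct[pos])) if pos.any() else float("nan")
    specificity = float(np.mean(correct[neg])) if neg.any() else float("nan")
    return accuracy, sensitivity, specificity


def nmae(
    predicted: Sequence[float], true: Sequence[float], subscore_range: float
) -> float:
    """Mean absolute error normalized by the subscore range, as a proportion."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("predicted and true must be equal-length and non-empty")
    if subscore_range <= 0:
        raise ValueError(f"subscore range must be positive, got {subscore_range}")
    return float(np.mean(np.abs(true - predicted)) / subscore_range)


def compare_error_models(
    abs_errors_a: Sequence[float], abs_errors_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two models' absolute errors.

    Exact null distribution when both samples are small (n <= 20) and
    tie-free; the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(abs_errors_a, dtype=float)
    b = np.asarray(abs_errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both error samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def error_covariate_correlation(
    errors: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of model error with an external patient factor."""
    e = np.asarray(errors, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if e.size != c.size or e.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(e).all() and np.isfinite(c).all()):
        raise ValueError("non-finite values in correlation input")
    if np.std(e) == 0 or np.std(c) == 0:
        return float("nan"), float("nan")  # undefined for zero-variance input
    r, p = stats.pearsonr(e, c)
    return float(r), float(p)


def feature_stability(
    per_round_selections: Sequence[Sequence[str]] | Sequence[CVRoundResult],
    threshold: float = 0.5,
) -> list[str]:
    """Features selected in at least ``threshold`` of CV rounds (inclusive).

    Sorted by selection frequency, most stable first; ties broken by name.
    """
    if len(per_round_selections) == 0:
        raise ValueError("need at least one CV round")
    rounds: list[tuple[str, ...]] = []
    for sel in per_round_selections:
        if isinstance(sel, CVRoundResult):
            rounds.append(tuple(sel.selected_features))
        else:
            rounds.append(tuple(sel))
    counts: dict[str, int] = {}
    for sel in rounds:
        for name in set(sel):
            counts[name] = counts.get(name, 0) + 1
    n = len(rounds)
    stable = [(c / n, name) for name, c in counts.items() if c / n >= threshold]
    stable.sort(key=lambda t: (-t[0], t[1]))
    return [name for _, name in stable]


def error_quartiles(abs_errors: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear (type-7) interpolation."""
    e = np.asarray(abs_errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sample")
    q1, med, q3 = np.percentile(e, [25, 50, 75])
    return float(q1), float(med), float(q3)
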