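"""Leave-one-out cross-validation with unity/zero scoring.

Each reading is held out in turn; the class-conditional tables (and, for the
naive-Bayes rule, the smoothed class prior) are re-estimated from the
remaining readings only, the held-out reading is predicted, and the fold
scores 1 on a correct prediction, 0 otherwise.  The percentage accuracy is
100 times the mean fold score.

Because fitting is pure counting, each fold's model is obtained by
subtracting the held-out reading's tallies from the full-data tallies --
algebraically identical to refitting from scratch (verified against a naive
refit in the test suite) and linear-time over folds.

The held-out unit is one reading by default; ``fold_unit="patient"`` holds
out all readings of a patient together, as a sensitivity analysis for the
double-read readings sharing a patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .classify import (
    ClassPrior,
    Prediction,
    predict_max_likelihood,
    predict_naive_bayes,
)
from .cohort import CLASS_TOKENS, Dataset
from .model import CLASS_CODES, ClassConditionalModel

__all__ = ["CVResult", "RULES", "loocv", "accuracy", "format_accuracy"]

RULES = ("max_likelihood", "naive_bayes")


def accuracy(fold_scores: Sequence[int]) -> float:
    """Percentage accuracy: 100 x mean of the unity/zero fold scores."""
    scores = np.asarray(fold_scores)
    if scores.size == 0:
        raise ValueError("accuracy of an empty fold-score vector is undefined")
    return float(100.0 * scores.mean())


def format_accuracy(percent: float) -> str:
    """One-decimal display, rounding half away from zero (69.14 -> '69.1')."""
    import decimal

    q = decimal.Decimal(repr(percent)).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return str(q)


@dataclass(frozen=True)
class CVResult:
    """Aggregate outcome of a leave-one-out run."""

    task: str
    rule: str
    fold_scores: tuple[int, ...]
    per_fold_predictions: tuple[Prediction, ...] = field(repr=False, default=())
    fold_unit: str = "reading"
    alpha: float = 1.0

    @property
    def n_folds(self) -> int:
        return len(self.fold_scores)

    @property
    def accuracy_percent(self) -> float:
        return accuracy(self.fold_scores)

    def confusion_matrix(self, true_classes: Sequence[int] | None = None) -> pd.DataFrame:
        """2x2 table of true class vs predicted class over all folds."""
        if true_classes is None:
            # a fold scores 1 iff prediction equals truth, so truth is
            # recoverable from the score in the two-class setting
            true_classes = [
                p.predicted_class if s == 1 else 3 - p.predicted_class
                for s, p in zip(self.fold_scores, self.per_fold_predictions)
            ]
        tokens = CLASS_TOKENS[self.task]
        mat = pd.DataFrame(
            0,
            index=[f"true_{tokens[c]}" for c in CLASS_CODES],
            columns=[f"pred_{tokens[c]}" for c in CLASS_CODES],
        )
        for t, p in zip(true_classes, self.per_fold_predictions):
            mat.iloc[t - 1, p.predicted_class - 1] += 1
        return mat

    def report(self, true_classes: Sequence[int] | None = None) -> str:
        """Human-readable summary: accuracy, fold count, confusion counts."""
        lines = [
            f"task: {self.task}",
            f"rule: {self.rule}",
            f"fold unit: {self.fold_unit}",
            f"alpha: {self.alpha}",
            f"folds: {self.n_folds}",
            f"accuracy: {format_accuracy(self.accuracy_percent)}%",
            "",
            self.confusion_matrix(true_classes).to_string(),
        ]
        return "\n".join(lines)

    def per_fold_frame(self) -> pd.DataFrame:
        from .classify import predictions_to_frame

        df = predictions_to_frame(self.per_fold_predictions, self.task)
        df.insert(1, "score", list(self.fold_scores))
        return df


def _tally(values: np.ndarray, labels: np.ndarray, schema) -> dict[int, np.ndarray]:
    """Per-class, per-feature level tallies as padded arrays (9 x max K)."""
    kmax = max(schema.level_counts)
    counts = {c: np.zeros((schema.n_features, kmax), dtype=np.int64) for c in CLASS_CODES}
    for c in CLASS_CODES:
        sub = values[labels == c]
        for i, K in enumerate(schema.level_counts):
            counts[c][i, :K] = np.bincount(sub[:, i] - 1, minlength=K)[:K]
    return counts


def _model_from_padded(schema, task, counts, alpha) -> ClassConditionalModel:
    per_class = {
        c: [counts[c][i, :K] for i, K in enumerate(schema.level_counts)]
        for c in CLASS_CODES
    }
    return ClassConditionalModel.from_counts(schema, task, per_class, alpha=alpha)


def loocv(
    data: Dataset,
    task: str,
    rule: str = "max_likelihood",
    alpha: float = 1.0,
    prior_mode: str = "smoothed",
    fold_unit: str = "reading",
) -> CVResult:
    """Leave-one-out cross-validation for either prediction rule.

    The dataset must be fully labelled for the task and contain at least two
    readings with both classes represented.  A fold whose training set loses
    a class entirely is still fitted -- smoothing keeps every probability
    defined.  Deterministic given the dataset; fold scores depend only on
    the identity of the held-out reading, not on row order.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if prior_mode not in ("smoothed", "raw"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    if fold_unit not in ("reading", "patient"):
        raise ValueError(f"unknown fold_unit {fold_unit!r}")
    n = len(data)
    if n < 2:
        raise ValueError("leave-one-out needs at least two readings")

    schema = data.schema
    values = np.asarray([r.values for r in data], dtype=np.int64)
    labels = np.asarray([r.class_code(task) for r in data], dtype=np.int64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be represented in the dataset")

    full_counts = _tally(values, labels, schema)
    full_sizes = {c: int((labels == c).sum()) for c in CLASS_CODES}

    if fold_unit == "reading":
        groups = [[j] for j in range(n)]
    else:
        by_patient: dict[str, list[int]] = {}
        for j, r in enumerate(data):
            key = r.patient_id if r.patient_id is not None else f"__row{j}"
            by_patient.setdefault(key, []).append(j)
        groups = list(by_patient.values())

    scores: list[int] = []
    predictions: list[Prediction] = []
    order: list[int] = []
    for group in groups:
        counts = {c: full_counts[c].copy() for c in CLASS_CODES}
        sizes = dict(full_sizes)
        for j in group:
            c = int(labels[j])
            sizes[c] -= 1
            for i in range(schema.n_features):
                counts[c][i, values[j, i] - 1] -= 1
        fold_model = _model_from_padded(schema, task, counts, alpha)
        if rule == "naive_bayes":
            fold_prior = ClassPrior(
                task=task,
                counts=(sizes[1], sizes[2]),
                smoothed=(prior_mode == "smoothed"),
            )
        for j in group:
            if rule == "max_likelihood":
                pred = predict_max_likelihood(fold_model, data[j])
            else:
                pred = predict_naive_bayes(fold_model, fold_prior, data[j])
            predictions.append(pred)
            scores.append(1 if pred.predicted_class == labels[j] else 0)
            order.append(j)

    # restore dataset row order so per-fold tables align with the input
    perm = np.argsort(order, kind="stable")
    scores_arr = tuple(int(scores[p]) for p in perm)
    preds = tuple(predictions[p] for p in perm)
    return CVResult(
        task=task,
        rule=rule,
        fold_scores=scores_arr,
        per_fold_predictions=preds,
        fold_unit=fold_unit,
        alpha=alpha,
    )
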