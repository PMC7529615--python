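"""Two-class prediction rules over the fitted categorical model.

Two rules are provided:

* maximum posterior-predictive likelihood -- predict the class whose fitted
  model assigns the reading the larger likelihood;
* naive Bayes -- weight each class likelihood by an estimate of the class
  marginal p(c) and normalise, giving a posterior over classes.

The class marginal is estimated with the same add-one smoothing as the
feature tables: p(c) = (N_c + 1) / (N + 2).  The raw proportion N_c / N is
also available (``smoothed=False``) since cohort summaries usually quote it.
Scores are compared in log space; an exact tie (within 1e-12 relative)
predicts class 1 -- the milder / rarer-intervention group in both tasks --
and is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import CLASS_TOKENS, Dataset, Reading, class_counts
from .model import CLASS_CODES, ClassConditionalModel, reading_log_likelihood

__all__ = [
    "ClassPrior",
    "Prediction",
    "estimate_class_prior",
    "predict_max_likelihood",
    "predict_naive_bayes",
    "predictions_to_frame",
]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class ClassPrior:
    """Class-marginal estimate for one task."""

    task: str
    counts: tuple[int, int]  # N_c per class code 1, 2
    smoothed: bool = True

    @property
    def N(self) -> int:
        return sum(self.counts)

    @property
    def pi(self) -> tuple[float, float]:
        """Per-class probabilities; smoothed: (N_c + 1)/(N + 2), raw: N_c/N."""
        n1, n2 = self.counts
        if self.smoothed:
            return ((n1 + 1) / (self.N + 2), (n2 + 1) / (self.N + 2))
        if self.N == 0:
            raise ValueError("raw class prior is undefined on an empty dataset")
        return (n1 / self.N, n2 / self.N)

    @classmethod
    def uniform(cls, task: str) -> "ClassPrior":
        """The prior-only estimate (no data): pi = (1/2, 1/2)."""
        return cls(task=task, counts=(0, 0), smoothed=True)


def estimate_class_prior(data: Dataset, task: str, smoothed: bool = True) -> ClassPrior:
    """Estimate p(c) from reading counts, add-one smoothed by default."""
    return ClassPrior(task=task, counts=class_counts(data, task), smoothed=smoothed)


@dataclass(frozen=True)
class Prediction:
    """Outcome of classifying one reading."""

    predicted_class: int
    rule: str
    log_likelihoods: tuple[float, float]
    per_class_posterior: Optional[tuple[float, float]] = None
    tie: bool = False

    @property
    def per_class_likelihood(self) -> tuple[float, float]:
        return (math.exp(self.log_likelihoods[0]), math.exp(self.log_likelihoods[1]))


def _argmax_with_tie(scores: Sequence[float]) -> tuple[int, bool]:
    s1, s2 = scores
    scale = max(abs(s1), abs(s2), 1.0)
    if abs(s1 - s2) <= _TIE_RTOL * scale:
        return 1, True
    return (1, False) if s1 > s2 else (2, False)


def predict_max_likelihood(
    model: ClassConditionalModel, r: Union[Reading, Sequence[int]]
) -> Prediction:
    """Predict the class with the larger posterior-predictive likelihood."""
    logliks = tuple(reading_log_likelihood(model, r, c) for c in CLASS_CODES)
    predicted, tie = _argmax_with_tie(logliks)
    return Prediction(
        predicted_class=predicted,
        rule="max_likelihood",
        log_likelihoods=logliks,
        tie=tie,
    )


def predict_naive_bayes(
    model: ClassConditionalModel,
    prior: ClassPrior,
    r: Union[Reading, Sequence[int]],
) -> Prediction:
    """Predict via Bayes' rule: posterior proportional to likelihood x prior.

    The posterior is normalised over the two classes and sums to one; the
    model and prior must target the same task.
    """
    if prior.task != model.task:
        raise ValueError(
            f"task mismatch: model targets {model.task!r}, prior {prior.task!r}"
        )
    logliks = tuple(reading_log_likelihood(model, r, c) for c in CLASS_CODES)
    pi = prior.pi
    log_scores = tuple(ll + math.log(p) for ll, p in zip(logliks, pi))
    # normalise in log space for numeric hygiene
    m = max(log_scores)
    weights = [math.exp(s - m) for s in log_scores]
    z = sum(weights)
    posterior = (weights[0] / z, weights[1] / z)
    predicted, tie = _argmax_with_tie(log_scores)
    return Prediction(
        predicted_class=predicted,
        rule="naive_bayes",
        log_likelihoods=logliks,
        per_class_posterior=posterior,
        tie=tie,
    )


def predictions_to_frame(predictions: Sequence[Prediction], task: str) -> pd.DataFrame:
    """Tabulate predictions: class token, per-class scores, tie flag."""
    tokens = CLASS_TOKENS[task]
    rows = []
    for idx, p in enumerate(predictions):
        post = p.per_class_posterior or (None, None)
        rows.append(
            {
                "reading": idx,
                "rule": p.rule,
                "predicted_class": tokens[p.predicted_class],
                "log_likelihood_class1": p.log_likelihoods[0],
                "log_likelihood_class2": p.log_likelihoods[1],
                "posterior_class1": post[0],
                "posterior_class2": post[1],
                "tie": p.tie,
            }
        )
    return pd.DataFrame(rows)
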