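"""Class-conditional categorical model with a Dirichlet prior.

Each of the nine capsule-endoscopy features is modelled, within a class, as a
categorical variable with parameter vector lambda.  A symmetric Dirichlet
prior with pseudo-count alpha (default 1, i.e. add-one / Laplace smoothing)
is placed on lambda and integrated out, giving the posterior-predictive
probability of level k:

    p(f_i = k | c) = (N_k + alpha_k) / (N + sum_k alpha_k)

where N_k is the tally of level k among the class-c readings and N the number
of class-c readings.  Features are conditionally independent given the class,
so a reading's likelihood is the product of its nine feature likelihoods.
Smoothing keeps every probability strictly positive (the zero-count problem),
so the model stays defined even for a class with no training readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CLASS_TOKENS, Dataset, FeatureSchema, Reading, canonical_schema

__all__ = [
    "CategoricalPosterior",
    "ClassConditionalModel",
    "fit",
    "posterior_predictive",
    "reading_likelihood",
    "reading_log_likelihood",
    "feature_histograms",
    "abnormal_mass_difference",
    "save_model",
    "load_model",
]

CLASS_CODES = (1, 2)

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CategoricalPosterior:
    """Posterior-predictive table for one (feature, class) pair.

    ``counts`` are the literal level tallies N_k among the class's readings;
    ``alpha`` the Dirichlet pseudo-counts (one per level).
    """

    feature_index: int  # 1-based, matching the f1..f9 column names
    class_code: int
    counts: tuple[int, ...]
    alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.alpha):
            raise ValueError("counts and alpha must have equal length")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("all Dirichlet pseudo-counts must be positive")
        if any(c < 0 for c in self.counts):
            raise ValueError("level counts must be non-negative")

    @property
    def K(self) -> int:
        return len(self.counts)

    @property
    def N(self) -> int:
        """Total readings of this class seen by the table."""
        return int(sum(self.counts))

    @property
    def probs(self) -> np.ndarray:
        """Posterior-predictive probabilities (N_k + a_k) / (N + sum a)."""
        counts = np.asarray(self.counts, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        return (counts + alpha) / (self.N + alpha.sum())

    def prob(self, k: int) -> float:
        if not (1 <= k <= self.K):
            raise ValueError(f"level {k} outside 1..{self.K}")
        return float(self.probs[k - 1])


@dataclass(frozen=True)
class ClassConditionalModel:
    """Fitted per-class, per-feature posterior-predictive tables (2 x 9)."""

    schema: FeatureSchema
    task: str
    alpha: float
    tables: dict[tuple[int, int], CategoricalPosterior] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(c, i) for c in CLASS_CODES for i in range(1, self.schema.n_features + 1)}
        if set(self.tables) != expected:
            raise ValueError(
                f"model requires one table per (class, feature); "
                f"expected {len(expected)}, got {len(self.tables)}"
            )

    def table(self, c: int, i: int) -> CategoricalPosterior:
        try:
            return self.tables[(c, i)]
        except KeyError:
            raise ValueError(f"no table for class {c}, feature {i}") from None

    @property
    def class_sizes(self) -> tuple[int, int]:
        return (self.table(1, 1).N, self.table(2, 1).N)

    @classmethod
    def from_counts(
        cls,
        schema: FeatureSchema,
        task: str,
        counts: dict[int, Sequence[Sequence[int]]],
        alpha: float = 1.0,
    ) -> "ClassConditionalModel":
        """Assemble a model from per-class, per-feature level tallies."""
        if alpha <= 0:
            raise ValueError(f"alpha must be positive, got {alpha}")
        tables = {}
        for c in CLASS_CODES:
            for i, spec in enumerate(schema.features, start=1):
                tally = tuple(int(x) for x in counts[c][i - 1])
                if len(tally) != spec.K:
                    raise ValueError(
                        f"class {c}, feature {spec.column}: expected {spec.K} "
                        f"level counts, got {len(tally)}"
                    )
                tables[(c, i)] = CategoricalPosterior(
                    feature_index=i,
                    class_code=c,
                    counts=tally,
                    alpha=(float(alpha),) * spec.K,
                )
        return cls(schema=schema, task=task, alpha=float(alpha), tables=tables)


def fit(data: Dataset, task: str, alpha: float = 1.0) -> ClassConditionalModel:
    """Fit the class-conditional model by tallying level codes per class.

    Every reading must carry the label the task needs.  ``alpha`` is the
    symmetric Dirichlet pseudo-count applied to every level (default 1,
    add-one smoothing); it must be positive.  A class with no readings is
    legal: its tables reduce to the uniform prior-predictive distribution.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    schema = data.schema
    counts = {
        c: [[0] * spec.K for spec in schema.features] for c in CLASS_CODES
    }
    for r in data:
        c = r.class_code(task)
        for i, v in enumerate(r.values):
            counts[c][i][v - 1] += 1
    return ClassConditionalModel.from_counts(schema, task, counts, alpha=alpha)


def posterior_predictive(model: ClassConditionalModel, c: int, i: int, k: int) -> float:
    """p(f_i = k | c) from the fitted table; strictly inside (0, 1)."""
    return model.table(c, i).prob(k)


def reading_log_likelihood(
    model: ClassConditionalModel, r: Union[Reading, Sequence[int]], c: int
) -> float:
    """log p(reading | c): sum of the nine feature log-probabilities.

    Accumulation is done in log space; with nine bounded factors underflow is
    impossible, but the log form keeps the pipeline safe for wider schemas.
    """
    values = r.values if isinstance(r, Reading) else model.schema.validate_values(r)
    if len(values) != model.schema.n_features:
        raise ValueError("reading does not match the model's schema")
    return float(
        sum(math.log(model.table(c, i).prob(k)) for i, k in enumerate(values, start=1))
    )


def reading_likelihood(
    model: ClassConditionalModel, r: Union[Reading, Sequence[int]], c: int
) -> float:
    """p(reading | c) = prod_i p(f_i = r_i | c)."""
    return math.exp(reading_log_likelihood(model, r, c))


def feature_histograms(model: ClassConditionalModel) -> pd.DataFrame:
    """Long-form table of the fitted per-feature, per-class histograms.

    One row per (feature, class, level) holding the posterior-predictive
    probability; within each (feature, class) group the probabilities sum
    to one.  These are the histograms a reviewer would inspect to see which
    features shift mass toward abnormal levels in the severe/CD class.
    """
    tokens = CLASS_TOKENS[model.task]
    rows = []
    for i, spec in enumerate(model.schema.features, start=1):
        for c in CLASS_CODES:
            tab = model.table(c, i)
            probs = tab.probs
            for k in range(1, spec.K + 1):
                rows.append(
                    {
                        "feature": spec.column,
                        "feature_name": spec.name,
                        "class_code": c,
                        "class_label": tokens[c],
                        "level": k,
                        "level_label": spec.level_labels[k - 1],
                        "count": tab.counts[k - 1],
                        "probability": float(probs[k - 1]),
                    }
                )
    return pd.DataFrame(rows)


def abnormal_mass_difference(model: ClassConditionalModel) -> pd.DataFrame:
    """Per feature, p(k>1 | class 2) - p(k>1 | class 1).

    Positive values mean the feature's abnormal levels carry more mass in the
    severe (or CD) class -- the qualitative contrast the histograms show.
    """
    rows = []
    for i, spec in enumerate(model.schema.features, start=1):
        mass = {c: float(model.table(c, i).probs[1:].sum()) for c in CLASS_CODES}
        rows.append(
            {
                "feature": spec.column,
                "feature_name": spec.name,
                "abnormal_mass_class1": mass[1],
                "abnormal_mass_class2": mass[2],
                "abnormal_mass_difference": mass[2] - mass[1],
            }
        )
    return pd.DataFrame(rows)


def save_model(model: ClassConditionalModel, path: Union[str, Path]) -> None:
    """Serialize a fitted model to a versioned, human-readable YAML document."""
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "task": model.task,
        "alpha": model.alpha,
        "schema": [
            {"column": f.column, "name": f.name, "levels": list(f.level_labels)}
            for f in model.schema.features
        ],
        "tables": [
            {
                "class_code": c,
                "feature": model.schema.features[i - 1].column,
                "counts": list(model.table(c, i).counts),
                "probs": [float(p) for p in model.table(c, i).probs],
            }
            for c in CLASS_CODES
            for i in range(1, model.schema.n_features + 1)
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_model(path: Union[str, Path]) -> ClassConditionalModel:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {doc.get('format_version')!r}")
    from .cohort import FeatureSpec

    schema = FeatureSchema(
        tuple(
            FeatureSpec(f["column"], f["name"], tuple(f["levels"]))
            for f in doc["schema"]
        )
    )
    col_to_idx = {spec.column: i for i, spec in enumerate(schema.features, start=1)}
    counts: dict[int, list[list[int]]] = {c: [None] * schema.n_features for c in CLASS_CODES}
    for entry in doc["tables"]:
        counts[int(entry["class_code"])][col_to_idx[entry["feature"]] - 1] = entry["counts"]
    return ClassConditionalModel.from_counts(schema, doc["task"], counts, alpha=float(doc["alpha"]))
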