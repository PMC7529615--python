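"""Domain types and tabular I/O for small-bowel capsule endoscopy cohorts.

A *reading* is one expert reviewer's annotation of one capsule study: nine
categorical features (area affected, distribution pattern, mosaic pattern,
fissuring, scalloping, villous atrophy, nodularity, ulcers, extent of abnormal
mucosa), optionally accompanied by a modified-Marsh histology grade, a disease
label (celiac disease, ``CD``, versus seronegative villous atrophy, ``SNVA``),
and patient/reader identifiers.  Level code 1 always denotes the normal or
absent condition; only the distribution-pattern feature has three levels
(normal / patchy / continuous).

Two binary prediction tasks are defined over a cohort:

* ``severity`` — mild Marsh grade (0, 1, 2; class 1) versus severe Marsh grade
  (3a, 3b, 3c; class 2);
* ``disease`` — SNVA (class 1) versus CD (class 2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "MARSH_LABELS",
    "MILD_MARSH",
    "SEVERE_MARSH",
    "DISEASE_LABELS",
    "TASKS",
    "CLASS_TOKENS",
    "FeatureSpec",
    "FeatureSchema",
    "Reading",
    "Dataset",
    "canonical_schema",
    "marsh_to_severity",
    "class_counts",
    "load_readings",
    "write_readings",
    "build_reference_fixture",
]

MARSH_LABELS: tuple[str, ...] = ("0", "1", "2", "3a", "3b", "3c")
MILD_MARSH: frozenset[str] = frozenset({"0", "1", "2"})
SEVERE_MARSH: frozenset[str] = frozenset({"3a", "3b", "3c"})
DISEASE_LABELS: tuple[str, ...] = ("SNVA", "CD")
TASKS: tuple[str, ...] = ("severity", "disease")

#: Human-readable class tokens per task, indexed by class code 1 / 2.
CLASS_TOKENS: dict[str, dict[int, str]] = {
    "severity": {1: "mild", 2: "severe"},
    "disease": {1: "SNVA", 2: "CD"},
}


def _check_task(task: str) -> str:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return task


@dataclass(frozen=True)
class FeatureSpec:
    """One categorical feature: a name, a CSV column, and its K level labels."""

    column: str
    name: str
    level_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.level_labels) < 2:
            raise ValueError(f"feature {self.name!r} needs at least 2 levels")

    @property
    def K(self) -> int:
        return len(self.level_labels)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of feature descriptors defining a reading's coding."""

    features: tuple[FeatureSpec, ...]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(f.K for f in self.features)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(f.column for f in self.features)

    def validate_values(self, values: Sequence[int]) -> tuple[int, ...]:
        """Check a level-code vector against the schema; return it as a tuple."""
        if len(values) != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature values, got {len(values)}"
            )
        out = []
        for spec, v in zip(self.features, values):
            iv = int(v)
            if iv != v or not (1 <= iv <= spec.K):
                raise ValueError(
                    f"feature {spec.column} ({spec.name}): level code {v!r} "
                    f"outside 1..{spec.K}"
                )
            out.append(iv)
        return tuple(out)


@lru_cache(maxsize=1)
def canonical_schema() -> FeatureSchema:
    """The packaged 9-feature schema (level counts 2,3,2,2,2,2,2,2,2)."""
    ref = importlib.resources.files("sbce_bayes.data") / "feature_schema.yaml"
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    feats = tuple(
        FeatureSpec(f["column"], f["name"], tuple(f["levels"]))
        for f in doc["features"]
    )
    return FeatureSchema(feats)


def marsh_to_severity(marsh_label: str) -> int:
    """Map a modified-Marsh grade to severity class: 1 (mild) or 2 (severe).

    Grades 0, 1 and 2 are mild; 3a, 3b and 3c (villous atrophy) are severe.
    """
    label = str(marsh_label)
    if label in MILD_MARSH:
        return 1
    if label in SEVERE_MARSH:
        return 2
    raise ValueError(
        f"unknown Marsh label {marsh_label!r}; expected one of {MARSH_LABELS}"
    )


@dataclass(frozen=True)
class Reading:
    """One reviewer's annotation of one capsule study."""

    values: tuple[int, ...]
    marsh_label: Optional[str] = None
    disease_label: Optional[str] = None
    patient_id: Optional[str] = None
    reader_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        if self.marsh_label is not None and self.marsh_label not in MARSH_LABELS:
            raise ValueError(
                f"unknown Marsh label {self.marsh_label!r}; "
                f"expected one of {MARSH_LABELS}"
            )
        if self.disease_label is not None and self.disease_label not in DISEASE_LABELS:
            raise ValueError(
                f"unknown disease label {self.disease_label!r}; "
                f"expected one of {DISEASE_LABELS}"
            )

    def class_code(self, task: str) -> int:
        """The reading's class (1 or 2) under the given task."""
        _check_task(task)
        if task == "severity":
            if self.marsh_label is None:
                raise ValueError(
                    f"reading (patient {self.patient_id!r}) lacks the Marsh "
                    "label required for the severity task"
                )
            return marsh_to_severity(self.marsh_label)
        if self.disease_label is None:
            raise ValueError(
                f"reading (patient {self.patient_id!r}) lacks the disease "
                "label required for the disease task"
            )
        return 1 if self.disease_label == "SNVA" else 2


@dataclass(frozen=True)
class Dataset:
    """A validated cohort: a schema plus a list of readings."""

    schema: FeatureSchema
    readings: tuple[Reading, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(self.readings))
        for idx, r in enumerate(self.readings):
            try:
                self.schema.validate_values(r.values)
            except ValueError as exc:
                raise ValueError(f"reading {idx}: {exc}") from None

    def __len__(self) -> int:
        return len(self.readings)

    def __iter__(self) -> Iterator[Reading]:
        return iter(self.readings)

    def __getitem__(self, idx: int) -> Reading:
        return self.readings[idx]

    @property
    def n_patients(self) -> int:
        ids = {r.patient_id for r in self.readings}
        return len(ids)

    def with_readings(self, readings: Iterable[Reading]) -> "Dataset":
        return replace(self, readings=tuple(readings))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with canonical feature columns and label columns."""
        rows = []
        for r in self.readings:
            row = dict(zip(self.schema.columns, r.values))
            row["marsh"] = r.marsh_label
            row["disease"] = r.disease_label
            row["patient_id"] = r.patient_id
            row["reader_id"] = r.reader_id
            rows.append(row)
        cols = list(self.schema.columns) + ["marsh", "disease", "patient_id", "reader_id"]
        return pd.DataFrame(rows, columns=cols)


def class_counts(data: Dataset, task: str) -> tuple[int, int]:
    """Per-class reading counts (N_1, N_2) for the given task."""
    _check_task(task)
    n1 = n2 = 0
    for r in data:
        if r.class_code(task) == 1:
            n1 += 1
        else:
            n2 += 1
    return n1, n2


def _parse_label(raw: object, row: int, column: str) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    token = str(raw).strip()
    if token == "" or token.lower() in ("nan", "none"):
        return None
    if column == "disease":
        canon = token.upper()
        if canon not in DISEASE_LABELS:
            raise ValueError(
                f"row {row}, column disease: unknown token {token!r} "
                f"(expected CD or SNVA)"
            )
        return canon
    if column == "marsh":
        canon = token.lower()
        if canon not in MARSH_LABELS:
            raise ValueError(
                f"row {row}, column marsh: unknown token {token!r} "
                f"(expected one of {MARSH_LABELS})"
            )
        return canon
    return token


def load_readings(
    source: Union[str, Path],
    schema: Optional[FeatureSchema] = None,
) -> Dataset:
    """Read a cohort from a comma-separated table with a header row.

    Canonical feature columns are ``f1..f9`` (integer level codes); optional
    columns ``marsh``, ``disease``, ``patient_id``, ``reader_id``.  Disease
    tokens are case-insensitive on read.  Row order is preserved.  Malformed
    cells are rejected with the row and column named.
    """
    schema = schema or canonical_schema()
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")

    readings = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        record = dict(zip(df.columns, row))
        values = []
        for spec in schema.features:
            raw = record[spec.column]
            try:
                v = int(str(raw).strip())
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {row_idx}, column {spec.column}: non-integer level "
                    f"code {raw!r}"
                ) from None
            if not (1 <= v <= spec.K):
                raise ValueError(
                    f"row {row_idx}, column {spec.column}: level code {v} "
                    f"outside 1..{spec.K}"
                )
            values.append(v)
        readings.append(
            Reading(
                values=tuple(values),
                marsh_label=_parse_label(record.get("marsh"), row_idx, "marsh"),
                disease_label=_parse_label(record.get("disease"), row_idx, "disease"),
                patient_id=_parse_label(record.get("patient_id"), row_idx, "patient_id"),
                reader_id=_parse_label(record.get("reader_id"), row_idx, "reader_id"),
            )
        )
    return Dataset(schema=schema, readings=tuple(readings))


def write_readings(data: Dataset, path: Union[str, Path]) -> None:
    """Write a cohort as UTF-8 CSV with canonical columns."""
    data.to_frame().to_csv(path, index=False, encoding="utf-8")


# Patient-level Marsh distribution of the reference cohort (72 patients).
_FIXTURE_MARSH_PATIENTS: tuple[tuple[str, int], ...] = (
    ("0", 9), ("1", 15), ("2", 3), ("3a", 8), ("3b", 19), ("3c", 18),
)
# SNVA patients per severe Marsh grade (SNVA entails villous atrophy, hence
# a severe grade); the remaining patients are CD.
_FIXTURE_SNVA_PER_GRADE: dict[str, int] = {"3a": 4, "3b": 7, "3c": 7}
# Patients given a discordant second reading: 4 mild CD + 5 severe CD, which
# lifts the 72 patients to 81 readings with class counts (31, 50) for
# severity and (18, 63) for disease.
_FIXTURE_N_DUP_MILD = 4
_FIXTURE_N_DUP_SEVERE = 5


def build_reference_fixture(seed: int = 0) -> Dataset:
    """Deterministic 81-reading synthetic stand-in for the study cohort.

    The label structure is exact: 72 patients whose Marsh grades follow the
    cohort's patient distribution (9, 15, 3, 8, 19, 18 across grades 0..3c),
    18 SNVA / 63 CD readings, 31 mild / 50 severe readings, with nine CD
    patients carrying a second, independently annotated reading.  The joint
    per-reading feature values were never published, so features are drawn
    from the synthetic generator's default severity-task class-conditional
    distributions; they are synthetic and labelled as such.
    """
    import numpy as np

    from .simulate import default_config, sample_feature_vector

    schema = canonical_schema()
    rng = np.random.default_rng(seed)
    config = default_config("severity")

    patients: list[tuple[str, str, str]] = []  # (patient_id, marsh, disease)
    pid = 0
    for grade, n in _FIXTURE_MARSH_PATIENTS:
        n_snva = _FIXTURE_SNVA_PER_GRADE.get(grade, 0)
        for j in range(n):
            pid += 1
            disease = "SNVA" if j < n_snva else "CD"
            patients.append((f"P{pid:02d}", grade, disease))

    # Duplicate the last eligible CD patients of each severity group --
    # a fixed, seed-independent choice so the label structure never varies.
    mild_cd = [p for p in patients if p[1] in MILD_MARSH and p[2] == "CD"]
    severe_cd = [p for p in patients if p[1] in SEVERE_MARSH and p[2] == "CD"]
    duplicated = mild_cd[-_FIXTURE_N_DUP_MILD:] + severe_cd[-_FIXTURE_N_DUP_SEVERE:]
    dup_ids = {p[0] for p in duplicated}

    readings = []
    for patient_id, grade, disease in patients:
        severity_class = marsh_to_severity(grade)
        lam = config.lambda_true[severity_class]
        readings.append(
            Reading(
                values=sample_feature_vector(lam, rng),
                marsh_label=grade,
                disease_label=disease,
                patient_id=patient_id,
                reader_id="R1",
            )
        )
        if patient_id in dup_ids:
            readings.append(
                Reading(
                    values=sample_feature_vector(lam, rng),
                    marsh_label=grade,
                    disease_label=disease,
                    patient_id=patient_id,
                    reader_id="R2",
                )
            )
    return Dataset(schema=schema, readings=tuple(readings))
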