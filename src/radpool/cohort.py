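"""Core containers: feature schema, multifocal cohort, patient-level feature matrix.

A cohort couples a per-tumor feature table (one row per segmented lesion)
with per-patient survival outcomes.  Every downstream stage — aggregation,
feature selection, model fitting — consumes these containers, so the
invariants are enforced eagerly here and nowhere else.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ADDITIVE = "additive"
INTENSIVE = "intensive"

#: reserved column names in the tumor table
PATIENT_ID = "patient_id"
TUMOR_ID = "tumor_id"
VOLUME = "volume_cc"

#: reserved column names in the outcome table
TIME = "time_months"
EVENT = "event"


class CohortValidationError(ValueError):
    """A cohort violates a structural invariant (ids, volumes, features)."""


class SchemaError(ValueError):
    """A feature schema does not cover, or conflicts with, the data."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered classification of radiomic features as additive or intensive.

    Additive features scale with tumor bulk (size/shape descriptors) and are
    summed across a patient's lesions; intensive features describe tumor
    quality (intensity, texture) and are averaged.  The optional family tag
    (``size``, ``shape``, ``firstorder``, ``texture``) is informational.
    """

    classes: tuple[tuple[str, str], ...]
    families: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.classes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        for name, cls in self.classes:
            if cls not in (ADDITIVE, INTENSIVE):
                raise SchemaError(f"unknown class {cls!r} for feature {name!r}")
        if not any(cls == INTENSIVE for _, cls in self.classes):
            raise SchemaError("schema must contain at least one intensive feature")

    @classmethod
    def from_dict(
        cls,
        classes: Mapping[str, str],
        families: Mapping[str, str] | None = None,
    ) -> "FeatureSchema":
        fam = tuple(families.items()) if families is not None else None
        return cls(tuple(classes.items()), fam)

    @property
    def feature_names(self) -> list[str]:
        return [n for n, _ in self.classes]

    @property
    def additive(self) -> list[str]:
        return [n for n, c in self.classes if c == ADDITIVE]

    @property
    def intensive(self) -> list[str]:
        return [n for n, c in self.classes if c == INTENSIVE]

    def class_of(self, name: str) -> str:
        for n, c in self.classes:
            if n == name:
                return c
        raise SchemaError(f"feature {name!r} not in schema")

    def family_of(self, name: str) -> str | None:
        if self.families is None:
            return None
        return dict(self.families).get(name)

    def validate_columns(self, columns: Iterable[str]) -> None:
        """Require an exact, ordered match between columns and the schema."""
        cols = list(columns)
        missing = [n for n in self.feature_names if n not in cols]
        extra = [c for c in cols if c not in self.feature_names]
        if extra:
            raise SchemaError(f"feature column(s) absent from schema: {extra}")
        if missing:
            raise SchemaError(f"schema feature(s) absent from data: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, cls in self.classes:
            rows.append({"feature_name": name, "class": cls,
                         "family": self.family_of(name) or ""})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureSchema":
        if not {"feature_name", "class"}.issubset(frame.columns):
            raise SchemaError("schema file needs columns feature_name, class")
        classes = tuple(zip(frame["feature_name"], frame["class"]))
        families = None
        if "family" in frame.columns:
            fam = [(n, f) for n, f in zip(frame["feature_name"], frame["family"])
                   if isinstance(f, str) and f]
            families = tuple(fam) if fam else None
        return cls(classes, families)

    def content_hash(self) -> str:
        payload = repr(self.classes).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class Cohort:
    """Tumor-level feature table joined to per-patient survival outcomes.

    ``tumors`` has columns ``patient_id, tumor_id, volume_cc`` followed by one
    column per schema feature (in schema order).  ``outcomes`` has columns
    ``patient_id, time_months, event`` plus optional categorical patient
    attributes; its row order defines the canonical patient order.
    """

    tumors: pd.DataFrame
    outcomes: pd.DataFrame
    schema: FeatureSchema
    provenance: object = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in (PATIENT_ID, TUMOR_ID, VOLUME):
            if col not in self.tumors.columns:
                raise CohortValidationError(f"tumor table missing column {col!r}")
        for col in (PATIENT_ID, TIME, EVENT):
            if col not in self.outcomes.columns:
                raise CohortValidationError(f"outcome table missing column {col!r}")

        dup = self.tumors.duplicated([PATIENT_ID, TUMOR_ID])
        if dup.any():
            bad = self.tumors.loc[dup, [PATIENT_ID, TUMOR_ID]].iloc[0]
            raise CohortValidationError(
                f"duplicate (patient, tumor) id: ({bad[PATIENT_ID]!r}, {bad[TUMOR_ID]!r})")
        if self.outcomes[PATIENT_ID].duplicated().any():
            raise CohortValidationError("duplicate patient id in outcomes")

        tumor_pids = set(self.tumors[PATIENT_ID])
        outcome_pids = set(self.outcomes[PATIENT_ID])
        orphans = sorted(tumor_pids - outcome_pids)
        if orphans:
            raise CohortValidationError(
                f"outcome missing for patient id(s): {orphans[:5]}")
        childless = sorted(outcome_pids - tumor_pids)
        if childless:
            raise CohortValidationError(
                f"patient(s) with no tumors: {childless[:5]}")

        vols = pd.to_numeric(self.tumors[VOLUME], errors="coerce")
        if vols.isna().any():
            row = int(np.flatnonzero(vols.isna())[0])
            raise CohortValidationError(f"non-numeric volume at tumor row {row}")
        if (vols <= 0).any():
            raise CohortValidationError("all tumor volumes must be > 0")

        feature_cols = [c for c in self.tumors.columns
                        if c not in (PATIENT_ID, TUMOR_ID, VOLUME)]
        self.schema.validate_columns(feature_cols)
        if self.tumors[feature_cols].isna().any().any():
            raise CohortValidationError("missing per-tumor feature values")

        times = pd.to_numeric(self.outcomes[TIME], errors="coerce")
        if times.isna().any() or (times <= 0).any():
            raise CohortValidationError("survival times must be numeric and > 0")
        ev = set(pd.unique(self.outcomes[EVENT]))
        if not ev.issubset({0, 1}):
            raise CohortValidationError(f"event indicator must be 0/1, got {ev}")

    # -- accessors --------------------------------------------------------
    @property
    def patient_ids(self) -> list:
        return self.outcomes[PATIENT_ID].tolist()

    @property
    def n_patients(self) -> int:
        return len(self.outcomes)

    @property
    def n_tumors(self) -> int:
        return len(self.tumors)

    @property
    def feature_names(self) -> list[str]:
        return self.schema.feature_names

    def tumor_counts(self) -> pd.Series:
        """Number of lesions per patient, indexed by patient id (canonical order)."""
        counts = self.tumors.groupby(PATIENT_ID).size()
        return counts.reindex(self.patient_ids)

    def subset(self, patient_ids: Iterable) -> "Cohort":
        """Restrict to the given patients, preserving canonical order."""
        keep = set(patient_ids)
        if not keep:
            raise CohortValidationError("cannot subset to zero patients")
        outcomes = self.outcomes[self.outcomes[PATIENT_ID].isin(keep)].reset_index(drop=True)
        tumors = self.tumors[self.tumors[PATIENT_ID].isin(keep)].reset_index(drop=True)
        return Cohort(tumors, outcomes, self.schema, provenance=self.provenance)


@dataclass
class PatientFeatureMatrix:
    """Patient-level features produced by one aggregation method.

    ``values`` is indexed by patient id in the cohort's canonical order; a
    metastasis-count covariate, when present, is the column named by
    ``count_column`` and is carried through feature selection untouched.
    """

    values: pd.DataFrame
    method: str
    k: int | None = None
    count_column: str | None = None
    selection: str | None = None  # provenance of any reduction applied

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise CohortValidationError(
                f"patient feature matrix for {self.method!r} has missing values")

    @property
    def feature_columns(self) -> list[str]:
        """Columns subject to selection/standardization (count column excluded)."""
        return [c for c in self.values.columns if c != self.count_column]

    @property
    def label(self) -> str:
        return f"{self.method}[k={self.k}]" if self.k is not None else self.method
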