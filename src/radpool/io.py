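"""Delimited-text I/O for cohorts, matrices, configs and result tables.

All files are UTF-8 CSV with a header row and '.' decimal separator.
Floats are written with 17 significant digits so a write/read round trip
reproduces the in-memory cohort bit-exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    EVENT,
    PATIENT_ID,
    TIME,
    TUMOR_ID,
    VOLUME,
    Cohort,
    CohortValidationError,
    FeatureSchema,
    PatientFeatureMatrix,
    SchemaError,
)
from .synthetic import GeneratorConfig

FLOAT_FMT = "%.17g"

TUMOR_FILE = "tumors.csv"
OUTCOME_FILE = "outcomes.csv"
SCHEMA_FILE = "schema.csv"


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write tumor table, outcome table and schema under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"tumors": out / TUMOR_FILE, "outcomes": out / OUTCOME_FILE,
             "schema": out / SCHEMA_FILE}
    cohort.tumors.to_csv(paths["tumors"], index=False, float_format=FLOAT_FMT)
    cohort.outcomes.to_csv(paths["outcomes"], index=False, float_format=FLOAT_FMT)
    cohort.schema.to_frame().to_csv(paths["schema"], index=False)
    return paths


def read_schema(schema_path) -> FeatureSchema:
    frame = pd.read_csv(schema_path, dtype=str, keep_default_na=False)
    return FeatureSchema.from_frame(frame)


def read_cohort(tumor_path, outcome_path, schema_path) -> Cohort:
    """Load a cohort from its three delimited files, validating eagerly.

    Malformed numeric cells are reported with their 1-based file line
    number (header = line 1).
    """
    schema = read_schema(schema_path)
    tumors = pd.read_csv(tumor_path, float_precision="round_trip")
    outcomes = pd.read_csv(outcome_path, float_precision="round_trip")

    for col in (PATIENT_ID, TUMOR_ID, VOLUME):
        if col not in tumors.columns:
            raise CohortValidationError(
                f"{tumor_path}: missing required column {col!r}")
    vols = pd.to_numeric(tumors[VOLUME], errors="coerce")
    bad = np.flatnonzero(vols.isna() | ~np.isfinite(vols))
    if len(bad):
        raise CohortValidationError(
            f"{tumor_path}: non-numeric volume at line {int(bad[0]) + 2}")
    feature_cols = [c for c in tumors.columns
                    if c not in (PATIENT_ID, TUMOR_ID, VOLUME)]
    schema.validate_columns(feature_cols)
    for col in feature_cols:
        nums = pd.to_numeric(tumors[col], errors="coerce")
        bad = np.flatnonzero(nums.isna())
        if len(bad):
            raise CohortValidationError(
                f"{tumor_path}: non-numeric value in {col!r} at line {int(bad[0]) + 2}")
        tumors[col] = nums
    tumors[VOLUME] = vols
    # order feature columns to the schema's canonical order
    tumors = tumors[[PATIENT_ID, TUMOR_ID, VOLUME] + schema.feature_names]
    return Cohort(tumors, outcomes, schema, provenance=str(tumor_path))


# ---------------------------------------------------------------------------
# patient matrices and result tables
# ---------------------------------------------------------------------------

def write_matrix(matrix: PatientFeatureMatrix, path, schema: FeatureSchema | None = None) -> Path:
    """Patient-level matrix with a provenance header line."""
    path = Path(path)
    header = (f"# radpool-matrix method={matrix.method} k={matrix.k} "
              f"count_column={matrix.count_column} "
              f"selection={matrix.selection} "
              f"schema={schema.content_hash() if schema else 'none'}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        matrix.values.to_csv(fh, float_format=FLOAT_FMT)
    return path


def read_matrix(path) -> PatientFeatureMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# radpool-matrix"):
            raise ValueError(f"{path}: not a radpool matrix file")
        meta = dict(tok.split("=", 1) for tok in header[2:].split()[1:])
        values = pd.read_csv(fh, index_col=PATIENT_ID,
                             float_precision="round_trip")
    k = None if meta.get("k") in (None, "None") else int(meta["k"])
    count_col = None if meta.get("count_column") in (None, "None") else meta["count_column"]
    selection = None if meta.get("selection") in (None, "None") else meta["selection"]
    return PatientFeatureMatrix(values, method=meta.get("method", "unknown"),
                                k=k, count_column=count_col, selection=selection)


def write_results(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------

def write_generator_config(config: GeneratorConfig, path) -> Path:
    path = Path(path)
    payload = asdict(config)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_generator_config(path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)

    def tup(x):
        return tuple(tup(v) if isinstance(v, list) else v for v in x)

    for key, val in list(payload.items()):
        if isinstance(val, list):
            payload[key] = tup(val)
    return GeneratorConfig(**payload)


def config_hash(config) -> str:
    payload = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_manifest(path, *, seed: int, config) -> Path:
    """Run manifest: config hash, seed, package versions."""
    import lifelines
    import sklearn
    import sksurv

    from . import __version__

    payload = {
        "radpool_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "scikit-survival": sksurv.__version__,
        "scikit-learn": sklearn.__version__,
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path
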