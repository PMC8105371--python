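"""Patient-level aggregation of per-tumor radiomic feature vectors.

Six methods map the set of lesions of one patient to a single feature row:

1. ``unweighted_average`` — additive features summed, intensive averaged.
2. ``weighted_average``   — intensive features volume-weighted over all lesions.
3. ``weighted_top_k``     — volume-weighted over the k largest lesions (k=3
   mirrors the three-metastasis cut-off of the Graded Prognostic Assessment).
4. ``largest_plus_count`` — largest lesion's features plus a lesion-count column.
5. ``largest_only``       — largest lesion's features.
6. ``smallest_only``      — smallest lesion's features (negative control).

The additive/intensive split follows the schema: size and shape descriptors
accumulate with tumor burden and are summed, everything else is a quality
measure and is averaged.  Under the weighted variants the additive features
are summed (unweighted) over the same included lesion set S, and intensive
features get weights w_i = v_i / sum_{j in S} v_j.
"""

from __future__ import annotations

import pandas as pd

from .cohort import (
    PATIENT_ID,
    TUMOR_ID,
    VOLUME,
    Cohort,
    PatientFeatureMatrix,
)

COUNT_COLUMN = "n_metastases"

METHODS = (
    "unweighted_average",
    "weighted_average",
    "weighted_top_k",
    "largest_plus_count",
    "largest_only",
    "smallest_only",
)


def _sorted_tumors(cohort: Cohort, ascending: bool) -> pd.DataFrame:
    # stable sort with tumor-id tie-break so volume ties are deterministic
    df = cohort.tumors
    return df.sort_values(
        [PATIENT_ID, VOLUME, TUMOR_ID],
        ascending=[True, ascending, True],
        kind="mergesort",
    )


def _finalize(values: pd.DataFrame, cohort: Cohort, method: str,
              k: int | None = None, count_column: str | None = None,
              ) -> PatientFeatureMatrix:
    cols = list(cohort.feature_names)
    if count_column:
        cols.append(count_column)
    values = values.reindex(index=cohort.patient_ids, columns=cols)
    values.index.name = PATIENT_ID
    return PatientFeatureMatrix(values, method=method, k=k, count_column=count_column)


def aggregate_unweighted(cohort: Cohort) -> PatientFeatureMatrix:
    """Sum additive features and average intensive features over all lesions."""
    g = cohort.tumors.groupby(PATIENT_ID)
    parts = []
    if cohort.schema.additive:
        parts.append(g[cohort.schema.additive].sum())
    parts.append(g[cohort.schema.intensive].mean())
    return _finalize(pd.concat(parts, axis=1), cohort, "unweighted_average")


def aggregate_weighted(cohort: Cohort, top_k: int | None = None) -> PatientFeatureMatrix:
    """Volume-weighted average of intensive features over the included lesions.

    With ``top_k`` set, only the k largest lesions per patient enter the
    included set S (all lesions when a patient has fewer than k).  Intensive
    features are weighted by lesion volume share within S; additive features
    are summed (unweighted) over S.
    """
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    ordered = _sorted_tumors(cohort, ascending=False)
    sub = ordered.groupby(PATIENT_ID, sort=False).head(top_k) if top_k else ordered

    total = sub.groupby(PATIENT_ID)[VOLUME].transform("sum")
    if (total <= 0).any():
        raise ValueError("zero total volume in an included lesion set")
    w = sub[VOLUME] / total

    parts = []
    if cohort.schema.additive:
        parts.append(sub.groupby(PATIENT_ID)[cohort.schema.additive].sum())
    weighted = sub[cohort.schema.intensive].mul(w, axis=0)
    parts.append(weighted.groupby(sub[PATIENT_ID]).sum())

    method = "weighted_top_k" if top_k is not None else "weighted_average"
    return _finalize(pd.concat(parts, axis=1), cohort, method, k=top_k)


def select_extreme(cohort: Cohort, which: str, append_count: bool = False,
                   ) -> PatientFeatureMatrix:
    """Take the single largest or smallest lesion's feature vector per patient.

    ``append_count`` adds the patient's total lesion count as an extra column
    (the largest-plus-count method); the count enters models raw, not as a
    feature subject to selection.
    """
    if which not in ("largest", "smallest"):
        raise ValueError(f"which must be 'largest' or 'smallest', got {which!r}")
    ordered = _sorted_tumors(cohort, ascending=(which == "smallest"))
    rows = ordered.groupby(PATIENT_ID, sort=False).head(1).set_index(PATIENT_ID)
    values = rows[cohort.feature_names].copy()

    if append_count:
        values[COUNT_COLUMN] = cohort.tumors.groupby(PATIENT_ID).size()
        method, count_column = "largest_plus_count", COUNT_COLUMN
    else:
        method = "largest_only" if which == "largest" else "smallest_only"
        count_column = None
    return _finalize(values, cohort, method, count_column=count_column)


def aggregate(cohort: Cohort, method: str, k: int | None = None,
              ) -> PatientFeatureMatrix:
    """Dispatch one of the six aggregation methods by label."""
    if method == "unweighted_average":
        return aggregate_unweighted(cohort)
    if method == "weighted_average":
        return aggregate_weighted(cohort)
    if method == "weighted_top_k":
        return aggregate_weighted(cohort, top_k=3 if k is None else k)
    if method == "largest_plus_count":
        return select_extreme(cohort, "largest", append_count=True)
    if method == "largest_only":
        return select_extreme(cohort, "largest")
    if method == "smallest_only":
        return select_extreme(cohort, "smallest")
    raise ValueError(f"unknown aggregation method {method!r}; choose from {METHODS}")
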