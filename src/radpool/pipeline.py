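"""Orchestration: method x model comparison, sub-group and sensitivity runs.

The comparison harness mirrors the study design: for each aggregation
method, build the patient-level matrix, reduce it (mRMR top-20 by default),
then benchmark each survival model by repeated 50% subsampling.  Sub-group
analyses repeat the comparison (Cox model only by default) within bins of
metastasis count or largest-lesion volume; sensitivity analyses vary the
top-k window (k = 2, 4), swap mRMR for PCA at 90% retained variance, and
run the penalized/forest models on all features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import aggregation as agg
from . import selection as sel
from .cohort import EVENT, PATIENT_ID, TIME, VOLUME, Cohort, PatientFeatureMatrix
from .survival import MODEL_KINDS, DegenerateDesignError, bootstrap_evaluate

logger = logging.getLogger("radpool")

SELECTION_MODES = ("mrmr_top20", "pca_90", "all_features")

RESULT_COLUMNS = ["analysis", "axis", "bin", "n_patients", "aggregation", "k",
                  "model", "selection", "mean_c", "ci_low", "ci_high",
                  "n_valid_replicates", "flag"]

DEFAULT_METHODS: tuple[tuple[str, int | None], ...] = (
    ("unweighted_average", None),
    ("weighted_average", None),
    ("weighted_top_k", 3),
    ("largest_plus_count", None),
    ("largest_only", None),
    ("smallest_only", None),
)


@dataclass(frozen=True)
class AnalysisPlan:
    """Declarative description of one benchmarking run."""

    methods: tuple[tuple[str, int | None], ...] = DEFAULT_METHODS
    models: tuple[str, ...] = ("cox", "cox_lasso", "rsf")
    selection: str = "mrmr_top20"
    n_mrmr: int = 20
    pca_retained: float = 0.9
    selection_scope: str = "global"  # or "per_replicate"
    n_replicates: int = 100
    fraction: float = 0.5
    cv_folds: int = 5
    count_bins: tuple[tuple[int, int | None], ...] = ((1, 5), (5, 11), (11, None))
    volume_bins: tuple[tuple[float, float | None], ...] = (
        (0.0, 0.2), (0.2, 0.7), (0.7, None))
    lasso_grid: dict | None = None
    rsf_grid: dict | None = None
    evaluate_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, _k in self.methods:
            if name not in agg.METHODS:
                raise ValueError(f"unsupported aggregation method {name!r}")
        for m in self.models:
            if m not in MODEL_KINDS:
                raise ValueError(f"unsupported model kind {m!r}")
        if self.selection not in SELECTION_MODES:
            raise ValueError(f"selection must be one of {SELECTION_MODES}")
        if self.selection_scope not in ("global", "per_replicate"):
            raise ValueError("selection_scope must be 'global' or 'per_replicate'")
        for bins, label in ((self.count_bins, "count_bins"),
                            (self.volume_bins, "volume_bins")):
            for (lo, hi), (lo2, _hi2) in zip(bins, bins[1:]):
                if hi != lo2:
                    raise ValueError(f"{label} must partition the axis "
                                     "(contiguous half-open intervals)")
            if bins[-1][1] is not None:
                raise ValueError(f"last {label} interval must be unbounded above")

    def grid_for(self, kind: str) -> dict | None:
        return {"cox": None, "cox_lasso": self.lasso_grid,
                "rsf": self.rsf_grid}[kind]


def _cell_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _fit_selector(plan: AnalysisPlan, matrix: PatientFeatureMatrix,
                  outcomes: pd.DataFrame) -> sel.SelectionResult:
    if plan.selection == "mrmr_top20":
        return sel.mrmr_select(matrix, outcomes, n_select=plan.n_mrmr)
    if plan.selection == "pca_90":
        return sel.pca_reduce(matrix, retained_variance=plan.pca_retained)
    return sel.passthrough(matrix)


def _flagged_row(method: str, k, model: str, selection: str, reason: str) -> dict:
    return {"aggregation": method, "k": "" if k is None else k, "model": model,
            "selection": selection, "mean_c": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "n_valid_replicates": 0, "flag": reason}


def run_comparison(cohort: Cohort, plan: AnalysisPlan) -> pd.DataFrame:
    """Benchmark every (aggregation method x survival model) cell of the plan.

    Returns one row per cell with the mean held-out C-index, its 2.5/97.5
    percentile interval over bootstrap replicates, and a degeneracy flag
    where a cell could not be scored.  Fully deterministic given the plan
    seed.
    """
    rows = []
    for method, k in plan.methods:
        matrix = agg.aggregate(cohort, method, k=k)
        selector = None
        sel_label = plan.selection
        if plan.selection_scope == "global":
            try:
                fitted = _fit_selector(plan, matrix, cohort.outcomes)
                matrix_red = fitted.transform(matrix)
                if fitted.method == "pca":
                    logger.info("pca components for %s: %d",
                                matrix.label, fitted.n_components)
                    sel_label = fitted.describe()
            except (ValueError, DegenerateDesignError) as err:
                logger.warning("selection failed for %s: %s", matrix.label, err)
                for model in plan.models:
                    rows.append(_flagged_row(method, k, model, plan.selection,
                                             f"selection: {err}"))
                continue
        else:
            matrix_red = matrix
            selector = lambda m, o, _p=plan: _fit_selector(_p, m, o)  # noqa: E731

        for model in plan.models:
            # one seed per model kind: every method is evaluated on the same
            # bootstrap splits, so method comparisons are paired
            seed = _cell_seed(plan.seed, MODEL_KINDS.index(model))
            logger.info("benchmark %s x %s (seed %d)", matrix.label, model, seed)
            result = bootstrap_evaluate(
                matrix_red, cohort.outcomes, model,
                n_replicates=plan.n_replicates, fraction=plan.fraction,
                seed=seed, grids=plan.grid_for(model), cv_folds=plan.cv_folds,
                refit=not plan.evaluate_only, select_fn=selector)
            row = result.to_row()
            row["aggregation"] = method  # method label, not the matrix tag
            row["selection"] = sel_label
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.insert(0, "analysis", "comparison")
    frame.insert(1, "axis", "")
    frame.insert(2, "bin", "")
    frame.insert(3, "n_patients", cohort.n_patients)
    return frame[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# sub-group analysis
# ---------------------------------------------------------------------------

def _bin_label(lo, hi, unit: str = "") -> str:
    if hi is None:
        return f">={lo}{unit}"
    return f"[{lo},{hi}){unit}"


def assign_bins(cohort: Cohort, axis: str, plan: AnalysisPlan) -> pd.Series:
    """Bin assignment per patient; bins partition the axis (half-open)."""
    if axis == "met_count":
        values = cohort.tumor_counts()
        bins = plan.count_bins
        unit = ""
    elif axis == "largest_volume":
        values = cohort.tumors.groupby(PATIENT_ID)[VOLUME].max().reindex(
            cohort.patient_ids)
        bins = plan.volume_bins
        unit = "cc"
    else:
        raise ValueError("axis must be 'met_count' or 'largest_volume'")
    labels = pd.Series("", index=values.index, dtype=object)
    for lo, hi in bins:
        mask = (values >= lo) if hi is None else ((values >= lo) & (values < hi))
        labels[mask] = _bin_label(lo, hi, unit)
    if (labels == "").any():
        raise ValueError("bins do not cover the axis")
    return labels


def subgroup_analysis(cohort: Cohort, plan: AnalysisPlan, axis: str,
                      ) -> pd.DataFrame:
    """Run the comparison inside each bin of the chosen axis (Cox by default).

    Feature selection is re-fitted within each bin; each bin's seed is the
    parent seed offset by the bin index so bins are independent but
    reproducible.
    """
    labels = assign_bins(cohort, axis, plan)
    bins = plan.count_bins if axis == "met_count" else plan.volume_bins
    unit = "" if axis == "met_count" else "cc"
    models = plan.models if plan.models != ("cox", "cox_lasso", "rsf") else ("cox",)
    frames = []
    for b_idx, (lo, hi) in enumerate(bins):
        label = _bin_label(lo, hi, unit)
        pids = labels.index[labels == label]
        if len(pids) == 0:
            row = {c: "" for c in RESULT_COLUMNS}
            row.update({"analysis": "subgroup", "axis": axis, "bin": label,
                        "n_patients": 0, "mean_c": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "n_valid_replicates": 0,
                        "flag": "empty bin"})
            frames.append(pd.DataFrame([row])[RESULT_COLUMNS])
            continue
        sub = cohort.subset(pids)
        sub_plan = replace(plan, models=models, seed=plan.seed + b_idx)
        frame = run_comparison(sub, sub_plan)
        frame["analysis"] = "subgroup"
        frame["axis"] = axis
        frame["bin"] = label
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_analysis(cohort: Cohort, plan: AnalysisPlan) -> pd.DataFrame:
    """Three perturbations of the main analysis.

    (a) volume-weighted top-k with k = 2 and k = 4 (alongside k = 3) for
    every model; (b) PCA at 90% retained variance instead of mRMR, Cox model,
    across every aggregation method; (c) no feature selection at all for the
    penalized Cox and forest models.
    """
    frames = []

    topk = replace(plan, methods=(("weighted_top_k", 2), ("weighted_top_k", 3),
                                  ("weighted_top_k", 4)))
    frame = run_comparison(cohort, topk)
    frame["analysis"] = "sensitivity_topk"
    frames.append(frame)

    pca_plan = replace(plan, selection="pca_90", models=("cox",), seed=plan.seed + 101)
    frame = run_comparison(cohort, pca_plan)
    frame["analysis"] = "sensitivity_pca"
    frames.append(frame)

    all_models = tuple(m for m in ("cox_lasso", "rsf") if m in plan.models) or ("cox_lasso",)
    all_plan = replace(plan, selection="all_features", models=all_models,
                       seed=plan.seed + 202)
    frame = run_comparison(cohort, all_plan)
    frame["analysis"] = "sensitivity_all_features"
    frames.append(frame)

    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(cohort: Cohort, plan: AnalysisPlan | None = None,
                     ) -> pd.DataFrame:
    """Demographics-style summary: strata counts with percentages, totals,
    Kaplan-Meier median survival and the censored fraction.

    Percentages are of total patients, rounded half-up to one decimal.
    Categorical patient attributes present in the outcome table (any column
    beyond id/time/event) are summarized the same way.
    """
    plan = plan or AnalysisPlan()
    n = cohort.n_patients
    rows = []

    def add(section, label, count=None, value=None):
        pct = round_half_up(100.0 * count / n) if count is not None else ""
        rows.append({"section": section, "label": label,
                     "count": "" if count is None else int(count),
                     "percent": pct,
                     "value": "" if value is None else value})

    add("totals", "patients", value=n)
    add("totals", "tumors", value=cohort.n_tumors)

    km = KaplanMeierFitter()
    km.fit(cohort.outcomes[TIME], cohort.outcomes[EVENT])
    add("survival", "median_survival_months", value=float(km.median_survival_time_))
    n_cens = int((cohort.outcomes[EVENT] == 0).sum())
    add("survival", "right_censored", count=n_cens)

    labels = assign_bins(cohort, "met_count", plan)
    for lo, hi in plan.count_bins:
        lab = _bin_label(lo, hi)
        add("metastasis_count", lab, count=int((labels == lab).sum()))

    reserved = {PATIENT_ID, TIME, EVENT}
    for col in cohort.outcomes.columns:
        if col in reserved:
            continue
        series = cohort.outcomes[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            for level, count in series.value_counts().items():
                add(col, str(level), count=int(count))
    return pd.DataFrame(rows)
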