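"""Survival models and censoring-aware discrimination metrics.

Three risk models are benchmarked: a Cox proportional-hazards model (Efron
handling of tied event times, via lifelines), an L1-penalized Cox model with
the penalty chosen by five-fold cross-validated concordance (scikit-survival
coxnet path), and a random survival forest tuned the same way.

Discrimination is Harrell's concordance index computed over comparable pairs
(t_i < t_j with event_i = 1); pairs with tied observed times are treated as
non-comparable.  Evaluation mirrors the bootstrap protocol of repeated 50%
subsampling without replacement: fit on the subsample, score the held-out
half, summarize the replicate C distribution by its mean and 2.5/97.5
percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cohort import EVENT, PATIENT_ID, TIME, PatientFeatureMatrix

MODEL_KINDS = ("cox", "cox_lasso", "rsf")

DEFAULT_LASSO_GRID: dict = {"alphas": tuple(np.logspace(-3, 1, 20))}
DEFAULT_RSF_GRID: dict = {
    "n_estimators": (200, 500),
    "min_samples_leaf": (5, 15),
    "max_features": ("sqrt", 0.333),
}


class DegenerateDesignError(RuntimeError):
    """Design matrix too degenerate to fit (collinear, no events, no fit)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(times, events, risks) -> float:
    """Harrell's C over comparable pairs; tied observed times not comparable.

    A pair (i, j) is comparable when t_i < t_j and patient i died.  Each
    comparable pair contributes 1 if risk_i > risk_j, 0.5 on a risk tie, 0
    otherwise.  Returns 0.5 (with a warning) when no pair is comparable.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    r = np.asarray(risks, dtype=float)
    if not (t.shape == e.shape == r.shape) or t.ndim != 1:
        raise ValueError("times, events, risks must be 1-d and equally long")
    if len(t) < 2:
        raise ValueError("need at least 2 observations")
    if not set(np.unique(e)).issubset({0, 1}):
        raise ValueError("events must be binary 0/1")
    if not np.all(np.isfinite(r)):
        raise ValueError("risks must be finite")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")

    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        warnings.warn("no comparable pairs; returning 0.5", stacklevel=2)
        return 0.5
    concordant = int(((r[:, None] > r[None, :]) & comparable).sum())
    tied = int(((r[:, None] == r[None, :]) & comparable).sum())
    return (concordant + 0.5 * tied) / n_comp


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """A fitted survival model with its training standardization.

    Feature columns are z-scored with statistics learned on the training
    split; the metastasis-count covariate (``count_column``) passes through
    raw.  ``score`` returns one finite risk per patient, higher meaning
    higher predicted hazard, and refuses matrices whose columns do not match
    the training columns exactly.
    """

    kind: str
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    count_column: str | None
    estimator: object
    best_params: dict = field(default_factory=dict)

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                f"feature mismatch: model trained on {self.feature_names}, "
                f"got {list(X.columns)}")
        Z = (X.to_numpy(dtype=float) - self.center) / self.scale
        return Z

    def score(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._standardize(X)
        if self.kind == "cox":
            risks = Z @ self.estimator.params_.to_numpy()
        elif self.kind == "cox_lasso":
            risks = self.estimator.predict(Z)
        else:
            risks = self.estimator.predict(Z)
        risks = np.asarray(risks, dtype=float).ravel()
        if not np.all(np.isfinite(risks)):
            raise DegenerateDesignError("non-finite risk scores")
        return risks

    @property
    def coefficients(self) -> pd.Series:
        """Cox coefficients on the original (unstandardized) feature scale."""
        if self.kind != "cox":
            raise AttributeError("coefficients exposed for the cox model only")
        return self.estimator.params_.to_numpy() / self.scale  # type: ignore

    def coefficient_table(self) -> pd.DataFrame:
        """Cox estimates, standard errors and 95% Wald CIs, original scale."""
        if self.kind != "cox":
            raise AttributeError("coefficient table exposed for the cox model only")
        beta = self.estimator.params_.to_numpy() / self.scale
        se = self.estimator.standard_errors_.to_numpy() / self.scale
        return pd.DataFrame({
            "coef": beta, "se": se,
            "ci_low": beta - 1.959963984540054 * se,
            "ci_high": beta + 1.959963984540054 * se,
        }, index=self.feature_names)


def _standardization(X: pd.DataFrame, count_column: str | None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    vals = X.to_numpy(dtype=float)
    center = vals.mean(axis=0)
    scale = vals.std(axis=0)
    for j, col in enumerate(X.columns):
        if col == count_column:
            center[j], scale[j] = 0.0, 1.0  # pass the count covariate raw
        elif scale[j] == 0.0:
            scale[j] = 1.0  # constant column -> zeros; rank check flags it
    return center, scale


def _as_frame(matrix) -> tuple[pd.DataFrame, str | None]:
    if isinstance(matrix, PatientFeatureMatrix):
        return matrix.values, matrix.count_column
    return matrix, None


def _outcome_arrays(outcomes: pd.DataFrame, index) -> tuple[np.ndarray, np.ndarray]:
    out = outcomes.set_index(PATIENT_ID) if PATIENT_ID in outcomes.columns else outcomes
    missing = [i for i in index if i not in out.index]
    if missing:
        raise ValueError(f"outcomes misaligned with matrix rows: missing {missing[:5]}")
    sub = out.loc[index]
    return sub[TIME].to_numpy(dtype=float), sub[EVENT].to_numpy(dtype=int)


def _cv_folds(n: int, n_folds: int, events: np.ndarray, seed: int):
    """Shuffled K-fold index pairs; reshuffle once if a training fold has no event."""
    for attempt in (0, 1):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        ok = all(events[np.concatenate([f for j, f in enumerate(folds) if j != i])].sum() >= 2
                 and events[folds[i]].sum() >= 1
                 for i in range(n_folds))
        if ok:
            return [(np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
                    for i in range(n_folds)]
    raise DegenerateDesignError("no events in a cross-validation fold")


def _fit_cox(Z: np.ndarray, times, events, names) -> CoxPHFitter:
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise DegenerateDesignError("collinear")
    df = pd.DataFrame(Z, columns=names)
    df[TIME] = times
    df[EVENT] = events
    cph = CoxPHFitter()  # Efron partial likelihood for tied event times
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=TIME, event_col=EVENT)
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        raise DegenerateDesignError(f"cox did not converge: {err}") from err
    return cph


def _fit_cox_lasso(Z, times, events, grids, cv_folds, seed):
    alphas = sorted(grids.get("alphas", DEFAULT_LASSO_GRID["alphas"]), reverse=True)
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    folds = _cv_folds(len(times), cv_folds, events, seed)
    mean_c = np.zeros(len(alphas))
    for train, test in folds:
        path = CoxnetSurvivalAnalysis(alphas=alphas, l1_ratio=1.0, fit_baseline_model=False)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                path.fit(Z[train], y[train])
        except (ValueError, ArithmeticError) as err:
            raise DegenerateDesignError(f"coxnet path failed: {err}") from err
        for a_idx, alpha in enumerate(alphas):
            risks = path.predict(Z[test], alpha=alpha)
            if np.ptp(risks) == 0 or not np.all(np.isfinite(risks)):
                mean_c[a_idx] += 0.5
            else:
                mean_c[a_idx] += concordance_index(times[test], events[test], risks)
    mean_c /= len(folds)
    best = int(np.argmax(mean_c))  # ties -> strongest penalty (alphas descending)
    model = CoxnetSurvivalAnalysis(alphas=alphas, l1_ratio=1.0, fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    return (_CoxnetAtAlpha(model, alphas[best]),
            {"alpha": alphas[best], "cv_mean_c": float(mean_c[best])})


class _CoxnetAtAlpha:
    """Frozen coxnet prediction at one penalty from a fitted path."""

    def __init__(self, path: CoxnetSurvivalAnalysis, alpha: float):
        self._path, self._alpha = path, alpha

    def predict(self, Z):
        return self._path.predict(Z, alpha=self._alpha)


def _fit_rsf(Z, times, events, grids, cv_folds, seed):
    grid = [(n, leaf, mf)
            for n in grids.get("n_estimators", DEFAULT_RSF_GRID["n_estimators"])
            for leaf in grids.get("min_samples_leaf", DEFAULT_RSF_GRID["min_samples_leaf"])
            for mf in grids.get("max_features", DEFAULT_RSF_GRID["max_features"])]
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    if len(grid) > 1:
        folds = _cv_folds(len(times), cv_folds, events, seed)
        scores = np.zeros(len(grid))
        for g_idx, (n, leaf, mf) in enumerate(grid):
            for train, test in folds:
                forest = RandomSurvivalForest(
                    n_estimators=n, min_samples_leaf=leaf, max_features=mf,
                    random_state=seed, n_jobs=1)
                forest.fit(Z[train], y[train])
                risks = forest.predict(Z[test])
                scores[g_idx] += (0.5 if np.ptp(risks) == 0 else
                                  concordance_index(times[test], events[test], risks))
        scores /= len(folds)
        n, leaf, mf = grid[int(np.argmax(scores))]
    else:
        n, leaf, mf = grid[0]
    forest = RandomSurvivalForest(n_estimators=n, min_samples_leaf=leaf,
                                  max_features=mf, random_state=seed, n_jobs=1)
    forest.fit(Z, y)
    return forest, {"n_estimators": n, "min_samples_leaf": leaf, "max_features": mf}


def fit_model(kind: str, matrix, outcomes: pd.DataFrame, cv_folds: int = 5,
              grids: dict | None = None, seed: int = 0) -> RiskModel:
    """Fit one survival model on a patient-level matrix.

    ``matrix`` is a :class:`PatientFeatureMatrix` or a plain DataFrame
    indexed by patient id; ``outcomes`` carries ``time_months`` and
    ``event`` per patient.  Hyperparameters for ``cox_lasso`` and ``rsf``
    are chosen by grid search over ``grids`` with ``cv_folds``-fold
    cross-validated concordance.  Raises :class:`DegenerateDesignError` for
    rank-deficient Cox designs and unfittable splits.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    X, count_column = _as_frame(matrix)
    times, events = _outcome_arrays(outcomes, X.index)
    if events.sum() < 2:
        raise DegenerateDesignError("fewer than 2 events in training data")

    center, scale = _standardization(X, count_column)
    Z = (X.to_numpy(dtype=float) - center) / scale
    grids = grids or {}

    if kind == "cox":
        est = _fit_cox(Z, times, events, list(X.columns))
        params: dict = {}
    elif kind == "cox_lasso":
        est, params = _fit_cox_lasso(Z, times, events, grids, cv_folds, seed)
    else:
        est, params = _fit_rsf(Z, times, events, grids, cv_folds, seed)

    return RiskModel(kind=kind, feature_names=list(X.columns), center=center,
                     scale=scale, count_column=count_column, estimator=est,
                     best_params=params)


# ---------------------------------------------------------------------------
# bootstrap evaluation
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Bootstrap C-index distribution for one (aggregation, model) cell."""

    aggregation: str
    model: str
    k: int | None
    replicate_c: np.ndarray  # NaN where a replicate was degenerate
    mean_c: float            # NaN when flagged
    ci_low: float
    ci_high: float
    n_valid: int
    flag: str | None = None

    def to_row(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "k": "" if self.k is None else self.k,
            "model": self.model,
            "mean_c": self.mean_c,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_valid_replicates": self.n_valid,
            "flag": self.flag or "",
        }


def summarize_replicates(aggregation: str, model: str, k: int | None,
                         replicate_c: np.ndarray,
                         flag_reasons: list[str]) -> BenchmarkResult:
    valid = replicate_c[np.isfinite(replicate_c)]
    if len(valid) == 0:
        reason = flag_reasons[0] if flag_reasons else "degenerate"
        return BenchmarkResult(aggregation, model, k, replicate_c,
                               np.nan, np.nan, np.nan, 0, flag=reason)
    lo, hi = np.percentile(valid, [2.5, 97.5])
    flag = None
    if len(valid) < len(replicate_c):
        flag = f"partial:{flag_reasons[0]}" if flag_reasons else "partial"
    return BenchmarkResult(aggregation, model, k, replicate_c,
                           float(valid.mean()), float(lo), float(hi),
                           int(len(valid)), flag=flag)


def bootstrap_evaluate(matrix, outcomes: pd.DataFrame, kind: str,
                       n_replicates: int = 100, fraction: float = 0.5,
                       seed: int = 0, grids: dict | None = None,
                       cv_folds: int = 5, refit: bool = True,
                       select_fn: Callable | None = None) -> BenchmarkResult:
    """Repeated-subsampling evaluation of one model on one feature matrix.

    Each replicate draws ``floor(fraction * N)`` patients without replacement
    as the training set, fits the model (optionally after per-replicate
    feature selection via ``select_fn(train_matrix, train_outcomes)``), and
    scores the held-out patients with the concordance index.  With
    ``refit=False`` the model is fitted once on all patients and each
    replicate merely re-evaluates C on its subsample.  Deterministic given
    ``seed``; degenerate replicates are recorded as NaN, never raised.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    X, count_column = _as_frame(matrix)
    n = len(X)
    m = int(np.floor(fraction * n))
    label, k = ((matrix.method, matrix.k) if isinstance(matrix, PatientFeatureMatrix)
                else ("matrix", None))

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    perms = [rng.permutation(n) for _ in range(n_replicates)]

    full_model = None
    if not refit:
        full_model = fit_model(kind, matrix, outcomes, cv_folds=cv_folds,
                               grids=grids, seed=int(rep_seeds[0]))

    cs = np.full(n_replicates, np.nan)
    reasons: list[str] = []
    for r in range(n_replicates):
        train_idx, test_idx = perms[r][:m], perms[r][m:]
        try:
            if refit:
                Xtr, Xte = X.iloc[train_idx], X.iloc[test_idx]
                tr = PatientFeatureMatrix(Xtr, method=label, k=k,
                                          count_column=count_column)
                if select_fn is not None:
                    sel = select_fn(tr, outcomes)
                    tr = sel.transform(tr)
                    Xte = sel.transform(
                        PatientFeatureMatrix(Xte, method=label, k=k,
                                             count_column=count_column)).values
                model = fit_model(kind, tr, outcomes, cv_folds=cv_folds,
                                  grids=grids, seed=int(rep_seeds[r]))
                risks = model.score(Xte if isinstance(Xte, pd.DataFrame) else Xte)
                t, e = _outcome_arrays(outcomes, X.index[test_idx])
            else:
                sub = X.index[train_idx]
                risks = full_model.score(X.loc[sub])
                t, e = _outcome_arrays(outcomes, sub)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cs[r] = concordance_index(t, e, risks)
        except DegenerateDesignError as err:
            reasons.append(err.reason)
    return summarize_replicates(label, kind, k, cs, reasons)
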