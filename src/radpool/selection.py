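"""Dimensionality reduction of patient-level feature matrices.

Two reducers feed the survival models: greedy minimum-redundancy
maximum-relevance selection of the top-ranked features, and principal
component analysis retaining a stated fraction of variance.  A pass-through
mode keeps every feature.

mRMR here is censoring-aware: the relevance of a feature is |C(f) - 0.5|,
where C(f) is the concordance between the feature used as a risk score and
the censored outcome; redundancy against the already-selected set is the
mean absolute Pearson correlation.  Features are added greedily by the
difference criterion (relevance minus redundancy), ties broken by column
order, so the ranking is deterministic.  A metastasis-count covariate, when
present, bypasses selection entirely and is re-attached to the reduced
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort import PatientFeatureMatrix
from .survival import concordance_index, _outcome_arrays

SELECTION_METHODS = ("mrmr", "pca", "none")


@dataclass
class SelectionResult:
    """A fitted reducer: ranked features (mrmr) or component basis (pca)."""

    method: str
    ranked: list[tuple[str, float]] = field(default_factory=list)  # mrmr
    n_components: int = 0                                          # pca
    explained_variance_ratio: np.ndarray | None = None
    components: np.ndarray | None = None   # (n_components, n_features)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    input_columns: list[str] = field(default_factory=list)
    count_column: str | None = None
    dropped: list[str] = field(default_factory=list)  # zero-variance columns

    @property
    def selected_features(self) -> list[str]:
        return [name for name, _ in self.ranked]

    def transform(self, matrix: PatientFeatureMatrix) -> PatientFeatureMatrix:
        """Map a patient matrix onto the reduced feature space."""
        values = matrix.values
        count_col = matrix.count_column
        if self.method == "none":
            out = values.copy()
        elif self.method == "mrmr":
            cols = self.selected_features + ([count_col] if count_col else [])
            missing = [c for c in cols if c not in values.columns]
            if missing:
                raise ValueError(f"matrix lacks selected feature(s): {missing}")
            out = values[cols].copy()
        else:  # pca
            feats = [c for c in self.input_columns]
            missing = [c for c in feats if c not in values.columns]
            if missing:
                raise ValueError(f"matrix lacks schema feature(s): {missing}")
            Z = (values[feats].to_numpy(dtype=float) - self.center) / self.scale
            proj = Z @ self.components.T
            out = pd.DataFrame(proj, index=values.index,
                               columns=[f"PC{i+1}" for i in range(self.n_components)])
            if count_col:
                out[count_col] = values[count_col]
        return PatientFeatureMatrix(out, method=matrix.method, k=matrix.k,
                                    count_column=count_col,
                                    selection=self.describe())

    def describe(self) -> str:
        if self.method == "mrmr":
            return f"mrmr_top{len(self.ranked)}"
        if self.method == "pca":
            return f"pca_{self.n_components}pc"
        return "all_features"

    def report(self) -> str:
        """Human-readable summary (ranked features or retained components)."""
        lines = [f"selection_method\t{self.method}"]
        if self.dropped:
            lines.append(f"dropped_zero_variance\t{','.join(self.dropped)}")
        if self.method == "mrmr":
            lines.append("rank\tfeature\tscore")
            for i, (name, score) in enumerate(self.ranked, start=1):
                lines.append(f"{i}\t{name}\t{score:.6f}")
        elif self.method == "pca":
            lines.append(f"n_components\t{self.n_components}")
            lines.append("component\texplained_variance_ratio")
            for i, r in enumerate(self.explained_variance_ratio[:self.n_components],
                                  start=1):
                lines.append(f"PC{i}\t{r:.6f}")
        return "\n".join(lines) + "\n"


def _usable_columns(matrix: PatientFeatureMatrix) -> tuple[list[str], list[str]]:
    cols = matrix.feature_columns
    vals = matrix.values[cols].to_numpy(dtype=float)
    sd = vals.std(axis=0)
    dropped = [c for c, s in zip(cols, sd) if s == 0.0]
    if dropped:
        warnings.warn(f"excluding zero-variance column(s): {dropped}", stacklevel=3)
    return [c for c in cols if c not in dropped], dropped


def mrmr_select(matrix: PatientFeatureMatrix, outcomes: pd.DataFrame,
                n_select: int) -> SelectionResult:
    """Greedy mRMR ranking against a censored survival outcome.

    First pick maximizes relevance |C(f) - 0.5| alone; subsequent picks
    maximize relevance minus mean |Pearson r| with the selected set.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    cols, dropped = _usable_columns(matrix)
    if not cols:
        raise ValueError("no non-constant features to select from")
    if n_select > len(cols):
        warnings.warn(
            f"n_select={n_select} exceeds {len(cols)} available features; "
            "selecting all", stacklevel=2)
        n_select = len(cols)

    X = matrix.values[cols].to_numpy(dtype=float)
    times, events = _outcome_arrays(outcomes, matrix.values.index)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        relevance = np.array([
            abs(concordance_index(times, events, X[:, j]) - 0.5)
            for j in range(len(cols))])
    abs_corr = np.abs(np.corrcoef(X, rowvar=False))
    if abs_corr.ndim == 0:  # single feature
        abs_corr = np.ones((1, 1))

    selected: list[int] = []
    ranked: list[tuple[str, float]] = []
    candidates = list(range(len(cols)))
    while len(selected) < n_select:
        if selected:
            redundancy = abs_corr[np.ix_(candidates, selected)].mean(axis=1)
        else:
            redundancy = np.zeros(len(candidates))
        scores = relevance[candidates] - redundancy
        best_pos = int(np.argmax(scores))  # ties -> lowest column index
        j = candidates.pop(best_pos)
        selected.append(j)
        ranked.append((cols[j], float(scores[best_pos])))

    return SelectionResult(method="mrmr", ranked=ranked, input_columns=cols,
                           count_column=matrix.count_column, dropped=dropped)


def pca_reduce(matrix: PatientFeatureMatrix, retained_variance: float,
               ) -> SelectionResult:
    """Minimal leading principal components retaining the stated variance.

    Columns are z-scored before decomposition (correlation-matrix PCA);
    the transform projects standardized new data onto the retained basis.
    """
    if not 0.0 < retained_variance <= 1.0:
        raise ValueError("retained_variance must lie in (0, 1]")
    if len(matrix.values) < 2:
        raise ValueError("need at least 2 patients for PCA")
    cols, dropped = _usable_columns(matrix)
    if not cols:
        raise ValueError("constant matrix: nothing to decompose")

    vals = matrix.values[cols].to_numpy(dtype=float)
    center = vals.mean(axis=0)
    scale = vals.std(axis=0)
    Z = (vals - center) / scale

    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    # components with numerically-zero variance do not count toward the rank
    nonzero = ratios > 1e-12
    cum = np.cumsum(ratios[nonzero])
    n_comp = int(np.searchsorted(cum, retained_variance - 1e-9) + 1)
    n_comp = min(n_comp, int(nonzero.sum()))

    return SelectionResult(
        method="pca", n_components=n_comp,
        explained_variance_ratio=ratios,
        components=pca.components_[:n_comp],
        center=center, scale=scale, input_columns=cols,
        count_column=matrix.count_column, dropped=dropped)


def passthrough(matrix: PatientFeatureMatrix) -> SelectionResult:
    """No reduction; every feature enters the model."""
    return SelectionResult(method="none",
                           input_columns=matrix.feature_columns,
                           count_column=matrix.count_column)
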