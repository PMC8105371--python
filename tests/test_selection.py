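import numpy as np
import pandas as pd
import pytest

from radpool import PatientFeatureMatrix, concordance_index, mrmr_select, passthrough, pca_reduce


def make_matrix(values, columns, count_column=None):
    frame = pd.DataFrame(values, columns=columns,
                         index=[f"P{i:05d}" for i in range(len(values))])
    return PatientFeatureMatrix(frame, method="toy", count_column=count_column)


def make_outcomes(index, times, events=None):
    return pd.DataFrame({"patient_id": list(index),
                         "time_months": times,
                         "event": events if events is not None else [1] * len(times)})


def brute_force_mrmr(X: pd.DataFrame, times, events, n_select):
    """Independent greedy reimplementation of the difference criterion."""
    cols = list(X.columns)
    rel = {c: abs(concordance_index(times, events, X[c].to_numpy()) - 0.5)
           for c in cols}
    selected = []
    while len(selected) < n_select and len(selected) < len(cols):
        best, best_score = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            red = (np.mean([abs(np.corrcoef(X[c], X[s])[0, 1]) for s in selected])
                   if selected else 0.0)
            score = rel[c] - red
            if score > best_score:  # strict: ties keep earliest column
                best, best_score = c, score
        selected.append(best)
    return selected


class TestMrmr:
    def test_negative_time_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(1, 40, 50)
        X = rng.standard_normal((50, 4))
        X[:, 2] = -times  # perfectly concordant with hazard ordering
        m = make_matrix(X, ["a", "b", "c", "d"])
        result = mrmr_select(m, make_outcomes(m.values.index, times), 3)
        assert result.selected_features[0] == "c"

    def test_duplicate_feature_gets_maximal_redundancy_penalty(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(1, 40, 60))[::-1].copy()
        a = np.arange(60, dtype=float)
        weak = rng.standard_normal(60)
        X = np.column_stack([a, a.copy(), weak])
        m = make_matrix(X, ["a", "a_copy", "weak"])
        result = mrmr_select(m, make_outcomes(m.values.index, times), 2)
        # a_copy is redundancy-1 against {a}: the weak independent feature wins
        assert result.selected_features == ["a", "weak"]

    def test_matches_bruteforce_greedy(self):
        rng = np.random.default_rng(2)
        times = rng.uniform(1, 50, 60)
        events = rng.integers(0, 2, 60)
        events[:5] = 1
        X = pd.DataFrame(rng.standard_normal((60, 6)),
                         columns=list("abcdef"))
        X["b"] = X["a"] * 0.9 + 0.1 * rng.standard_normal(60)
        m = make_matrix(X.to_numpy(), list(X.columns))
        result = mrmr_select(m, make_outcomes(m.values.index, times, events), 6)
        oracle = brute_force_mrmr(m.values, times, events, 6)
        assert result.selected_features == oracle

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(1, 50, 80)
        X = rng.standard_normal((80, 5))
        m1 = make_matrix(X, list("abcde"))
        scaled = X * np.array([3.0, -2.0, 0.5, 10.0, 1.0]) + np.array([1, 2, 3, 4, 5])
        m2 = make_matrix(scaled, list("abcde"))
        out = make_outcomes(m1.values.index, times)
        assert (mrmr_select(m1, out, 4).selected_features
                == mrmr_select(m2, out, 4).selected_features)

    def test_overlong_request_selects_all_with_warning(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.standard_normal((30, 3)), list("abc"))
        out = make_outcomes(m.values.index, rng.uniform(1, 10, 30))
        with pytest.warns(UserWarning, match="selecting all"):
            result = mrmr_select(m, out, 10)
        assert len(result.ranked) == 3
        assert len(set(result.selected_features)) == 3

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3))
        X[:, 1] = 7.0
        m = make_matrix(X, list("abc"))
        out = make_outcomes(m.values.index, rng.uniform(1, 10, 40))
        with pytest.warns(UserWarning, match="zero-variance"):
            result = mrmr_select(m, out, 2)
        assert "b" not in result.selected_features and result.dropped == ["b"]

    def test_count_column_bypasses_selection_and_reattaches(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([rng.standard_normal((40, 3)),
                             rng.integers(1, 9, 40)])
        m = make_matrix(X, ["a", "b", "c", "n_metastases"],
                        count_column="n_metastases")
        out = make_outcomes(m.values.index, rng.uniform(1, 10, 40))
        result = mrmr_select(m, out, 2)
        reduced = result.transform(m)
        assert "n_metastases" not in result.selected_features
        assert list(reduced.values.columns)[-1] == "n_metastases"
        assert reduced.count_column == "n_metastases"


class TestPca:
    def test_rank_one_matrix_needs_one_component(self):
        rng = np.random.default_rng(7)
        latent = rng.standard_normal(30)
        X = np.outer(latent, [1.0, -2.0, 0.5])
        result = pca_reduce(make_matrix(X, list("abc")), 0.9)
        assert result.n_components == 1

    def test_full_retention_equals_matrix_rank(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 4))
        m = make_matrix(X, list("abcd"))
        result = pca_reduce(m, 1.0)
        Z = (X - X.mean(0)) / X.std(0)
        assert result.n_components == np.linalg.matrix_rank(Z)

    def test_component_count_matches_eigen_oracle(self):
        # three features with a prescribed correlation structure
        rng = np.random.default_rng(9)
        R = np.array([[1.0, 0.85, 0.1], [0.85, 1.0, 0.1], [0.1, 0.1, 1.0]])
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((4000, 3)) @ L.T
        result = pca_reduce(make_matrix(X, list("abc")), 0.9)
        # oracle: eigen-decomposition of the sample correlation matrix
        evals = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        ratios = evals / evals.sum()
        oracle = int(np.searchsorted(np.cumsum(ratios), 0.9 - 1e-9) + 1)
        assert result.n_components == oracle

    def test_ratios_non_increasing_and_threshold_met(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 6))
        result = pca_reduce(make_matrix(X, list("abcdef")), 0.8)
        r = result.explained_variance_ratio
        assert (np.diff(r) <= 1e-12).all()
        assert r[:result.n_components].sum() >= 0.8 - 1e-9

    def test_reconstruction_error_decreases_with_threshold(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 8)) @ rng.standard_normal((8, 8))
        m = make_matrix(X, [f"f{i}" for i in range(8)])
        errors = []
        for thr in (0.5, 0.8, 0.99):
            res = pca_reduce(m, thr)
            Z = (X - res.center) / res.scale
            proj = Z @ res.components.T @ res.components
            errors.append(np.linalg.norm(Z - proj))
        assert errors[0] >= errors[1] >= errors[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pca_reduce(make_matrix([[1.0, 2.0]], ["a", "b"]), 0.9)
        constant = np.full((10, 2), 3.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            with pytest.raises(ValueError, match="constant"):
                pca_reduce(make_matrix(constant, ["a", "b"]), 0.9)
        with pytest.raises(ValueError, match="retained_variance"):
            pca_reduce(make_matrix(np.eye(3), list("abc")), 0.0)


def test_passthrough_keeps_everything():
    rng = np.random.default_rng(12)
    m = make_matrix(rng.standard_normal((20, 3)), list("abc"))
    reduced = passthrough(m).transform(m)
    pd.testing.assert_frame_equal(reduced.values, m.values)
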