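import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radpool import (
    DegenerateDesignError,
    PatientFeatureMatrix,
    bootstrap_evaluate,
    concordance_index,
    fit_model,
)


def pair_enumeration_c(times, events, risks):
    """O(n^2) oracle: loop over all ordered pairs, spec tie rules."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den if den else 0.5


def make_survival_frame(n, beta=0.8, censor_frac=0.15, seed=0, p=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    lp = beta * X[:, 0]
    t = 16.0 * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1 / 1.2)
    c = rng.uniform(0, np.quantile(t, 1 - censor_frac) * 2, size=n) \
        if censor_frac > 0 else np.full(n, np.inf)
    obs = np.minimum(t, c)
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)],
                         index=[f"P{i:05d}" for i in range(n)])
    outcomes = pd.DataFrame({"patient_id": frame.index,
                             "time_months": np.maximum(obs, 1e-6),
                             "event": (t <= c).astype(int)})
    return frame, outcomes


class TestConcordance:
    def test_perfect_discrimination(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.ones(5, dtype=int)
        assert concordance_index(t, e, -t) == 1.0

    def test_all_risk_ties_give_half(self):
        t = np.array([1.0, 2, 3, 4])
        assert concordance_index(t, np.ones(4, int), np.zeros(4)) == 0.5

    def test_worked_example_matches_pair_enumeration(self):
        t = np.array([2.0, 4.0, 5.0, 7.0])
        e = np.array([1, 1, 0, 1])
        r = np.array([0.3, 0.9, 0.1, 0.4])
        assert concordance_index(t, e, r) == pair_enumeration_c(t, e, r)

    def test_tied_times_are_not_comparable(self):
        t = np.array([3.0, 3.0, 5.0])
        e = np.array([1, 1, 1])
        r = np.array([2.0, 1.0, 0.0])
        # only the two (tied, 5.0) pairs count, both concordant
        assert concordance_index(t, e, r) == 1.0

    def test_no_comparable_pairs_warns_and_returns_half(self):
        t = np.array([5.0, 5.0])
        with pytest.warns(UserWarning, match="no comparable"):
            assert concordance_index(t, np.array([1, 1]), np.array([1.0, 2.0])) == 0.5

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equally long"):
            concordance_index([1.0, 2.0], [1], [0.5])
        with pytest.raises(ValueError, match="binary"):
            concordance_index([1.0, 2.0], [1, 2], [0.5, 0.2])
        with pytest.raises(ValueError, match="finite"):
            concordance_index([1.0, 2.0], [1, 1], [np.inf, 0.2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_complement_identity_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        t = rng.uniform(1, 30, n)
        e = rng.integers(0, 2, n)
        r = rng.standard_normal(n)  # continuous: no risk ties a.s.
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            c = concordance_index(t, e, r)
            c_neg = concordance_index(t, e, -r)
            c_mono = concordance_index(t, e, np.exp(2.0 * r))
        assert c + c_neg == pytest.approx(1.0)
        assert c_mono == pytest.approx(c)

    def test_agrees_with_lifelines_when_no_ties(self):
        from lifelines.utils import concordance_index as ll_c
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 50, 80)  # continuous times: tie rule irrelevant
        e = rng.integers(0, 2, 80)
        r = rng.standard_normal(80)
        assert concordance_index(t, e, r) == pytest.approx(ll_c(t, -r, e))


class TestFitModel:
    def test_null_feature_coefficient_near_zero(self):
        X, out = make_survival_frame(2000, beta=0.0, seed=2)
        model = fit_model("cox", X, out)
        tab = model.coefficient_table()
        assert abs(tab.loc["f0", "coef"]) < 3 * tab.loc["f0", "se"]

    def test_effect_sign_matches_concordance_direction(self):
        X, out = make_survival_frame(400, beta=0.7, seed=3)
        model = fit_model("cox", X, out)
        c = concordance_index(out["time_months"], out["event"], X["f0"])
        assert np.sign(model.coefficients[0]) == np.sign(c - 0.5)

    def test_duplicate_column_flags_cox_but_not_lasso(self):
        X, out = make_survival_frame(150, beta=0.6, seed=4)
        X2 = X.copy()
        X2["f0_copy"] = X2["f0"]
        with pytest.raises(DegenerateDesignError, match="collinear"):
            fit_model("cox", X2, out)
        model = fit_model("cox_lasso", X2, out,
                          grids={"alphas": (0.01, 0.1, 1.0)}, seed=0)
        assert np.isfinite(model.score(X2)).all()

    def test_too_few_events_rejected(self):
        X, out = make_survival_frame(30, seed=5)
        out["event"] = 0
        with pytest.raises(DegenerateDesignError, match="events"):
            fit_model("cox", X, out)

    def test_score_refuses_mismatched_columns(self):
        X, out = make_survival_frame(100, seed=6, p=2)
        model = fit_model("cox", X, out)
        with pytest.raises(ValueError, match="feature mismatch"):
            model.score(X[["f1", "f0"]])  # silent reorder forbidden

    def test_rsf_fits_and_scores(self):
        X, out = make_survival_frame(120, beta=0.8, seed=7, p=3)
        model = fit_model("rsf", X, out, seed=1,
                          grids={"n_estimators": (30,), "min_samples_leaf": (5,),
                                 "max_features": ("sqrt",)})
        risks = model.score(X)
        assert risks.shape == (120,) and np.isfinite(risks).all()

    def test_misaligned_outcomes_rejected(self):
        X, out = make_survival_frame(50, seed=8)
        with pytest.raises(ValueError, match="misaligned"):
            fit_model("cox", X, out.iloc[:40])


class TestBootstrap:
    def test_fixed_seed_identical_results(self):
        X, out = make_survival_frame(120, beta=0.8, seed=9, p=2)
        pfm = PatientFeatureMatrix(X, method="m")
        a = bootstrap_evaluate(pfm, out, "cox", n_replicates=6, seed=5)
        b = bootstrap_evaluate(pfm, out, "cox", n_replicates=6, seed=5)
        np.testing.assert_array_equal(a.replicate_c, b.replicate_c)
        assert a.mean_c == b.mean_c and (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_summary_matches_percentile_oracle(self):
        X, out = make_survival_frame(150, beta=0.8, seed=10, p=2)
        res = bootstrap_evaluate(PatientFeatureMatrix(X, method="m"), out,
                                 "cox", n_replicates=12, seed=2)
        valid = res.replicate_c[np.isfinite(res.replicate_c)]
        assert res.mean_c == pytest.approx(valid.mean())
        lo, hi = np.percentile(valid, [2.5, 97.5])
        assert (res.ci_low, res.ci_high) == pytest.approx((lo, hi))
        assert res.ci_low <= res.mean_c <= res.ci_high
        assert ((res.replicate_c[np.isfinite(res.replicate_c)] >= 0).all()
                and (valid <= 1).all())

    def test_all_degenerate_is_flagged_not_raised(self):
        X, out = make_survival_frame(60, seed=11)
        X["dup"] = X["f0"]  # always rank-deficient for cox
        res = bootstrap_evaluate(PatientFeatureMatrix(X, method="m"), out,
                                 "cox", n_replicates=4, seed=3)
        assert res.flag == "collinear"
        assert res.n_valid == 0 and np.isnan(res.mean_c)

    def test_evaluate_only_mode_runs(self):
        X, out = make_survival_frame(120, beta=0.8, seed=12)
        res = bootstrap_evaluate(PatientFeatureMatrix(X, method="m"), out,
                                 "cox", n_replicates=5, seed=4, refit=False)
        assert res.n_valid == 5

    def test_oracle_risks_approach_full_cohort_c(self):
        # supply the true linear predictor as the only feature: held-out C
        # should concentrate near the C of the true risk on the full cohort
        X, out = make_survival_frame(700, beta=1.2, censor_frac=0.0, seed=13)
        res = bootstrap_evaluate(PatientFeatureMatrix(X, method="m"), out,
                                 "cox", n_replicates=20, seed=6)
        c_full = concordance_index(out["time_months"], out["event"], X["f0"])
        assert abs(res.mean_c - c_full) < 0.03

    def test_invalid_fraction_rejected(self):
        X, out = make_survival_frame(40, seed=14)
        with pytest.raises(ValueError, match="fraction"):
            bootstrap_evaluate(X, out, "cox", fraction=1.0)
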