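import math

import numpy as np
import pandas as pd
import pytest

import peaquant as pq
from peaquant.risk_models import CoxError


def brute_force_c(time, event, score, weight):
    """Literal double-loop concordance oracle."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (event[i] == 1 and time[i] < time[j]) or (
                event[i] == 1 and event[j] == 0 and time[i] == time[j]
            )
            if not comparable:
                continue
            w = weight[i] * weight[j]
            den += w
            if score[i] > score[j]:
                num += w
            elif score[i] == score[j]:
                num += 0.5 * w
    return num / den


def censored_data(seed, n=200, beta=0.5):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    lam = 0.1 * np.exp(beta * x)
    t = rng.exponential(1 / lam)
    cens = rng.uniform(0.5, 10, n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "time": np.minimum(t, cens),
        "event": (t <= cens).astype(int),
        "weight": 1.0,
        "in_subcohort": True,
        "x": x,
    })


class TestRcsBasis:
    def test_nonlinear_columns_vanish_below_first_knot(self):
        basis = pq.SplineBasis((2.0, 4.0, 6.0, 8.0))
        Z = basis.transform(np.linspace(-5, 2, 50))
        assert np.allclose(Z[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self):
        basis = pq.SplineBasis((2.0, 4.0, 6.0, 8.0))
        x = np.linspace(8.5, 20, 60)
        Z = basis.transform(x)
        for col in range(3):
            assert np.allclose(np.diff(Z[:, col], 2), 0.0, atol=1e-9)

    def test_matches_truncated_power_formula(self):
        t = np.array([1.0, 3.0, 6.0, 9.0])
        basis = pq.SplineBasis(tuple(t))
        x = np.linspace(-2, 12, 200)
        Z = basis.transform(x)

        def plus3(v):
            return np.maximum(v, 0.0) ** 3

        for j in (0, 1):
            direct = (
                plus3(x - t[j])
                - plus3(x - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
                + plus3(x - t[3]) * (t[2] - t[j]) / (t[3] - t[2])
            ) / (t[3] - t[0]) ** 2
            np.testing.assert_allclose(Z[:, j + 1], direct, rtol=1e-12)

    def test_auto_knots_at_percentiles(self):
        x = np.random.default_rng(0).normal(size=500)
        basis, Z = pq.rcs_basis(x, "auto")
        np.testing.assert_allclose(basis.knots, np.percentile(x, [5, 35, 65, 95]))
        assert Z.shape == (500, 3)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            pq.SplineBasis((1.0, 1.0, 2.0, 3.0))


class TestWeightedCox:
    def test_equal_weights_match_unweighted(self):
        df = censored_data(1)
        f1 = pq.fit_weighted_cox(df, df[["x"]])
        df2 = df.assign(weight=3.0)
        f2 = pq.fit_weighted_cox(df2, df2[["x"]])
        assert f2.coef[0] == pytest.approx(f1.coef[0], abs=1e-8)

    def test_tiny_n_matches_grid_search_oracle(self):
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "event": [1, 1, 0, 1, 1, 0, 1, 1],
            "weight": 1.0,
            "z": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        })
        fit = pq.fit_weighted_cox(df, df[["z"]])

        def pll(beta):  # oracle: literal Breslow partial likelihood
            ll = 0.0
            for i in range(len(df)):
                if df["event"][i] != 1:
                    continue
                risk = df["time"] >= df["time"][i]
                ll += beta * df["z"][i] - math.log(np.sum(np.exp(beta * df["z"][risk])))
            return ll

        grid = np.arange(-3, 3, 1e-4)
        best = grid[np.argmax([pll(b) for b in grid])]
        assert fit.coef[0] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_with_weights_and_robust_se(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 250
        df = censored_data(3, n=n)
        df["x2"] = rng.binomial(1, 0.4, n).astype(float)
        df["weight"] = rng.integers(1, 4, n).astype(float)
        fit = pq.fit_weighted_cox(df, df[["x", "x2"]])
        cph = CoxPHFitter().fit(df[["time", "event", "weight", "x", "x2"]],
                                "time", "event", weights_col="weight", robust=True)
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.robust_se, cph.standard_errors_.values, rtol=1e-4)
        assert fit.loglik_full == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_score_norm_small_at_optimum(self):
        from peaquant.risk_models import _cox_loglik_grad_hess

        df = censored_data(4).sort_values("time").reset_index(drop=True)
        fit = pq.fit_weighted_cox(df, df[["x"]])
        _, grad, _ = _cox_loglik_grad_hess(
            fit.coef, df["time"].to_numpy(), df["event"].to_numpy(int),
            df[["x"]].to_numpy(float), df["weight"].to_numpy(float))
        assert np.linalg.norm(grad) < 1e-8

    def test_lr_chisq_invariant_to_affine_rescaling(self):
        df = censored_data(5)
        f1 = pq.fit_weighted_cox(df, df[["x"]])
        df2 = df.assign(x=3.0 * df["x"] + 7.0)
        f2 = pq.fit_weighted_cox(df2, df2[["x"]])
        assert f2.lr_chisq == pytest.approx(f1.lr_chisq, rel=1e-8)

    def test_rank_deficiency_names_columns(self):
        df = censored_data(6)
        df["x_dup"] = df["x"]
        with pytest.raises(CoxError, match="rank deficient"):
            pq.fit_weighted_cox(df, df[["x", "x_dup"]])

    def test_no_events_rejected(self):
        df = censored_data(7)
        df["event"] = 0
        with pytest.raises(CoxError):
            pq.fit_weighted_cox(df, df[["x"]])


class TestHarrellsC:
    def test_hand_worked_example(self):
        assert pq.harrells_c([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 1, 2]) == 5 / 6

    def test_perfect_discrimination(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert pq.harrells_c(t, np.ones(5, int), np.arange(5.0)) == 1.0

    def test_matches_brute_force_on_random_censored_weighted(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            time = rng.integers(1, 10, n).astype(float)  # forces ties
            event = rng.integers(0, 2, n)
            score = rng.integers(0, 5, n).astype(float)  # forces score ties
            weight = rng.uniform(1, 3, n)
            if not ((event == 1) & (time < time.max())).any():
                continue
            got = pq.harrells_c(time, event, score, weight)
            want = brute_force_c(time, event, score, weight)
            assert got == pytest.approx(want, rel=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            pq.harrells_c([1.0, 2.0], [0, 0], [1.0, 2.0])


class TestHrQ3Q1:
    def test_linear_effect_closed_form(self):
        df = censored_data(8)
        fit = pq.fit_weighted_cox(df, df[["x"]])
        x = df["x"].to_numpy()
        hr, lo, hi = pq.hr_q3_vs_q1(fit, lambda v: v[:, None], x, [0])
        q1, q3 = np.percentile(x, [25, 75])
        assert hr == pytest.approx(math.exp(fit.coef[0] * (q3 - q1)), rel=1e-10)
        assert lo < hr < hi

    def test_null_effect_gives_unit_hr(self):
        df = censored_data(9)
        df["noise"] = np.random.default_rng(0).normal(size=len(df))
        fit = pq.fit_weighted_cox(df, df[["noise"]])
        hr, lo, hi = pq.hr_q3_vs_q1(fit, lambda v: v[:, None], df["noise"].to_numpy(), [0])
        assert lo < 1.0 < hi

    def test_spline_fit_on_loglinear_data_matches_closed_form(self):
        df = censored_data(10, n=600, beta=0.5)
        cohort = pq.SurvivalCohort(df)
        m = pq.fit_model(cohort, pq.ModelSpec("m", ("x",), ("x",)))
        x = df["x"].to_numpy()
        basis = m.knots["x"]
        hr, lo, hi = pq.hr_q3_vs_q1(m.fit, basis.transform, x, [0, 1, 2])
        q1, q3 = np.percentile(x, [25, 75])
        true_hr = math.exp(0.5 * (q3 - q1))
        assert lo < true_hr < hi


class TestFni:
    def test_identical_models_zero(self):
        df = censored_data(11)
        fit = pq.fit_weighted_cox(df, df[["x"]])
        assert pq.fni(fit, fit) == 0.0

    def test_null_reduced_model_one(self):
        df = censored_data(12)
        fit = pq.fit_weighted_cox(df, df[["x"]])
        assert pq.fni(None, fit) == 1.0

    def test_variable_already_present_zero(self):
        df = censored_data(13)
        fit = pq.fit_weighted_cox(df, df[["x"]])
        assert pq.fni(fit, fit) == 0.0

    def test_independent_biomarker_fni_small(self):
        vals = []
        for s in range(15):
            df = censored_data(100 + s, n=400)
            df["junk"] = np.random.default_rng(s).normal(size=len(df))
            full = pq.fit_weighted_cox(df, df[["x", "junk"]])
            red = pq.fit_weighted_cox(df, df[["x"]])
            vals.append(pq.fni(red, full))
        assert np.mean(vals) < 0.1


class TestBootstrapOptimism:
    def test_fixed_score_zero_optimism(self):
        df = censored_data(14)
        cohort = pq.SurvivalCohort(df)
        res = pq.bootstrap_optimism(cohort, None, B=50, seed=0,
                                    fixed_score=df["x"].to_numpy())
        assert res["optimism"] == 0.0
        assert res["corrected_c"] == res["apparent_c"]

    def test_overfit_model_shrinks(self):
        rng = np.random.default_rng(99)
        df = censored_data(20, n=70)
        for k in range(8):
            df[f"n{k}"] = rng.normal(size=len(df))
        cohort = pq.SurvivalCohort(df)
        spec = pq.ModelSpec("overfit", tuple(["x"] + [f"n{k}" for k in range(8)]))
        res = pq.bootstrap_optimism(cohort, spec, B=40, seed=1)
        assert res["corrected_c"] < res["apparent_c"]

    def test_seed_deterministic_and_stable_in_B(self):
        df = censored_data(21, n=150)
        cohort = pq.SurvivalCohort(df)
        spec = pq.ModelSpec("m", ("x",))
        r1 = pq.bootstrap_optimism(cohort, spec, B=60, seed=5)
        r2 = pq.bootstrap_optimism(cohort, spec, B=60, seed=5)
        r3 = pq.bootstrap_optimism(cohort, spec, B=120, seed=6)
        assert r1["corrected_c"] == r2["corrected_c"]
        assert abs(r1["corrected_c"] - r3["corrected_c"]) < 0.03


class TestCompareModels:
    def test_identical_specs_zero_difference(self):
        df = censored_data(22, n=200)
        cohort = pq.SurvivalCohort(df)
        specs = [pq.ModelSpec("a", ("x",)), pq.ModelSpec("b", ("x",))]
        per_model, pairs = pq.compare_models(cohort, specs, B_optimism=10,
                                             B_pairwise=20, seed=0, compute_fni=False)
        assert pairs["c_diff"].iloc[0] == 0.0

    def test_strong_biomarker_model_wins(self):
        rng = np.random.default_rng(30)
        n = 400
        clin = rng.normal(size=n)
        bio = rng.normal(size=n)
        lam = 0.1 * np.exp(0.2 * clin + 1.0 * bio)
        t = rng.exponential(1 / lam)
        cens = np.full(n, 8.0)
        df = pd.DataFrame({"subject_id": range(n), "time": np.minimum(t, cens),
                           "event": (t <= cens).astype(int), "weight": 1.0,
                           "in_subcohort": True, "clin": clin, "bio": bio})
        cohort = pq.SurvivalCohort(df)
        specs = [pq.ModelSpec("clinical", ("clin",)),
                 pq.ModelSpec("clinical+bio", ("clin", "bio"))]
        per_model, pairs = pq.compare_models(cohort, specs, B_optimism=10,
                                             B_pairwise=200, seed=0)
        c = per_model.set_index("model")["c_index"]
        assert c["clinical+bio"] > c["clinical"]
        row = pairs.iloc[0]
        assert row["ci_hi"] < 0 or row["ci_lo"] > 0  # CI excludes 0
        assert per_model.set_index("model").loc["clinical+bio", "fni_bio"] > 0.5

    def test_subject_order_invariant_ranking(self):
        df = censored_data(23, n=150)
        df["x2"] = np.random.default_rng(2).normal(size=len(df))
        cohort1 = pq.SurvivalCohort(df)
        cohort2 = pq.SurvivalCohort(df.iloc[::-1].reset_index(drop=True))
        specs = [pq.ModelSpec("a", ("x",)), pq.ModelSpec("b", ("x", "x2"))]
        m1, _ = pq.compare_models(cohort1, specs, B_optimism=5, B_pairwise=10,
                                  seed=0, compute_fni=False)
        m2, _ = pq.compare_models(cohort2, specs, B_optimism=5, B_pairwise=10,
                                  seed=0, compute_fni=False)
        np.testing.assert_allclose(m1["c_index"], m2["c_index"], atol=1e-12)

    def test_missing_columns_listed(self):
        df = censored_data(24)
        cohort = pq.SurvivalCohort(df)
        with pytest.raises(ValueError, match="ghost"):
            pq.compare_models(cohort, [pq.ModelSpec("bad", ("x", "ghost"))],
                              B_optimism=2, B_pairwise=2, seed=0)


class TestWeightsDerivation:
    def test_full_table_defaults_to_unit_weights(self):
        df = censored_data(25).drop(columns="weight")
        out = pq.derive_case_cohort_weights(df)
        assert (out["weight"] == 1.0).all()

    def test_inverse_sampling_fraction(self):
        df = censored_data(26).drop(columns="weight")
        n_cases = int(df["event"].sum())
        n_nc = len(df) - n_cases
        out = pq.derive_case_cohort_weights(df, n_cohort_total=len(df) + 100)
        expect = (n_nc + 100) / n_nc
        assert out.loc[out["event"] == 0, "weight"].iloc[0] == pytest.approx(expect)
        assert (out.loc[out["event"] == 1, "weight"] == 1.0).all()


def test_select_spline_covariates_prefers_nonlinear_effect():
    rng = np.random.default_rng(40)
    n = 500
    x_lin = rng.normal(size=n)
    x_nonlin = rng.uniform(-2, 2, n)
    lam = 0.1 * np.exp(0.3 * x_lin + 0.8 * x_nonlin**2)
    t = rng.exponential(1 / lam)
    df = pd.DataFrame({"subject_id": range(n), "time": np.minimum(t, 8.0),
                       "event": (t <= 8.0).astype(int), "weight": 1.0,
                       "in_subcohort": True, "x_lin": x_lin, "x_nonlin": x_nonlin})
    cohort = pq.SurvivalCohort(df)
    chosen = pq.select_spline_covariates(cohort, ("x_lin", "x_nonlin"),
                                         ("x_lin", "x_nonlin"), top_k=1)
    assert chosen == ("x_nonlin",)
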