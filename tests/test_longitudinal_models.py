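import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from keytype.longitudinal_models import (
    covariate_relevance,
    explained_variance,
    fit_hybrid_lmm,
    fit_random_intercept_lmm,
    format_scaled_effect,
    hybrid_decompose,
    prepare_visit_table,
    sd_scaled_effect,
)


def visit_rows(n_subjects=6, trials=(20.0, 22.0, 21.0, 21.0)):
    rows = []
    for i in range(n_subjects):
        for j, label in enumerate(("M0", "M3")):
            rows.append(
                {
                    "subject_id": f"S{i}",
                    "visit_label": label,
                    "visit_date": pd.Timestamp("2020-01-01") + pd.Timedelta(days=91 * j),
                    "nhpt_trial_1": trials[0],
                    "nhpt_trial_2": trials[1],
                    "nhpt_trial_3": trials[2],
                    "nhpt_trial_4": trials[3],
                    "sdmt_score": 55,
                    "age": 45.0,
                    "sex": "female",
                    "education": "high",
                }
            )
    return pd.DataFrame(rows)


class TestPrepareVisitTable:
    def test_four_trials_averaged(self):
        v = prepare_visit_table(visit_rows())
        assert v["nhpt_s"].iloc[0] == pytest.approx(21.0)

    def test_outlier_above_threshold_set_missing(self):
        v = prepare_visit_table(visit_rows(trials=(44.0, 46.0, 45.0, 45.0)))
        assert v["nhpt_s"].isna().all()
        assert v.attrs["nhpt_outliers_removed"] == len(v)

    def test_outlier_rate_accounting(self):
        raw = visit_rows(n_subjects=200).iloc[:387].copy()
        raw.loc[raw.index[:14], ["nhpt_trial_1", "nhpt_trial_2", "nhpt_trial_3",
                                 "nhpt_trial_4"]] = 45.0
        v = prepare_visit_table(raw)
        assert v.attrs["nhpt_scores_total"] == 387
        assert v.attrs["nhpt_outliers_removed"] == 14
        rate = 100 * v.attrs["nhpt_outliers_removed"] / v.attrs["nhpt_scores_total"]
        assert round(rate, 1) == 3.6

    def test_days_since_baseline(self):
        v = prepare_visit_table(visit_rows())
        assert set(v["days_since_baseline"]) == {0, 91}

    def test_incomplete_trials_missing(self):
        raw = visit_rows()
        raw.loc[raw.index[0], "nhpt_trial_4"] = np.nan
        v = prepare_visit_table(raw)
        assert np.isnan(v["nhpt_s"].iloc[0])
        assert v["nhpt_s"].notna().iloc[1:].all()


class TestHybridDecompose:
    def test_worked_example(self):
        d = pd.DataFrame({"subject_id": "S1", "x": [1.0, 2.0, 3.0]})
        out = hybrid_decompose(d, "x")
        assert (out["x_between"] == 2.0).all()
        assert list(out["x_within"]) == [-1.0, 0.0, 1.0]

    def test_single_visit_subject(self):
        d = pd.DataFrame({"subject_id": ["S1"], "x": [5.0]})
        out = hybrid_decompose(d, "x")
        assert out["x_within"].iloc[0] == 0.0

    def test_deviations_sum_to_zero(self, rng):
        d = pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i}" for i in range(20)], 5),
                "x": rng.normal(0.5, 0.2, 100),
            }
        )
        out = hybrid_decompose(d, "x")
        sums = out.groupby("subject_id")["x_within"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_subject_shift_moves_only_between_column(self, rng):
        d = pd.DataFrame(
            {"subject_id": np.repeat(["S1", "S2"], 4), "x": rng.normal(size=8)}
        )
        shifted = d.copy()
        shifted.loc[shifted["subject_id"] == "S1", "x"] += 3.5
        a, b = hybrid_decompose(d, "x"), hybrid_decompose(shifted, "x")
        assert np.allclose(a["x_within"], b["x_within"])
        assert np.allclose(
            b.loc[b.subject_id == "S1", "x_between"] - a.loc[a.subject_id == "S1", "x_between"],
            3.5,
        )


def simulate_panel(rng, n_subjects=150, n_visits=4, beta=2.0, subject_sd=1.5,
                   resid_sd=1.0, x_between_sd=1.0, x_within_sd=0.5, beta_within=None):
    subj = np.repeat(np.arange(n_subjects), n_visits)
    xb = rng.normal(0, x_between_sd, n_subjects)[subj]
    xw = rng.normal(0, x_within_sd, n_subjects * n_visits)
    x = xb + xw
    bw = beta if beta_within is None else beta_within
    u = rng.normal(0, subject_sd, n_subjects)[subj]
    y = 1.0 + beta * xb + bw * xw + u + rng.normal(0, resid_sd, len(subj))
    return pd.DataFrame(
        {"subject_id": [f"S{i}" for i in subj], "x": x, "y": y,
         "visit_label": np.tile([f"M{j}" for j in range(n_visits)], n_subjects)}
    )


class TestMixedModelFits:
    def test_matches_ols_without_heterogeneity(self, rng):
        d = simulate_panel(rng, n_subjects=400, subject_sd=0.0)
        res = fit_random_intercept_lmm(d, "y", ("x",))
        ols = sm.OLS(d["y"], sm.add_constant(d["x"])).fit()
        assert res.beta("x") == pytest.approx(ols.params["x"], abs=0.02)

    def test_intercept_only_total_variance_recovery(self, rng):
        subj = np.repeat(np.arange(200), 4)
        y = rng.normal(0, 2.0, 200)[subj] + rng.normal(0, 1.5, 800)  # total var 6.25
        d = pd.DataFrame({"subject_id": subj.astype(str), "y": y})
        res = fit_random_intercept_lmm(d, "y", ())
        assert res.total_variance == pytest.approx(6.25, rel=0.15)

    def test_hybrid_equals_overall_under_equal_effects(self, rng):
        d = simulate_panel(rng, n_subjects=600, beta=2.0)
        overall = fit_random_intercept_lmm(d, "y", ("x",))
        hybrid = fit_hybrid_lmm(d, "y", "x")
        # all three estimate the same effect; ~3 Monte-Carlo SDs of their spread
        assert hybrid.beta("x_between") == pytest.approx(overall.beta("x"), abs=0.2)
        assert hybrid.beta("x_within") == pytest.approx(overall.beta("x"), abs=0.25)

    def test_hybrid_separates_unequal_effects(self, rng):
        d = simulate_panel(rng, n_subjects=400, beta=3.0, beta_within=1.0)
        hybrid = fit_hybrid_lmm(d, "y", "x")
        assert hybrid.beta("x_between") == pytest.approx(3.0, abs=0.3)
        assert hybrid.beta("x_within") == pytest.approx(1.0, abs=0.3)

    def test_wald_ci_brackets_estimate(self, rng):
        d = simulate_panel(rng, n_subjects=100)
        res = fit_hybrid_lmm(d, "y", "x")
        lo, hi = res.ci("x_between")
        assert lo < res.beta("x_between") < hi

    def test_constant_within_predictor_drops_within_term(self, rng):
        d = simulate_panel(rng, n_subjects=50)
        d["x"] = d.groupby("subject_id")["x"].transform("mean")  # constant per subject
        res = fit_hybrid_lmm(d, "y", "x")
        assert "x_within" in res.dropped_terms
        assert "x_within" not in res.params.index

    def test_occasion_random_intercept_absorbs_practice_effect(self, rng):
        n, v = 120, 5
        subj = np.repeat(np.arange(n), v)
        occ = np.tile(np.arange(v), n)
        x = rng.normal(0, 1, n)[subj]
        y = 50 + 2.0 * x + 1.5 * occ + rng.normal(0, 1.0, n)[subj] + rng.normal(0, 2, n * v)
        d = pd.DataFrame(
            {"subject_id": subj.astype(str), "visit_label": [f"M{o}" for o in occ],
             "x": x, "y": y}
        )
        res = fit_random_intercept_lmm(d, "y", ("x",), occasion_effect=True)
        assert res.beta("x") == pytest.approx(2.0, abs=0.3)
        assert res.variance_components["occasion_var"] > 1.0

    def test_single_subject_rejected(self):
        d = pd.DataFrame({"subject_id": "S1", "y": [1.0, 2.0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(d, "y", ("x",))


class TestReportingArithmetic:
    @pytest.mark.parametrize(
        "v_model,v0,expected",
        [(8.0, 13.7, 41.6), (82.7, 110.9, 25.4), (74.4, 110.9, 32.9), (13.7, 13.7, 0.0)],
    )
    def test_explained_variance(self, v_model, v0, expected):
        assert round(explained_variance(v_model, v0), 1) == expected

    def test_explained_variance_integer_display(self):
        assert round(explained_variance(8.0, 13.7)) == 42

    def test_negative_explained_variance_allowed(self):
        assert explained_variance(15.0, 13.7) < 0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            explained_variance(1.0, 0.0)

    @pytest.mark.parametrize(
        "crude,adjusted,expected",
        [(12.62, 12.56, False), (-8.57, -5.02, True), (10.0, 9.0, True)],
    )
    def test_covariate_relevance(self, crude, adjusted, expected):
        relevant, _ = covariate_relevance(crude, adjusted)
        assert relevant is expected

    def test_covariate_relevance_zero_crude(self):
        relevant, change = covariate_relevance(0.0, 1.0)
        assert relevant and np.isnan(change)

    @pytest.mark.parametrize(
        "beta,sd,expected",
        [(15.91, 0.16, 2.5), (6.94, 0.16, 1.1), (-11.25, 0.41, -4.6),
         (-0.35, 0.41, -0.14), (123.0, 0.0, 0.0)],
    )
    def test_sd_scaled_effect(self, beta, sd, expected):
        assert format_scaled_effect(sd_scaled_effect(beta, sd)) == expected

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            sd_scaled_effect(1.0, -0.1)
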