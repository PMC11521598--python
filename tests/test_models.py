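"""Mixed models, likelihood-ratio tests, stepwise selection, post hocs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from dyadsync import models
from dyadsync.models import ModelSpec


def random_intercept_table(rng, n_groups=50, n_obs=6, tau=2.0, sigma=1.0,
                           betas=(1.0, 0.5), extra_null=0):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0.0, tau)
        for _ in range(n_obs):
            xs = rng.standard_normal(1 + extra_null)
            y = betas[0] + betas[1] * xs[0] + b + rng.normal(0.0, sigma)
            row = {"dyad": g, "x": xs[0], "y": y}
            for k in range(extra_null):
                row[f"z{k}"] = xs[1 + k]
            rows.append(row)
    return pd.DataFrame(rows)


class TestStandardize:
    def test_exact_mean_zero_sd_one(self):
        out = models.standardize_predictors(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.standard_normal(50)})
        once = models.standardize_predictors(df, ["a"])
        twice = models.standardize_predictors(once, ["a"])
        np.testing.assert_allclose(once["a"], twice["a"], atol=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.uniform(0, 10, 40), "b": rng.normal(5, 2, 40)})
        out = models.standardize_predictors(df, ["a", "b"])
        for col in ("a", "b"):
            x = df[col].to_numpy()
            np.testing.assert_allclose(out[col], (x - x.mean()) / x.std(ddof=1))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            models.standardize_predictors(pd.DataFrame({"a": [2.0, 2.0, 2.0]}), ["a"])


class TestFitLmm:
    def test_intercept_only_single_group_is_sample_mean(self):
        df = pd.DataFrame({"dyad": ["d"] * 30,
                           "y": np.random.default_rng(0).normal(4.0, 1.0, 30)})
        fit = models.fit_lmm(ModelSpec(response="y", fixed=[]), df)
        assert fit.params["Intercept"] == pytest.approx(df["y"].mean(), abs=1e-6)

    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(2)
        df = random_intercept_table(rng, n_groups=30, n_obs=4, tau=0.0)
        # remove all between-group variation so the intercept variance is
        # estimated at the boundary (exactly zero) and GLS collapses to OLS
        df["y"] -= df.groupby("dyad")["y"].transform("mean") - df["y"].mean()
        fit = models.fit_lmm(ModelSpec(response="y", fixed=["x"], estimation="ML"), df)
        assert fit.tau00 < 1e-6
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert fit.params["Intercept"] == pytest.approx(beta_ols[0], abs=1e-4)
        assert fit.params["x"] == pytest.approx(beta_ols[1], abs=1e-4)

    def test_conditional_r2_bounds_marginal(self):
        rng = np.random.default_rng(3)
        fit = models.fit_lmm(ModelSpec(response="y", fixed=["x"]),
                             random_intercept_table(rng))
        assert fit.r2_conditional >= fit.r2_marginal
        assert fit.icc == pytest.approx(fit.tau00 / (fit.tau00 + fit.sigma2))

    def test_crossed_random_intercepts_fit(self):
        rng = np.random.default_rng(4)
        rows = []
        video_effect = {0: -0.5, 1: 0.0, 2: 0.5}
        for g in range(30):
            b = rng.normal(0, 1.0)
            for v in range(3):
                rows.append({"dyad": g, "video": v,
                             "y": 1.0 + b + video_effect[v] + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        fit = models.fit_lmm(ModelSpec(response="y", fixed=[],
                                       random_intercepts=["dyad", "video"]), df)
        assert fit.converged
        assert fit.tau00 > 0.5  # dyad + video variance both contribute


class TestLrt:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(5)
        df = random_intercept_table(rng, n_groups=20, n_obs=4)
        fit = models.fit_lmm(ModelSpec(response="y", fixed=["x"], estimation="ML"), df)
        chi2, dof, p = models.likelihood_ratio_test(fit, fit)
        assert chi2 == 0.0 and dof == 0 and p == 1.0

    def test_printed_chi2_example(self):
        """chi2 = 5.82 on 4 df gives p close to 0.21."""
        p = float(sstats.chi2.sf(5.82, 4))
        assert p == pytest.approx(0.21, abs=0.005)

    def test_matches_independent_tail_computation(self):
        rng = np.random.default_rng(6)
        df = random_intercept_table(rng, n_groups=25, n_obs=4, extra_null=1)
        full = models.fit_lmm(ModelSpec(response="y", fixed=["x", "z0"],
                                        estimation="ML"), df)
        nested = models.fit_lmm(ModelSpec(response="y", fixed=["x"],
                                          estimation="ML"), df)
        chi2, dof, p = models.likelihood_ratio_test(nested, full)
        assert chi2 == pytest.approx(2.0 * (full.llf - nested.llf))
        assert dof == 1
        # independent recomputation of the chi-square upper tail
        grid = np.linspace(chi2, chi2 + 400, 400_000)
        tail = np.trapezoid(sstats.chi2.pdf(grid, dof), grid)
        assert p == pytest.approx(tail, abs=1e-4)

    def test_reml_rejected(self):
        rng = np.random.default_rng(7)
        df = random_intercept_table(rng, n_groups=20, n_obs=4)
        fit = models.fit_lmm(ModelSpec(response="y", fixed=["x"]), df)
        with pytest.raises(ValueError, match="REML"):
            models.likelihood_ratio_test(fit, fit)

    def test_noise_column_never_lowers_full_loglik(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            r = np.random.default_rng(seed)
            df = random_intercept_table(r, n_groups=20, n_obs=4, extra_null=1)
            full = models.fit_lmm(ModelSpec(response="y", fixed=["x", "z0"],
                                            estimation="ML"), df)
            nested = models.fit_lmm(ModelSpec(response="y", fixed=["x"],
                                              estimation="ML"), df)
            assert full.llf >= nested.llf - 1e-6


class TestBackwardStepwise:
    def test_all_significant_model_keeps_everything(self):
        rng = np.random.default_rng(9)
        rows = []
        for g in range(40):
            b = rng.normal(0, 0.5)
            for _ in range(4):
                x1, x2 = rng.standard_normal(2)
                rows.append({"dyad": g, "x1": x1, "x2": x2,
                             "y": 1.0 + 0.8 * x1 + 0.8 * x2 + b + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        trace = models.backward_stepwise(ModelSpec(response="y", fixed=["x1", "x2"]), df)
        assert trace.steps == []
        assert sorted(trace.final_spec.fixed) == ["x1", "x2"]

    def test_marginality_protects_main_effects(self):
        rng = np.random.default_rng(10)
        rows = []
        for g in range(40):
            b = rng.normal(0, 0.5)
            for _ in range(4):
                x = rng.standard_normal()
                a = rng.choice(["joint", "disjoint"])
                y = b + (1.0 * x if a == "joint" else 0.0) + rng.normal(0, 0.7)
                rows.append({"dyad": g, "x": x, "attention": a, "y": y})
        df = pd.DataFrame(rows)
        trace = models.backward_stepwise(
            ModelSpec(response="y", fixed=["x", "attention", "x:attention"]), df)
        final = trace.final_spec.fixed
        if "x:attention" in final:
            assert "x" in final and "attention" in final

    def test_trace_is_replayable(self):
        rng = np.random.default_rng(11)
        df = random_intercept_table(rng, n_groups=30, n_obs=4, extra_null=3)
        spec = ModelSpec(response="y", fixed=["x", "z0", "z1", "z2"])
        t1 = models.backward_stepwise(spec, df)
        t2 = models.backward_stepwise(spec, df)
        assert [s.term for s in t1.steps] == [s.term for s in t2.steps]
        assert t1.final_spec.fixed == t2.final_spec.fixed
        d = t1.to_dict()
        assert set(d) >= {"ordering", "steps", "final_fixed"}


class TestHolm:
    def test_two_value_example(self):
        np.testing.assert_allclose(models.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(models.holm_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            models.holm_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_matches_brute_force_step_down(self, pvals):
        """Step-down oracle: sort, scale by (m-i), running max, cap at 1."""
        adj = models.holm_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[idx]))
            expected[idx] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)


class TestNonparametricPosthoc:
    def test_monotone_and_inverted_spearman(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 3,
                           "c": -np.arange(10.0)})
        out = models.nonparametric_posthoc(df, [("spearman", "a", "b"),
                                                ("spearman", "a", "c")])
        assert out.loc[0, "statistic"] == pytest.approx(1.0)
        assert out.loc[1, "statistic"] == pytest.approx(-1.0)
        assert (out["p_holm"] >= out["p"] - 1e-12).all()

    def test_small_sample_matches_rank_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, 8)
        y = rng.uniform(0, 1, 8)
        df = pd.DataFrame({"x": x, "y": y})
        out = models.nonparametric_posthoc(df, [("spearman", "x", "y")], adjust=False)
        rx, ry = sstats.rankdata(x), sstats.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert out.loc[0, "statistic"] == pytest.approx(rho_oracle, abs=1e-12)

    def test_mannwhitney_matches_exhaustive_count(self):
        g1 = [1.2, 3.4, 2.2]
        g2 = [4.5, 2.9, 5.1, 3.8]
        df = pd.DataFrame({"v": g1 + g2, "grp": ["a"] * 3 + ["b"] * 4})
        out = models.nonparametric_posthoc(df, [("mannwhitney", "v", "grp")],
                                           adjust=False)
        u_oracle = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                       for a in g1 for b in g2)
        assert out.loc[0, "statistic"] == pytest.approx(u_oracle)

    def test_too_small_sample_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError):
            models.nonparametric_posthoc(df, [("spearman", "x", "y")])

    def test_shapiro_screen_runs(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"n": rng.standard_normal(50), "u": rng.uniform(0, 1, 50)})
        out = models.shapiro_normality(df, ["n", "u"])
        assert set(out["column"]) == {"n", "u"}
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
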