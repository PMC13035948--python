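"""PPML estimation, clustered inference, diagnostics and effect sizes."""

import warnings

import numpy as np
import pandas as pd
import pytest

import migsim as ms
from migsim.ppml import _poisson_loglik, clustered_vcov


def _panel_from_rows(rows, extra_cols=()):
    cols = ["origin", "destination", "year", "flow", *extra_cols]
    return ms.FlowPanel(pd.DataFrame(rows, columns=cols))


class TestFit:
    def test_binary_predictor_recovers_group_mean_ratio(self):
        """PPML with one binary regressor reproduces group means:
        beta = log(mean(x=1)/mean(x=0)), intercept = log(mean(x=0))."""
        rows = [
            ("A", "B", 2002, 8.0, 0.0),
            ("B", "A", 2002, 12.0, 0.0),
            ("A", "C", 2002, 18.0, 1.0),
            ("C", "A", 2002, 22.0, 1.0),
        ]
        panel = _panel_from_rows(rows, extra_cols=["x"])
        spec = ms.ModelSpec(predictors={"x": "none"}, fixed_effects=())
        model = ms.fit_ppml(panel, spec)
        assert model.params["x"] == pytest.approx(np.log(2.0), abs=1e-7)
        assert model.params["const"] == pytest.approx(np.log(10.0), abs=1e-7)

    def test_intercept_only_constant_flows(self):
        rows = [("A", "B", 2002, 6.0), ("B", "A", 2002, 6.0),
                ("A", "C", 2002, 6.0), ("C", "A", 2002, 6.0)]
        panel = _panel_from_rows(rows)
        model = ms.fit_ppml(panel, ms.ModelSpec(predictors={}, fixed_effects=()))
        assert model.params["const"] == pytest.approx(np.log(6.0), abs=1e-8)
        assert np.allclose(model.fitted, 6.0)

    def test_first_order_conditions_hold(self, fitted_model):
        """Score = 0 at the solution for every retained design column,
        which implies fitted totals equal observed totals."""
        X = fitted_model.design.to_numpy()
        resid = fitted_model.frame["flow"].to_numpy() - fitted_model.fitted
        score = X.T @ resid
        scale = np.abs(X).T @ fitted_model.frame["flow"].to_numpy() + 1.0
        assert np.all(np.abs(score) / scale < 1e-6)
        assert fitted_model.fitted.sum() == pytest.approx(
            fitted_model.frame["flow"].sum(), rel=1e-8
        )

    def test_collinear_predictor_dropped_with_warning(self, synth_panel):
        df = synth_panel.data.copy()
        df["dist_copy"] = df["log_distance"]
        panel = ms.FlowPanel(df, locations=synth_panel.locations)
        spec = ms.ModelSpec(
            predictors={"log_distance": "none", "dist_copy": "none"},
            fixed_effects=("origin",), clusters=()
        )
        with pytest.warns(UserWarning, match="collinear"):
            model = ms.fit_ppml(panel, spec)
        assert "dist_copy" in model.dropped_columns

    def test_nested_logliks_ordered(self, fitted_model):
        assert fitted_model.loglik >= fitted_model.loglik_fe_only
        assert fitted_model.loglik_fe_only >= fitted_model.loglik_null

    def test_zero_flows_are_retained(self, robust_spec):
        truth = ms.SyntheticTruth(seed=11, intercept=0.0)
        panel = ms.generate_panel(truth)
        assert (panel.data["flow"] == 0).any()
        model = ms.fit_ppml(panel, robust_spec)
        assert model.n_obs == len(panel.data)
        assert np.all(model.fitted > 0)

    def test_deterministic_given_input(self, synth_panel, robust_spec):
        m1 = ms.fit_ppml(synth_panel, robust_spec)
        m2 = ms.fit_ppml(synth_panel, robust_spec)
        assert (m1.params == m2.params).all()


class TestClusteredVcov:
    def test_no_clusters_equals_robust_sandwich(self, synth_panel, robust_spec):
        model = ms.fit_ppml(synth_panel, robust_spec)
        X = model.design.to_numpy()
        n, k = X.shape
        mu = model.fitted
        resid = model.frame["flow"].to_numpy() - mu
        bread = np.linalg.pinv((X * mu[:, None]).T @ X)
        s = resid[:, None] * X
        expected = (n / (n - k)) * bread @ (s.T @ s) @ bread
        assert np.allclose(model.vcov.to_numpy(), expected, atol=1e-12)

    def test_singleton_clusters_equal_robust(self):
        """One cluster dimension with every record its own cluster gives
        exactly the heteroskedasticity-robust sandwich."""
        rng = np.random.default_rng(11)
        rows = []
        for i in range(40):  # unique origin per record
            x = rng.normal()
            rows.append((f"O{i:02d}", "Z", 2002, float(rng.poisson(np.exp(1 + 0.5 * x))), x))
        panel = _panel_from_rows(rows, extra_cols=["x"])
        spec = ms.ModelSpec(predictors={"x": "none"}, fixed_effects=(), clusters=())
        model = ms.fit_ppml(panel, spec)
        V1 = clustered_vcov(model, ("origin",)).to_numpy()
        assert np.allclose(V1, model.vcov.to_numpy(), atol=1e-14)

    def test_two_way_matches_subset_enumeration(self, synth_panel, robust_spec):
        """V(o) + V(d) - V(o x d), each term from a direct per-subset oracle."""
        model = ms.fit_ppml(synth_panel, robust_spec)
        X = model.design.to_numpy()
        mu = model.fitted
        resid = model.frame["flow"].to_numpy() - mu
        bread = np.linalg.pinv((X * mu[:, None]).T @ X)
        s = resid[:, None] * X

        n, k = X.shape

        def oracle(keys):
            meat = np.zeros((k, k))
            for g in keys.unique():
                sg = s[(keys == g).to_numpy()].sum(axis=0)
                meat += np.outer(sg, sg)
            G = keys.nunique()
            return (G / (G - 1)) * ((n - 1) / (n - k)) * (bread @ meat @ bread)

        frame = model.frame
        expected = (
            oracle(frame["origin"])
            + oracle(frame["destination"])
            - oracle(frame["origin"] + "|" + frame["destination"])
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            V = clustered_vcov(model, ("origin", "destination")).to_numpy()
        # PSD repair may perturb; compare against the repaired oracle
        w, U = np.linalg.eigh(0.5 * (expected + expected.T))
        expected_psd = (U * np.clip(w, 0, None)) @ U.T
        assert np.allclose(V, expected_psd, atol=1e-10 * np.abs(V).max())

    def test_cluster_dependence_inflates_variance(self):
        """Duplicating every record within a cluster leaves the iid sandwich
        too small: clustered variances must be strictly larger."""
        rng = np.random.default_rng(5)
        rows = []
        for o in "ABCDEFGH":
            for d in "ABCDEFGH":
                if o == d:
                    continue
                x = rng.normal()
                y = float(rng.poisson(np.exp(1.0 + 0.5 * x)))
                for year in (2002, 2003):  # identical duplicate per cluster
                    rows.append((o, d, year, y, x))
        panel = _panel_from_rows(rows, extra_cols=["x"])
        spec = ms.ModelSpec(predictors={"x": "none"}, fixed_effects=(),
                            clusters=())
        model = ms.fit_ppml(panel, spec)
        robust = model.vcov.loc["x", "x"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            V = clustered_vcov(model, ("origin", "destination"))
        assert V.loc["x", "x"] > robust

    def test_single_cluster_dimension_rejected(self, synth_panel):
        spec = ms.ModelSpec(predictors={"log_distance": "none"},
                            fixed_effects=("origin",), clusters=())
        df = synth_panel.data[synth_panel.data["year"] == synth_panel.years[0]]
        model = ms.fit_ppml(ms.FlowPanel(df, locations=synth_panel.locations), spec)
        with pytest.raises(ValueError, match="single cluster"):
            clustered_vcov(model, ("year",))

    def test_vcov_symmetric_psd(self, fitted_model):
        V = fitted_model.vcov.to_numpy()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-10


class TestResetAndFitStatistics:
    def test_reset_p_in_unit_interval(self, fitted_model):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rr = ms.reset_test(fitted_model)
        assert 0.0 <= rr.p_value <= 1.0

    def test_reset_degenerate_on_constant_predictor(self):
        rows = [("A", "B", 2002, 6.0), ("B", "A", 2002, 6.0),
                ("A", "C", 2002, 6.0), ("C", "A", 2002, 6.0)]
        panel = _panel_from_rows(rows)
        model = ms.fit_ppml(panel, ms.ModelSpec(predictors={}, fixed_effects=()))
        rr = ms.reset_test(model)
        assert rr.degenerate and rr.p_value is None

    def test_reset_detects_omitted_quadratic(self):
        """Power probe: a quadratic distance term omitted from the fit is
        flagged far above the nominal rate."""
        rej = 0
        spec = ms.ModelSpec(
            predictors={"log_distance": "none", "tie": "none",
                        "log_ratio": "none"},
        )
        for r in range(30):
            truth = ms.SyntheticTruth(n_locations=10, years=(2002, 2003, 2004),
                                      seed=50_000 + r)
            truth.beta["log_distance"] = 0.0
            panel = ms.generate_panel(truth)
            df = panel.data.copy()
            rng = np.random.default_rng(60_000 + r)
            df["flow"] = rng.poisson(
                np.exp(np.log(np.maximum(df["flow"], 0.5)))
                * np.exp(0.3 * df["log_distance"] ** 2)
            ).astype(float)
            model = ms.fit_ppml(ms.FlowPanel(df, locations=panel.locations), spec)
            rr = ms.reset_test(model)
            rej += rr.p_value is not None and rr.p_value < 0.05
        assert rej / 30 > 0.3

    def test_perfect_fit_statistics(self, synth_panel, robust_spec):
        model = ms.fit_ppml(synth_panel, robust_spec)
        stats = ms.fit_statistics(model, include_reset=False)
        assert 0.0 <= stats.squared_correlation <= 1.0
        # squared correlation equals the squared Pearson correlation
        direct = np.corrcoef(model.frame["flow"], model.fitted)[0, 1] ** 2
        assert stats.squared_correlation == pytest.approx(direct, abs=1e-12)

    def test_fe_only_baseline_within_r2_zero(self, synth_panel):
        spec = ms.ModelSpec(predictors={}, fixed_effects=("origin", "destination",
                                                          "year"))
        model = ms.fit_ppml(synth_panel, spec)
        assert model.loglik_fe_only is None  # no substantive predictors
        stats = ms.fit_statistics(model, include_reset=False)
        assert stats.within_adjusted_pseudo_r2 is None

    def test_constant_fitted_degenerate_correlation_is_zero(self):
        rows = [("A", "B", 2002, 1.0), ("B", "A", 2002, 3.0),
                ("A", "C", 2002, 5.0), ("C", "A", 2002, 7.0)]
        panel = _panel_from_rows(rows)
        model = ms.fit_ppml(panel, ms.ModelSpec(predictors={}, fixed_effects=()))
        with pytest.warns(UserWarning, match="degenerate correlation"):
            stats = ms.fit_statistics(model, include_reset=False)
        assert stats.squared_correlation == 0.0

    def test_adding_predictor_never_decreases_loglik(self, synth_panel):
        base = ms.fit_ppml(
            synth_panel,
            ms.ModelSpec(predictors={"log_distance": "none"},
                         fixed_effects=("origin", "destination", "year"),
                         clusters=()),
        )
        bigger = ms.fit_ppml(
            synth_panel,
            ms.ModelSpec(predictors={"log_distance": "none", "tie": "none"},
                         fixed_effects=("origin", "destination", "year"),
                         clusters=()),
        )
        assert bigger.loglik >= base.loglik - 1e-6


class TestEffectSize:
    @pytest.mark.parametrize(
        "beta,kind,delta,expected",
        [
            (0.5117, "exponential", None, 66.8),
            (0.9911, "exponential", None, 169.4),
            (0.0, "exponential", None, 0.0),
            (0.0, "elasticity", 10.0, 0.0),
            (-0.7955, "elasticity", 10.0, -7.955),
            (0.3893, "elasticity", 10.0, 3.893),
        ],
    )
    def test_worked_examples(self, beta, kind, delta, expected):
        assert ms.effect_size(beta, kind, delta) == pytest.approx(expected, abs=0.05)

    def test_exponential_is_exact_mean_ratio(self):
        """exp(beta)-1 equals the percent difference of fitted group means
        for a 0->1 binary switch, computed directly from a toy fit."""
        rows = [
            ("A", "B", 2002, 8.0, 0.0),
            ("B", "A", 2002, 12.0, 0.0),
            ("A", "C", 2002, 18.0, 1.0),
            ("C", "A", 2002, 22.0, 1.0),
        ]
        panel = ms.FlowPanel(
            pd.DataFrame(rows, columns=["origin", "destination", "year", "flow", "x"])
        )
        model = ms.fit_ppml(panel, ms.ModelSpec(predictors={"x": "none"},
                                                fixed_effects=()))
        es = ms.effect_size(model.params["x"], "exponential")
        assert es == pytest.approx(100.0 * (20.0 / 10.0 - 1.0), abs=1e-5)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            ms.effect_size(np.inf, "exponential")
        with pytest.raises(ValueError):
            ms.effect_size(0.5, "elasticity")


class TestFittedIntervals:
    def test_interval_contains_fit_and_is_positive(self, fitted_model):
        bands = ms.fitted_intervals(fitted_model, level=0.95)
        assert (bands["lower"] > 0).all()
        assert (bands["lower"] <= bands["fitted"]).all()
        assert (bands["fitted"] <= bands["upper"]).all()

    def test_nesting_in_level(self, fitted_model):
        b90 = ms.fitted_intervals(fitted_model, level=0.90)
        b95 = ms.fitted_intervals(fitted_model, level=0.95)
        assert (b95["lower"] <= b90["lower"] + 1e-12).all()
        assert (b90["upper"] <= b95["upper"] + 1e-12).all()

    def test_level_validation(self, fitted_model):
        with pytest.raises(ValueError):
            ms.fitted_intervals(fitted_model, level=1.2)

    def test_standard_normal_quantile_width(self):
        # eta = 0, se = 1: bounds are exp(-+1.959964)
        z = 1.959963984540054
        assert ms.sigma_from_interval(0.0, 2 * z, 0.95) == pytest.approx(1.0, abs=1e-9)


def test_parameter_recovery_quick(robust_spec):
    """Short recovery probe (the full 200-replication harness runs in the
    acceptance suite): estimates center on the truth."""
    truth = ms.SyntheticTruth(seed=0)
    est = []
    for r in range(10):
        panel = ms.generate_panel(ms.SyntheticTruth(seed=100 + r))
        model = ms.fit_ppml(panel, robust_spec)
        est.append([model.params[t] for t in model.term_names])
    est = np.array(est)
    names = [robust_spec.term_name(p) for p in robust_spec.predictors]
    true = np.array([truth.beta[p] for p in robust_spec.predictors])
    bias = est.mean(axis=0) - true
    se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
    assert np.all(np.abs(bias) < 4 * se + 0.02), dict(zip(names, bias))


def test_poisson_loglik_matches_scipy():
    from scipy import stats as sps

    y = np.array([0.0, 1.0, 4.0, 7.0])
    mu = np.array([0.5, 1.2, 3.0, 9.0])
    assert _poisson_loglik(y, mu) == pytest.approx(
        sps.poisson.logpmf(y.astype(int), mu).sum(), abs=1e-10
    )
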