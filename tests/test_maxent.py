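import numpy as np
import pandas as pd
import pytest

import sdmax
from sdmax import FeatureSpec
from sdmax.maxent import kkt_slack
from sdmax.reference import fit_maxent_lbfgs


def random_instance(seed, n_bg=150, n_pres=30, n_layers=3,
                    classes=("linear", "quadratic")):
    """Small presence/background instance with a planted preference."""
    rng = np.random.default_rng(seed)
    bg_df = pd.DataFrame(
        rng.normal(size=(n_bg, n_layers)),
        columns=[f"v{i}" for i in range(n_layers)],
    )
    w = rng.normal(size=n_layers)
    logits = bg_df.to_numpy() @ w
    p = np.exp(logits - logits.max())
    p /= p.sum()
    pres_df = bg_df.iloc[rng.choice(n_bg, size=n_pres, p=p)].reset_index(drop=True)
    spec = FeatureSpec.from_background(bg_df, classes=classes)
    return spec, spec.build(pres_df), spec.build(bg_df)


class TestBuildFeatures:
    def test_min_max_scaling_and_clamping(self):
        bg = pd.DataFrame({"v": [2.0, 4.0, 6.0]})
        spec = FeatureSpec.from_background(bg, classes=("linear",))
        assert spec.build(pd.DataFrame({"v": [2.0]}))[0, 0] == 0.0
        assert spec.build(pd.DataFrame({"v": [6.0]}))[0, 0] == 1.0
        # projection values outside the training range are clamped
        assert spec.build(pd.DataFrame({"v": [100.0]}))[0, 0] == 1.0
        assert spec.build(pd.DataFrame({"v": [-100.0]}))[0, 0] == 0.0

    def test_quadratic_is_square_of_scaled(self):
        bg = pd.DataFrame({"v": [0.0, 2.0]})
        spec = FeatureSpec.from_background(bg)
        row = spec.build(pd.DataFrame({"v": [1.0]}))
        assert row.tolist() == [[0.5, 0.25]]
        assert spec.feature_names == ["v", "v^2"]
        assert spec.owners == ["v", "v"]

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            FeatureSpec.from_background(pd.DataFrame({"v": [3.0, 3.0, 3.0]}))

    def test_unsupported_class_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            FeatureSpec(["v"], classes=("hinge",), bounds={"v": (0, 1)})


class TestFitMaxent:
    def test_constant_features_give_uniform_model(self):
        # all presences and background at the same feature value: no
        # constraint can bind, so lambda stays 0 and the fit is uniform
        spec = FeatureSpec(["v"], classes=("linear",), bounds={"v": (0.0, 1.0)})
        P = np.full((10, 1), 0.5)
        B = np.full((100, 1), 0.5)
        model, trace = sdmax.fit_maxent(P, B, spec)
        assert model.lam[0] == 0.0
        p = sdmax.predict_raw(model, B)
        assert np.allclose(p, 1.0 / 100)
        assert trace.total() == 0.0

    def test_two_cell_kkt_boundary_matches_grid_search(self):
        # background {f=0, f=1}, presences all at f=1: the optimum puts
        # E[f] exactly at 1 - beta (KKT boundary); a dense grid over
        # lambda is the oracle
        spec = FeatureSpec(["v"], classes=("linear",), bounds={"v": (0.0, 1.0)})
        P = np.ones((20, 1))
        B = np.array([[0.0], [1.0]] * 25)
        beta0 = 0.5  # s_j = 0 so the floor applies: beta = 1e-4
        model, _ = sdmax.fit_maxent(P, B, spec, beta0=beta0, tol=1e-12)
        beta = model.beta[0]
        grid = np.linspace(0.0, 30.0, 2_000_001)
        from scipy.special import logsumexp
        obj = -grid + logsumexp(B * grid[None, :], axis=0) + beta * np.abs(grid)
        lam_star = grid[np.argmin(obj)]
        assert model.lam[0] == pytest.approx(lam_star, abs=2e-4)
        w = np.exp(B[:, 0] * model.lam[0])
        e_f = (w * B[:, 0]).sum() / w.sum()
        assert e_f == pytest.approx(1.0 - beta, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("classes", [("linear",), ("linear", "quadratic")])
    def test_matches_independent_convex_solver(self, seed, classes):
        spec, P, B = random_instance(seed, classes=classes)
        model, _ = sdmax.fit_maxent(P, B, spec, beta0=0.5, tol=1e-10)
        lam_ref, obj_ref = fit_maxent_lbfgs(P, B, beta=model.beta)
        assert model.objective <= obj_ref + 1e-6  # ours is never worse
        assert abs(model.objective - obj_ref) < 1e-4
        assert np.abs(model.lam - lam_ref).max() < 1e-2

    @pytest.mark.parametrize("seed", range(3))
    def test_kkt_certificate(self, seed):
        spec, P, B = random_instance(seed + 50)
        tol = 1e-8
        model, _ = sdmax.fit_maxent(P, B, spec, beta0=0.3, tol=tol)
        cert = kkt_slack(model, B)
        assert (cert["violation"] <= 10 * tol).all()
        active = cert[cert["active"]]
        assert (active["active_slack"] <= 10 * tol).all()

    def test_raw_probabilities_sum_to_one_and_entropy_bounded(self):
        spec, P, B = random_instance(7)
        model, _ = sdmax.fit_maxent(P, B, spec)
        p = sdmax.predict_raw(model, B)
        assert np.isclose(p.sum(), 1.0, atol=1e-9)
        assert model.entropy <= np.log(model.n_background) + 1e-12
        assert np.isclose(model.entropy, -(p * np.log(p)).sum(), atol=1e-9)

    def test_trace_improvements_sum_to_objective_decrease(self):
        spec, P, B = random_instance(8)
        model, trace = sdmax.fit_maxent(P, B, spec, beta0=0.5)
        from scipy.special import logsumexp
        null_obj = float(logsumexp(np.zeros(len(B))))  # lambda = 0
        assert trace.total() == pytest.approx(null_obj - model.objective, abs=1e-9)

    def test_input_validation(self):
        spec = FeatureSpec(["v"], classes=("linear",), bounds={"v": (0.0, 1.0)})
        with pytest.raises(ValueError, match="presence"):
            sdmax.fit_maxent(np.ones((2, 1)), np.ones((100, 1)), spec)
        with pytest.raises(ValueError, match="background"):
            sdmax.fit_maxent(np.ones((10, 1)), np.ones((10, 1)), spec)

    def test_nonconvergence_warns_but_returns(self):
        spec, P, B = random_instance(9)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            model, _ = sdmax.fit_maxent(P, B, spec, tol=1e-14, max_iter=1)
        assert not model.converged


class TestPredictions:
    def test_null_model_logistic_is_half_everywhere(self):
        spec = FeatureSpec(["v"], classes=("linear",), bounds={"v": (0.0, 1.0)})
        P = np.full((10, 1), 0.5)
        B = np.full((100, 1), 0.5)
        model, _ = sdmax.fit_maxent(P, B, spec)
        q = sdmax.predict_logistic(model, B)
        assert np.allclose(q, 0.5)

    def test_logistic_monotone_in_raw_and_vanishes_at_zero(self, fitted_model):
        model, B = fitted_model["model"], fitted_model["B"]
        p = sdmax.predict_raw(model, B)
        q = sdmax.predict_logistic(model, B)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= 0)
        assert ((q > 0) & (q < 1)).all()

    def test_raw_score_monotone_in_feature_under_positive_lambda(self):
        spec = FeatureSpec(["v"], classes=("linear",), bounds={"v": (0.0, 1.0)})
        P = np.ones((10, 1)) * 0.9
        B = np.linspace(0, 1, 100)[:, None]
        model, _ = sdmax.fit_maxent(P, B, spec, beta0=0.1)
        assert model.lam[0] > 0
        p = sdmax.predict_raw(model, B)
        assert np.all(np.diff(p.ravel()) > 0)

    def test_missing_layer_rejected(self, fitted_model):
        with pytest.raises(KeyError, match="env1"):
            fitted_model["model"].spec.build(pd.DataFrame({"zzz": [1.0]}))


class TestTrainingGain:
    def test_null_model_has_zero_gain(self):
        spec = FeatureSpec(["v"], classes=("linear",), bounds={"v": (0.0, 1.0)})
        P = np.full((10, 1), 0.5)
        B = np.full((100, 1), 0.5)
        model, _ = sdmax.fit_maxent(P, B, spec)
        assert sdmax.training_gain(model, P) == pytest.approx(0.0, abs=1e-12)

    def test_gain_positive_and_bounded_by_log_n(self, fitted_model):
        model, P = fitted_model["model"], fitted_model["P"]
        g = sdmax.training_gain(model, P)
        assert g > 0.0
        assert g <= np.log(model.n_background)


class TestSerialization:
    def test_yaml_roundtrip_reproduces_predictions(self, fitted_model, tmp_path):
        model, B = fitted_model["model"], fitted_model["B"]
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        loaded = sdmax.MaxEntModel.from_yaml(path)
        assert np.array_equal(loaded.lam, model.lam)
        assert np.array_equal(
            sdmax.predict_logistic(loaded, B), sdmax.predict_logistic(model, B))
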