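"""LSSVRM KKT system, closed-form leave-one-out, WOA, feature selection."""

import numpy as np
import pandas as pd
import pytest

from neurograph.cognition_prediction import (
    FeatureSet,
    WoaConfig,
    _error_metrics,
    _loo_residuals_explicit,
    fit_lssvrm,
    loo_residuals_closed_form,
    predict_lssvrm,
    predict_moca_loo,
    select_features,
    woa_a_schedule,
    woa_minimize,
)
from neurograph.group_inference import PartialCorrelationResult


def test_single_training_point_predicts_constant():
    # first KKT row forces alpha = 0, so b = y0 and f is constant
    m = fit_lssvrm(np.array([[2.0]]), np.array([5.0]), C=3.0, sigma=1.0)
    assert m.alpha[0] == pytest.approx(0.0, abs=1e-12)
    assert m.b == pytest.approx(5.0)
    assert predict_lssvrm(m, [[100.0]])[0] == pytest.approx(5.0)


def test_two_point_linear_kernel_hand_solution():
    for C in (0.5, 4.0, 1e6):
        m = fit_lssvrm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=C, kernel="linear")
        assert m.b == pytest.approx(0.0, abs=1e-9)
        assert abs(m.alpha[1]) == pytest.approx(1 / (2 + 1 / C), abs=1e-9)
        assert predict_lssvrm(m, [[0.7]])[0] == pytest.approx(2 * 0.7 / (2 + 1 / C), abs=1e-9)
    # C -> infinity recovers the generating line f(x) = x
    m = fit_lssvrm(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=1e9, kernel="linear")
    assert predict_lssvrm(m, [[0.3]])[0] == pytest.approx(0.3, abs=1e-6)


def test_constant_targets_fit_exactly():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 2))
    y = np.full(8, 7.5)
    for kernel in ("rbf", "linear"):
        m = fit_lssvrm(X, y, C=10.0, sigma=0.8, kernel=kernel)
        assert np.allclose(m.alpha, 0.0, atol=1e-9)
        assert np.allclose(predict_lssvrm(m, rng.normal(size=(4, 2))), 7.5, atol=1e-8)


def test_kkt_residual_small_on_random_fits():
    rng = np.random.default_rng(1)
    for _ in range(10):
        n = int(rng.integers(5, 30))
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        C = float(10 ** rng.uniform(-2, 3))
        sigma = float(10 ** rng.uniform(-1, 1))
        m = fit_lssvrm(X, y, C, sigma)
        K = np.exp(
            -((X[:, None, :] - X[None, :, :]) ** 2).sum(-1) / (2 * sigma**2)
        )
        M = np.zeros((n + 1, n + 1))
        M[0, 1:] = M[1:, 0] = 1.0
        M[1:, 1:] = K + np.eye(n) / C
        sol = np.concatenate([[m.b], m.alpha])
        rhs = np.concatenate([[0.0], y])
        assert np.linalg.norm(M @ sol - rhs) < 1e-8
        assert abs(m.alpha.sum()) < 1e-8  # first KKT row


def test_closed_form_loo_equals_explicit_refits():
    rng = np.random.default_rng(2)
    for i in range(20):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_lssvrm(X, y, C=float(10 ** rng.uniform(-1, 2)), sigma=float(10 ** rng.uniform(-0.5, 0.5)))
        closed = loo_residuals_closed_form(m)
        explicit = _loo_residuals_explicit(m)
        assert np.max(np.abs(closed - explicit)) < 1e-8


def test_closed_form_loo_two_point_hand_case():
    X = np.array([[0.0], [1.0]])
    y = np.array([2.0, 6.0])
    m = fit_lssvrm(X, y, C=5.0, sigma=1.0)
    res = loo_residuals_closed_form(m)
    # leaving one point out, the single-point model predicts the other's y
    assert res[0] == pytest.approx(y[0] - y[1], abs=1e-10)
    assert res[1] == pytest.approx(y[1] - y[0], abs=1e-10)


def test_duplicated_point_shrinks_loo_residual():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    m = fit_lssvrm(X, y, C=2.0, sigma=1.0)
    base_loo = abs(loo_residuals_closed_form(m)[0])
    X2 = np.vstack([X, X[0]])
    y2 = np.append(y, y[0])
    m2 = fit_lssvrm(X2, y2, C=2.0, sigma=1.0)
    dup_loo = abs(loo_residuals_closed_form(m2)[0])
    in_sample = abs(y2[0] - predict_lssvrm(m2, X[0:1])[0])
    assert dup_loo < base_loo or dup_loo == pytest.approx(in_sample, rel=0.5)


def test_woa_a_schedule_endpoints():
    assert woa_a_schedule(0, 50) == 2.0
    assert woa_a_schedule(49, 50) == 0.0


def test_woa_trace_monotone_and_bounds_respected():
    cfg = WoaConfig(population=10, iterations=30, bounds=((-5.0, 5.0), (-5.0, 5.0)), seed=4)
    best, val, trace = woa_minimize(lambda x: float(np.sum(x**2)), cfg)
    assert np.all(np.diff(trace) <= 0)
    assert np.all((best >= -5) & (best <= 5))
    assert val == pytest.approx(trace[-1])


def test_woa_seeded_reproducible_and_handles_nonfinite():
    cfg = WoaConfig(population=8, iterations=20, bounds=((-10.0, 10.0),), seed=5)

    def obj(x):
        return np.nan if abs(x[0]) < 0.001 else (x[0] - 3) ** 2

    b1 = woa_minimize(obj, cfg)
    b2 = woa_minimize(obj, cfg)
    assert np.array_equal(b1[0], b2[0]) and b1[1] == b2[1]
    assert np.isfinite(b1[1])


def test_error_metrics_hand_case():
    m = _error_metrics(np.array([20.0, 25.0]), np.array([22.0, 24.0]))
    assert m["mse"] == pytest.approx(2.5)
    assert m["rmse"] == pytest.approx(np.sqrt(2.5), abs=1e-4)
    assert m["mae"] == pytest.approx(1.5)
    assert m["mape"] == pytest.approx(100 * (2 / 20 + 1 / 25) / 2) == pytest.approx(7.0)
    perfect = _error_metrics(np.array([20.0, 25.0]), np.array([20.0, 25.0]))
    assert perfect["mse"] == perfect["mae"] == 0 and perfect["r2"] == 1.0
    assert _error_metrics(np.array([0.0, 5.0]), np.array([1.0, 4.0]))["mape"] is None


def _pcorr(metric, scope, r, p):
    return PartialCorrelationResult(metric=metric, r_partial=r, p_value=p, n=45, scope=scope)


def test_select_features_planted_globals():
    results = [
        _pcorr("gamma", "global", 0.6, 1e-5),
        _pcorr("sigma", "global", 0.55, 1e-4),
        _pcorr("Eg", "global", 0.05, 0.8),
        _pcorr("Ne:Insula_R", "nodal", 0.4, 0.001),
        _pcorr("Ne:Heschl_R", "nodal", 0.02, 0.9),
    ]
    table = pd.DataFrame(
        np.random.default_rng(0).normal(size=(10, 4)),
        columns=["gamma", "sigma", "Eg", "Ne:Insula_R"],
    )
    fs_g = select_features([_pcorr(r.metric, r.scope, r.r_partial, r.p_value) for r in results], table, mode="global_only")
    assert fs_g.names == ["gamma", "sigma"]
    fs_gn = select_features(results, table, mode="global_plus_nodal")
    assert set(fs_g.names) <= set(fs_gn.names)  # superset by construction
    assert "Ne:Insula_R" in fs_gn.names


def test_select_features_error_and_fallback():
    results = [_pcorr("gamma", "global", 0.1, 0.9), _pcorr("sigma", "global", 0.2, 0.7)]
    table = pd.DataFrame(np.zeros((5, 2)) + np.arange(5)[:, None], columns=["gamma", "sigma"])
    with pytest.raises(ValueError, match="FDR"):
        select_features(results, table, mode="global_only")
    with pytest.warns(UserWarning, match="FALLBACK"):
        fs = select_features(results, table, mode="global_only", fallback_top_k=1)
    assert fs.names == ["sigma"]  # larger |r|
    assert "FALLBACK" in fs.selection_rule


def test_null_associations_select_nothing_in_most_seeds():
    """All-null features: FDR selection empty in >= 90% of 50 seeds (n=45)."""
    from neurograph.group_inference import partial_correlation

    empty = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        feats = rng.normal(size=(45, 7))
        y = rng.normal(size=45)
        cov = rng.normal(size=(45, 3))
        results = [
            partial_correlation(feats[:, j], y, cov, metric=f"m{j}") for j in range(7)
        ]
        for r in results:
            r.scope = "global"
        table = pd.DataFrame(feats, columns=[f"m{j}" for j in range(7)])
        try:
            select_features(results, table, mode="global_only")
        except ValueError:
            empty += 1
    assert empty >= 45


def test_loo_prediction_recovers_planted_coupling():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 2))
    y = np.clip(np.rint(22 + X @ np.array([2.0, -1.5]) + rng.normal(0, 1, 30)), 0, 30)
    fs = FeatureSet(X=X, names=["f1", "f2"], mode="global_only")
    res = predict_moca_loo(fs, y, WoaConfig(population=10, iterations=20, seed=0))
    assert res.r_squared > 0.5
    assert res.rmse == pytest.approx(np.sqrt(res.mse))
    assert len(res.fold_hyperparams) == 30
    assert res.mode == "nested"


def test_single_level_mode_warns_and_runs():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 1))
    y = 20 + 3 * X[:, 0] + rng.normal(0, 0.5, 12)
    fs = FeatureSet(X=X, names=["f"], mode="global_only")
    with pytest.warns(UserWarning, match="single-level"):
        res = predict_moca_loo(
            fs, y, WoaConfig(population=8, iterations=10, seed=1), nested=False
        )
    assert res.mode == "single-level"
    assert np.isfinite(res.mse)


def test_loo_rejects_tiny_samples():
    fs = FeatureSet(X=np.zeros((3, 1)) + np.arange(3)[:, None], names=["f"], mode="global_only")
    with pytest.raises(ValueError, match="at least 5"):
        predict_moca_loo(fs, np.array([1.0, 2.0, 3.0]))
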