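"""MoCA prediction: least-squares SVR tuned by the whale optimization algorithm.

The least-squares support vector regression machine (LSSVRM) replaces the
SVR quadratic program with the equality-constrained saddle-point system

    [ 0   1^T      ] [ b     ]   [ 0 ]
    [ 1   K + I/C  ] [ alpha ] = [ y ]

with K the kernel Gram matrix (RBF exp(-||xi-xj||^2 / (2 sigma^2)) or
linear), C the regularization weight, and prediction
f(x) = sum_i alpha_i K(x, x_i) + b.  Leave-one-out residuals of this model
have a closed form, e_i = alpha_i / (M^-1)_{ii} with M the full saddle
matrix — used as a fast inner objective during hyperparameter search.

Hyperparameters (log10 C, log10 sigma) are tuned by the whale optimization
algorithm (WOA), a population metaheuristic alternating prey-encircling,
logarithmic-spiral, and random-search position updates with a linearly
decaying coefficient a: 2 -> 0.

Evaluation follows a leave-one-out protocol over patients: features are
z-scored on each training fold, hyperparameters tuned by minimizing the
fold's closed-form LOO MSE (no leakage of the held-out subject), and the
pooled predictions scored by MSE, RMSE, MAE, MAPE (%) and R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_inference import PartialCorrelationResult, bh_fdr


@dataclass
class FeatureSet:
    """Selected feature matrix plus the selection audit trail."""

    X: np.ndarray
    names: list[str]
    mode: str  # "global_only" | "global_plus_nodal"
    selection_rule: str = "FDR-significant partial correlation with MoCA"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.names):
            raise ValueError("feature matrix width does not match names")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one feature")
        if not np.isfinite(self.X).all():
            raise ValueError("features must be finite")


@dataclass
class LssvrmModel:
    kernel: str
    sigma: float
    C: float
    alpha: np.ndarray
    b: float
    X_train: np.ndarray
    y_train: np.ndarray
    _M_inv: np.ndarray | None = None


@dataclass(frozen=True)
class WoaConfig:
    population: int = 20
    iterations: int = 50
    # search box per dimension: (log10 C, log10 sigma)
    bounds: tuple = ((-3.0, 6.0), (-3.0, 3.0))
    spiral_b: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bound ({lo}, {hi})")


@dataclass
class PredictionResult:
    actual: np.ndarray
    predicted: np.ndarray
    fold_hyperparams: list[tuple[float, float]]  # (C, sigma) per fold
    mse: float
    rmse: float
    mae: float
    mape: float | None  # percent; None when an actual score is 0
    r_squared: float
    mode: str = "nested"

    def metrics_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": self.mape,
            "r_squared": self.r_squared,
        }


# ---------------------------------------------------------------------------
# kernels and the KKT linear system


def _kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: str, sigma: float) -> np.ndarray:
    if kernel == "linear":
        return A @ B.T
    if kernel == "rbf":
        d2 = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma**2))
    raise ValueError(f"unknown kernel {kernel!r}")


def fit_lssvrm(
    X: np.ndarray, y: np.ndarray, C: float, sigma: float = 1.0, kernel: str = "rbf"
) -> LssvrmModel:
    """Solve the LSSVRM saddle-point system for (b, alpha).

    The first row of the system enforces sum(alpha) = 0; the remaining rows
    are the regularized kernel interpolation conditions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one training point")
    if C <= 0:
        raise ValueError("C must be positive")
    if kernel == "rbf" and sigma <= 0:
        raise ValueError("sigma must be positive for the RBF kernel")
    K = _kernel_matrix(X, X, kernel, sigma)
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / C
    rhs = np.concatenate([[0.0], y])
    try:
        M_inv = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular KKT system (C={C:g}); a smaller C adds jitter I/C and "
            "usually restores solvability"
        ) from err
    sol = M_inv @ rhs
    return LssvrmModel(
        kernel=kernel,
        sigma=sigma,
        C=C,
        alpha=sol[1:],
        b=float(sol[0]),
        X_train=X,
        y_train=y,
        _M_inv=M_inv,
    )


def predict_lssvrm(model: LssvrmModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    K = _kernel_matrix(X_new, model.X_train, model.kernel, model.sigma)
    return K @ model.alpha + model.b


def loo_residuals_closed_form(model: LssvrmModel) -> np.ndarray:
    """PRESS-style leave-one-out residuals e_i = alpha_i / (M^-1)_{ii}.

    Equals the residual of an explicit refit without point i.  Falls back
    to explicit refits when the inverse diagonal is numerically degenerate.
    """
    n = model.alpha.size
    if model._M_inv is None:
        return _loo_residuals_explicit(model)
    diag = np.diag(model._M_inv)[1:]
    if np.any(np.abs(diag) < 1e-14) or not np.isfinite(diag).all():
        warnings.warn(
            "ill-conditioned KKT inverse; using explicit leave-one-out refits",
            stacklevel=2,
        )
        return _loo_residuals_explicit(model)
    return model.alpha / diag


def _loo_residuals_explicit(model: LssvrmModel) -> np.ndarray:
    n = model.X_train.shape[0]
    res = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sub = fit_lssvrm(
            model.X_train[keep], model.y_train[keep], model.C, model.sigma, model.kernel
        )
        res[i] = model.y_train[i] - predict_lssvrm(sub, model.X_train[i : i + 1])[0]
    return res


# ---------------------------------------------------------------------------
# whale optimization algorithm


def woa_a_schedule(iteration: int, iterations: int) -> float:
    """Linearly decaying encircling coefficient: a = 2 at the first
    iteration, 0 at the last."""
    return 2.0 - 2.0 * iteration / max(iterations - 1, 1)


def woa_minimize(objective, cfg: WoaConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize a bounded objective with the whale optimization algorithm.

    Returns (best position, best value, best-so-far trace).  The shrinking
    coefficient a decays linearly from 2 at the first iteration to 0 at the
    last; each whale either encircles the current best (|A| < 1), searches
    around a random whale (|A| >= 1), or follows a logarithmic spiral
    around the best, each dimension updated with its own random draws.
    Non-finite objective values are treated as +inf.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    dim = lo.size

    def safe_obj(x: np.ndarray) -> float:
        v = objective(x)
        return float(v) if np.isfinite(v) else np.inf

    pos = lo + rng.random((cfg.population, dim)) * (hi - lo)
    fitness = np.array([safe_obj(p) for p in pos])
    best_idx = int(np.argmin(fitness))
    best_pos = pos[best_idx].copy()
    best_val = float(fitness[best_idx])
    trace = np.empty(cfg.iterations + 1)
    trace[0] = best_val
    for t in range(cfg.iterations):
        a = woa_a_schedule(t, cfg.iterations)
        for i in range(cfg.population):
            p = rng.random()
            if p < 0.5:
                for j in range(dim):
                    r1, r2 = rng.random(), rng.random()
                    A = 2.0 * a * r1 - a
                    Cc = 2.0 * r2
                    if abs(A) < 1:
                        target = best_pos[j]
                    else:
                        target = pos[rng.integers(cfg.population), j]
                    pos[i, j] = target - A * abs(Cc * target - pos[i, j])
            else:
                el = rng.uniform(-1.0, 1.0)
                spiral = np.exp(cfg.spiral_b * el) * np.cos(2.0 * np.pi * el)
                pos[i] = np.abs(best_pos - pos[i]) * spiral + best_pos
            pos[i] = np.clip(pos[i], lo, hi)
            fitness[i] = safe_obj(pos[i])
            if fitness[i] < best_val:
                best_val = float(fitness[i])
                best_pos = pos[i].copy()
        trace[t + 1] = best_val
    return best_pos, best_val, trace


# ---------------------------------------------------------------------------
# feature selection and the leave-one-out evaluation loop


def select_features(
    results: list[PartialCorrelationResult],
    feature_table: pd.DataFrame,
    mode: str = "global_only",
    q: float = 0.05,
    fallback_top_k: int | None = None,
) -> FeatureSet:
    """Features = measures whose partial correlation with MoCA survives FDR.

    ``results`` carry metric name, scope ("global"/"nodal"), and raw p;
    FDR is applied within each scope family.  ``feature_table`` is
    patients x named measures (AUC scale).  mode "global_only" keeps
    significant global measures; "global_plus_nodal" adds significant
    nodal measures (a superset by construction).
    """
    if mode not in ("global_only", "global_plus_nodal"):
        raise ValueError(f"unknown mode {mode!r}")
    selected: list[str] = []
    for scope in ("global", "nodal"):
        fam = [r for r in results if r.scope == scope]
        if not fam:
            continue
        p_adj, flags = bh_fdr([r.p_value for r in fam], q=q)
        for r, pa, keep in zip(fam, p_adj, flags):
            r.adjusted_p = float(pa)
            if keep and (scope == "global" or mode == "global_plus_nodal"):
                selected.append(r.metric)
    rule = "FDR-significant partial correlation with MoCA"
    if not selected:
        if fallback_top_k is None:
            raise ValueError(
                "no measure passed FDR-corrected selection; pass fallback_top_k "
                "for a top-|r| fallback (non-standard: flagged in selection_rule)"
            )
        eligible = [
            r
            for r in results
            if r.scope == "global" or mode == "global_plus_nodal"
        ]
        eligible.sort(key=lambda r: -abs(r.r_partial))
        selected = [r.metric for r in eligible[:fallback_top_k]]
        rule = f"FALLBACK top-{fallback_top_k} |r| (nothing survived FDR)"
        warnings.warn(rule, stacklevel=2)
    missing = [s for s in selected if s not in feature_table.columns]
    if missing:
        raise KeyError(f"selected measures missing from feature table: {missing}")
    return FeatureSet(
        X=feature_table[selected].to_numpy(dtype=float),
        names=selected,
        mode=mode,
        selection_rule=rule,
    )


def _error_metrics(y: np.ndarray, yhat: np.ndarray) -> dict:
    err = y - yhat
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(y))) if np.all(y != 0) else None
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else np.nan
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "mae": mae, "mape": mape, "r2": r2}


def _tune_on(X: np.ndarray, y: np.ndarray, woa_cfg: WoaConfig, kernel: str) -> tuple[float, float]:
    """WOA search over (log10 C, log10 sigma) minimizing closed-form LOO MSE."""

    def objective(theta: np.ndarray) -> float:
        C = 10.0 ** theta[0]
        sigma = 10.0 ** theta[1]
        try:
            model = fit_lssvrm(X, y, C, sigma, kernel)
        except np.linalg.LinAlgError:
            return np.inf
        res = loo_residuals_closed_form(model)
        return float(np.mean(res**2))

    best, _, _ = woa_minimize(objective, woa_cfg)
    return 10.0 ** best[0], 10.0 ** best[1]


def predict_moca_loo(
    features: FeatureSet,
    y: np.ndarray,
    woa_cfg: WoaConfig | None = None,
    kernel: str = "rbf",
    nested: bool = True,
) -> PredictionResult:
    """Leave-one-out MoCA prediction with per-fold WOA-tuned LSSVRM.

    nested=True (default): hyperparameters are re-tuned on each training
    fold only, so the held-out subject never influences model selection.
    nested=False tunes once on the full data set before the LOO loop
    (single-level protocol; optimistically biased, kept for comparability).
    """
    X_all = features.X
    y = np.asarray(y, dtype=float)
    n = X_all.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for leave-one-out evaluation")
    if y.size != n:
        raise ValueError("y length does not match feature rows")
    woa_cfg = woa_cfg or WoaConfig()
    preds = np.empty(n)
    fold_hp: list[tuple[float, float]] = []
    fixed_hp: tuple[float, float] | None = None
    if not nested:
        mu, sd = X_all.mean(axis=0), X_all.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        fixed_hp = _tune_on((X_all - mu) / sd, y, woa_cfg, kernel)
        warnings.warn(
            "single-level protocol: hyperparameters tuned on the full data "
            "set; leave-one-out error is optimistically biased",
            stacklevel=2,
        )
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr = X_all[keep], y[keep]
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X_tr_z = (X_tr - mu) / sd
        x_te_z = (X_all[i] - mu) / sd
        if nested:
            fold_cfg = WoaConfig(
                population=woa_cfg.population,
                iterations=woa_cfg.iterations,
                bounds=woa_cfg.bounds,
                spiral_b=woa_cfg.spiral_b,
                seed=woa_cfg.seed + i,
            )
            C, sigma = _tune_on(X_tr_z, y_tr, fold_cfg, kernel)
        else:
            C, sigma = fixed_hp  # type: ignore[misc]
        model = fit_lssvrm(X_tr_z, y_tr, C, sigma, kernel)
        preds[i] = predict_lssvrm(model, x_te_z[None, :])[0]
        fold_hp.append((C, sigma))
    m = _error_metrics(y, preds)
    return PredictionResult(
        actual=y,
        predicted=preds,
        fold_hyperparams=fold_hp,
        mse=m["mse"],
        rmse=m["rmse"],
        mae=m["mae"],
        mape=m["mape"],
        r_squared=m["r2"],
        mode="nested" if nested else "single-level",
    )
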