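"""Group statistics: covariate-adjusted tests, FDR, partial correlation.

Network measures are compared between groups by ordinary least squares on
[intercept, group, age, sex, education]; the group coefficient's t and
two-sided p are reported (equivalent to an ANCOVA group contrast).
Multiple comparisons are controlled by Benjamini-Hochberg step-up FDR,
applied within each family (one nodal metric over 90 nodes, or the global
measures together).  Brain-behavior association uses partial correlation:
Pearson r between the residuals of metric and MoCA after regressing each
on the covariates.

Demographic summary tests mirror the usual clinical-table toolkit: pooled
two-sample t from summary statistics, 2x2 chi-square, Mann-Whitney U with
normal approximation and tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_metrics import NullEnsembleConfig, auc_trapezoid, mean_clustering, metric_curves
from .network_construction import binarize_at_sparsity, build_structural_network
from .synthetic_cohort import RegionalChannelTable


@dataclass
class AdjustedTestResult:
    metric: str
    t_statistic: float
    p_value: float
    group_means: dict
    group_sds: dict
    covariates: tuple
    adjusted_p: float | None = None


@dataclass
class PartialCorrelationResult:
    metric: str
    r_partial: float
    p_value: float
    n: int
    adjusted_p: float | None = None
    scope: str = "global"  # "global" or "nodal"


def _design_matrix(groups: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.tolist()}")
    indicator = (g == labels[-1]).astype(float)  # np.unique sorts ascending
    cols = [np.ones(g.size), indicator]
    names = ["intercept", "group"]
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype == object or str(v.dtype) == "category":
                v = pd.factorize(v)[0]
            cols.append(np.asarray(v, dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        const = [names[i] for i in range(1, X.shape[1]) if np.ptp(X[:, i]) == 0]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"constant/collinear columns: {const or 'collinear combination'}"
        )
    return X


def adjusted_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | None,
    metric: str = "metric",
) -> AdjustedTestResult:
    """Two-group comparison of a per-subject measure, adjusting for covariates.

    OLS of the measure on [intercept, group, covariates]; t and two-sided p
    for the group coefficient.  With no covariates this reduces to the
    classical two-sample t test (equal variances).
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    for lab in np.unique(g):
        if (g == lab).sum() < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 subjects")
    X = _design_matrix(g, covariates)
    fit = sm.OLS(y, X).fit()
    t_val, p_val = float(fit.tvalues[1]), float(fit.pvalues[1])
    if abs(fit.params[1]) < 1e-12:  # exactly no group effect (e.g. noise-free)
        t_val, p_val = 0.0, 1.0
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    means = {str(lab): float(y[g == lab].mean()) for lab in np.unique(g)}
    sds = {str(lab): float(y[g == lab].std(ddof=1)) for lab in np.unique(g)}
    return AdjustedTestResult(
        metric=metric,
        t_statistic=t_val,
        p_value=p_val,
        group_means=means,
        group_sds=sds,
        covariates=cov_names,
    )


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics; returns (t, p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("both SDs zero with unequal means: t is infinite")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


def chi_square_2x2(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (Yates correction off by default)."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0):
            raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation; (U, z, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie correction in the variance
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var == 0:
        return float(u1), 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(u1), float(z), float(p)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, significance flags at q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def partial_correlation(
    x, y, covariates: pd.DataFrame | np.ndarray | None, metric: str = "metric"
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates]; r is the
    Pearson correlation of the residuals and p comes from
    t = r sqrt((n - k - 2) / (1 - r^2)) on n - k - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[-1] == 0):
        Z = np.ones((x.size, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(x.size), C])
        k = C.shape[1]
    if x.size <= k + 2:
        raise ValueError(f"need n > k + 2 (= {k + 2}) observations, got {x.size}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = x.size - k - 2
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    p = 2 * stats.t.sf(abs(t), df=df)
    return PartialCorrelationResult(metric=metric, r_partial=r, p_value=float(p), n=x.size)


def _cp_auc_curve(values: np.ndarray, grid: np.ndarray) -> float:
    """Cp AUC of the covariance network of a subjects x regions matrix."""
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 0.0)
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = r[iu, ju]
    order = np.lexsort((ju, iu, -w))
    pos = order[w[order] > 0]
    n_pairs = n * (n - 1) // 2
    cps = []
    adj = np.zeros((n, n), dtype=bool)
    prev_k = 0
    for s in grid:
        k = min(int(np.floor(s * n_pairs)), pos.size)
        sel = pos[prev_k:k]
        adj[iu[sel], ju[sel]] = True
        adj[ju[sel], iu[sel]] = True
        prev_k = k
        cps.append(mean_clustering(adj))
    return float(auc_trapezoid(np.asarray(cps), grid))


def structural_group_comparison(
    table_g1: RegionalChannelTable,
    table_g2: RegionalChannelTable,
    grid: np.ndarray,
    mode: str = "threshold-wise",
    metrics: tuple = ("Cp", "Lp", "Eg", "Eloc"),
    null_cfg: NullEnsembleConfig | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare group-level structural covariance topology between two groups.

    mode "threshold-wise": for each metric, a two-sample t across the
    per-threshold values of the two group curves (the mean +/- SD across
    thresholds presentation).  mode "permutation": subject labels are
    shuffled between groups, networks and metric AUCs rebuilt, and an
    empirical two-sided p computed on the observed AUC difference
    (permutation statistic: Cp AUC per metric unless null_cfg enables
    normalized metrics; only un-normalized metrics are permuted for cost).
    """
    if table_g1.channel != table_g2.channel:
        raise ValueError("tables must come from the same channel")
    grid = np.asarray(grid, dtype=float)
    if mode == "threshold-wise":
        c1 = metric_curves(build_structural_network(table_g1), grid, null_cfg)
        c2 = metric_curves(build_structural_network(table_g2), grid, null_cfg)
        return threshold_wise_comparison(c1.global_curves, c2.global_curves, metrics)
    if mode != "permutation":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    v1 = table_g1.values.to_numpy(dtype=float)
    v2 = table_g2.values.to_numpy(dtype=float)
    pooled = np.vstack([v1, v2])
    n1 = v1.shape[0]
    obs = _cp_auc_curve(v1, grid) - _cp_auc_curve(v2, grid)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        d = _cp_auc_curve(pooled[perm[:n1]], grid) - _cp_auc_curve(pooled[perm[n1:]], grid)
        if abs(d) >= abs(obs):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return pd.DataFrame(
        [
            {
                "metric": "Cp_auc",
                "observed_difference": obs,
                "p_value": p,
                "n_permutations": n_permutations,
            }
        ]
    )


def threshold_wise_comparison(
    curves_g1: pd.DataFrame, curves_g2: pd.DataFrame, metrics: tuple
) -> pd.DataFrame:
    """Two-sample t across per-threshold values for each metric (curves input)."""
    if not curves_g1.index.equals(curves_g2.index):
        raise ValueError("sparsity grids differ between the two groups")
    rows = []
    for m in metrics:
        a = curves_g1[m].to_numpy()
        b = curves_g2[m].to_numpy()
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "metric": m,
                "mean_g1": a.mean(),
                "sd_g1": a.std(ddof=1),
                "mean_g2": b.mean(),
                "sd_g2": b.std(ddof=1),
                "t_value": float(t),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"], out["significant"] = bh_fdr(out["p_value"].to_numpy())
    return out


def nodal_group_tests(
    nodal_auc_by_subject: pd.DataFrame,
    groups: np.ndarray,
    covariates: pd.DataFrame | None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted group tests for one nodal metric's per-node AUCs.

    ``nodal_auc_by_subject`` is subjects x nodes; the FDR family is the set
    of nodes (one metric, one network kind).
    """
    rows = []
    for node in nodal_auc_by_subject.columns:
        res = adjusted_group_test(
            nodal_auc_by_subject[node].to_numpy(), groups, covariates, metric=str(node)
        )
        rows.append(
            {
                "node": node,
                "t_value": res.t_statistic,
                "p_value": res.p_value,
                **{f"mean_{k}": v for k, v in res.group_means.items()},
                **{f"sd_{k}": v for k, v in res.group_sds.items()},
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"], out["significant"] = bh_fdr(out["p_value"].to_numpy(), q=q)
    return out
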