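"""Pipeline orchestration, plain-text I/O, and run manifests.

Five stages — simulate, build-networks, metrics, stats, predict — each
write their outputs plus a JSON manifest (config echo, seed, input hashes)
into a run directory, so every file is traceable to a configuration and a
seed.  All tabular I/O is headered CSV/TSV with full-precision decimal
text; matrices round-trip exactly.  User-facing node indices are 1-based
AAL; in-memory arrays are 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cognition_prediction import (
    WoaConfig,
    predict_moca_loo,
    select_features,
)
from .graph_metrics import GLOBAL_METRICS, MetricCurve, NullEnsembleConfig, metric_curves
from .group_inference import (
    PartialCorrelationResult,
    nodal_group_tests,
    partial_correlation,
    structural_group_comparison,
    threshold_wise_comparison,
    bh_fdr,
)
from .network_construction import (
    BinaryNetwork,
    ConnectivityMatrix,
    build_functional_network,
    build_structural_network,
    sparsity_grid,
)
from .nodes import NodeTable, load_node_table
from .synthetic_cohort import (
    CHANNELS,
    GeneratorConfig,
    RegionalChannelTable,
    RoiTimeSeries,
    generate_functional_cohort,
    generate_structural_cohort,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly

STAGES = ("simulate", "build-networks", "metrics", "stats", "predict")


class MissingUpstreamError(FileNotFoundError):
    """An earlier pipeline stage has not produced its outputs yet."""

    def __init__(self, missing: Path, needed_stage: str):
        super().__init__(
            f"missing {missing}; run the {needed_stage!r} stage first"
        )
        self.needed_stage = needed_stage


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    channels: tuple = CHANNELS
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_nulls: int = 100
    swaps_per_edge: int = 10
    fdr_q: float = 0.05
    woa_population: int = 20
    woa_iterations: int = 50
    prediction_mode: str = "global_plus_nodal"  # or "global_only"
    nested_tuning: bool = True
    # top-|r| fallback size when nothing survives FDR (None = strict error)
    fallback_top_k: int | None = 2
    # functional metric stage cost scales with subjects x thresholds x nulls;
    # None = all subjects
    max_functional_subjects: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = raw.pop("generator", {})
        gen = GeneratorConfig(**gen_raw)
        cfg = cls(generator=gen, **raw)
        if "seed" not in gen_raw:  # generator inherits the pipeline seed
            cfg.generator = dataclasses.replace(gen, seed=cfg.seed)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: Path, stage: str, cfg: PipelineConfig, inputs: list[Path], outputs: list[Path]
) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / f"manifest_{stage.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# matrix / edge-list readers and writers


def write_matrix_tsv(path: str | Path, weights: np.ndarray, labels: list[str]) -> None:
    """Dense symmetric matrix as TSV with one header column per region."""
    df = pd.DataFrame(np.asarray(weights, dtype=float), columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix_tsv(
    path: str | Path, n_nodes: int = 90, atol: float = 1e-9
) -> tuple[np.ndarray, list[str]]:
    """Read a dense matrix TSV, validating shape, numeric cells and symmetry."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] != n_nodes:
        raise ValueError(f"{path}: expected {n_nodes} columns, found {df.shape[1]}")
    if df.shape[0] != n_nodes:
        raise ValueError(f"{path}: expected {n_nodes} rows, found {df.shape[0]}")
    try:
        w = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        bad = df.columns[df.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
        raise ValueError(f"{path}: non-numeric cells in columns {list(bad)}") from err
    if not np.allclose(w, w.T, atol=atol):
        i, j = np.unravel_index(np.argmax(np.abs(w - w.T)), w.shape)
        raise ValueError(
            f"{path}: matrix asymmetric beyond {atol} (worst at row {i + 1}, col {j + 1})"
        )
    return w, list(df.columns)


def write_edge_list(
    path: str | Path, cm_or_net: ConnectivityMatrix | BinaryNetwork
) -> None:
    """Edge list (node_i, node_j, weight) with 1-based AAL indices."""
    if isinstance(cm_or_net, BinaryNetwork):
        w = cm_or_net.adjacency.astype(float)
    else:
        w = cm_or_net.weights
    iu, ju = np.triu_indices(w.shape[0], k=1)
    sel = w[iu, ju] != 0
    df = pd.DataFrame(
        {"node_i": iu[sel] + 1, "node_j": ju[sel] + 1, "weight": w[iu, ju][sel]}
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list_binary(path: str | Path, n_nodes: int = 90, sparsity: float | None = None) -> BinaryNetwork:
    """Edge list -> BinaryNetwork (every listed pair becomes an edge)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("node_i", "node_j"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    i = df["node_i"].to_numpy(dtype=int) - 1
    j = df["node_j"].to_numpy(dtype=int) - 1
    if np.any((i < 0) | (i >= n_nodes) | (j < 0) | (j >= n_nodes)):
        raise ValueError(f"{path}: node index outside 1..{n_nodes}")
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[i, j] = True
    adj |= adj.T
    n_pairs = n_nodes * (n_nodes - 1) // 2
    s = sparsity if sparsity is not None else adj.sum() / 2 / n_pairs
    return BinaryNetwork(adjacency=adj, sparsity=float(s))


def write_timeseries_tsv(path: str | Path, ts: RoiTimeSeries, labels: list[str]) -> None:
    pd.DataFrame(ts.series, columns=labels).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_timeseries_tsv(path: str | Path, subject_id: str, sampling_interval: float = 2.0) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] != 90:
        raise ValueError(f"{path}: expected 90 region columns, found {df.shape[1]}")
    return RoiTimeSeries(
        subject_id=subject_id,
        series=df.to_numpy(dtype=float),
        sampling_interval=sampling_interval,
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
    nodes = load_node_table()
    outputs: list[Path] = []
    tables = generate_structural_cohort(gen)
    chan_dir = outdir / "channels"
    chan_dir.mkdir(exist_ok=True)
    for (channel, group), table in tables.items():
        p = chan_dir / f"{channel}_{group}.csv"
        table.values.to_csv(p, float_format=FLOAT_FMT)
        outputs.append(p)
    series, subjects = generate_functional_cohort(gen)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in series:
        p = ts_dir / f"{ts.subject_id}.tsv"
        write_timeseries_tsv(p, ts, nodes.names)
        outputs.append(p)
    subj_path = outdir / "subjects.csv"
    subjects.to_csv(subj_path, index=False)
    outputs.append(subj_path)
    outputs.append(write_manifest(outdir, "simulate", cfg, [], outputs))
    return outputs


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingUpstreamError(path, stage)
    return path


def stage_build_networks(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    nodes = load_node_table()
    net_dir = outdir / "networks"
    net_dir.mkdir(parents=True, exist_ok=True)
    inputs, outputs = [], []
    for channel in cfg.channels:
        for group in ("patient", "control"):
            src = _require(outdir / "channels" / f"{channel}_{group}.csv", "simulate")
            inputs.append(src)
            values = pd.read_csv(src, index_col=0)
            table = RegionalChannelTable(channel=channel, group=group, values=values)
            cm = build_structural_network(table)
            p = net_dir / f"structural_{channel}_{group}.tsv"
            write_matrix_tsv(p, cm.weights, cm.node_labels)
            outputs.append(p)
            pe = net_dir / f"structural_{channel}_{group}_edges.tsv"
            write_edge_list(pe, cm)
            outputs.append(pe)
    subj_path = _require(outdir / "subjects.csv", "simulate")
    inputs.append(subj_path)
    subjects = pd.read_csv(subj_path)
    for sid in subjects["subject_id"]:
        src = _require(outdir / "timeseries" / f"{sid}.tsv", "simulate")
        ts = read_timeseries_tsv(src, sid)
        cm = build_functional_network(ts, nodes.names, apply_fisher=True)
        p = net_dir / f"functional_{sid}.tsv"
        write_matrix_tsv(p, cm.weights, cm.node_labels)
        outputs.append(p)
    outputs.append(write_manifest(outdir, "build-networks", cfg, inputs, outputs))
    return outputs


def _null_cfg(cfg: PipelineConfig, offset: int = 0) -> NullEnsembleConfig:
    return NullEnsembleConfig(
        n_nulls=cfg.n_nulls, swaps_per_edge=cfg.swaps_per_edge, seed=cfg.seed + offset
    )


def _curve_records(curve: MetricCurve, entity_id: str, kind: str):
    long_rows = []
    for metric in curve.global_curves.columns:
        for thr, val in curve.global_curves[metric].items():
            long_rows.append(
                {
                    "entity_id": entity_id,
                    "kind": kind,
                    "metric": metric,
                    "threshold": thr,
                    "value": val,
                }
            )
    auc_rows = [
        {"entity_id": entity_id, "kind": kind, "scope": "global", "metric": m, "node": "", "auc": v}
        for m, v in curve.auc.items()
    ]
    for metric, vec in curve.nodal_auc.items():
        for node_idx, v in enumerate(vec):
            auc_rows.append(
                {
                    "entity_id": entity_id,
                    "kind": kind,
                    "scope": "nodal",
                    "metric": metric,
                    "node": node_idx + 1,
                    "auc": v,
                }
            )
    return long_rows, auc_rows


def stage_metrics(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    nodes = load_node_table()
    met_dir = outdir / "metrics"
    met_dir.mkdir(parents=True, exist_ok=True)
    inputs, long_rows, auc_rows = [], [], []
    s_grid = sparsity_grid("structural_group")
    f_grid = sparsity_grid("functional_subject")
    for channel in cfg.channels:
        for group in ("patient", "control"):
            src = _require(
                outdir / "networks" / f"structural_{channel}_{group}.tsv", "build-networks"
            )
            inputs.append(src)
            w, labels = read_matrix_tsv(src)
            cm = ConnectivityMatrix(
                weights=w, node_labels=labels, kind="structural_group", channel=channel,
                entity_id=group,
            )
            curve = metric_curves(cm, s_grid, _null_cfg(cfg))
            lr, ar = _curve_records(curve, f"{channel}:{group}", "structural_group")
            long_rows += lr
            auc_rows += ar
    subjects = pd.read_csv(_require(outdir / "subjects.csv", "simulate"))
    if cfg.max_functional_subjects is not None:
        # stratified head: half the budget from each group
        k = cfg.max_functional_subjects
        parts = [
            subjects.loc[subjects["group"] == g, "subject_id"].head(k - k // 2 if g == "patient" else k // 2)
            for g in ("patient", "control")
        ]
        sids = pd.concat(parts).tolist()
    else:
        sids = subjects["subject_id"].tolist()
    for sid in sids:
        src = _require(outdir / "networks" / f"functional_{sid}.tsv", "build-networks")
        w, labels = read_matrix_tsv(src)
        cm = ConnectivityMatrix(
            weights=w, node_labels=labels, kind="functional_subject", entity_id=sid,
            fisher_z=True,
        )
        curve = metric_curves(cm, f_grid, _null_cfg(cfg))
        lr, ar = _curve_records(curve, sid, "functional_subject")
        long_rows += lr
        auc_rows += ar
    p_long = met_dir / "curves_long.csv"
    pd.DataFrame(long_rows).to_csv(p_long, index=False, float_format=FLOAT_FMT)
    p_auc = met_dir / "auc.csv"
    pd.DataFrame(auc_rows).to_csv(p_auc, index=False, float_format=FLOAT_FMT)
    outputs = [p_long, p_auc]
    outputs.append(write_manifest(outdir, "metrics", cfg, inputs, outputs))
    return outputs


def _functional_auc_tables(outdir: Path) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """(global AUC wide table, nodal AUC wide tables, subjects) for functional nets."""
    auc_path = _require(outdir / "metrics" / "auc.csv", "metrics")
    subjects = pd.read_csv(_require(outdir / "subjects.csv", "simulate"))
    auc = pd.read_csv(auc_path)
    func = auc[auc["kind"] == "functional_subject"]
    glob = (
        func[func["scope"] == "global"]
        .pivot(index="entity_id", columns="metric", values="auc")
    )
    nodal = {}
    for metric in func.loc[func["scope"] == "nodal", "metric"].unique():
        sub = func[(func["scope"] == "nodal") & (func["metric"] == metric)]
        nodal[metric] = sub.pivot(index="entity_id", columns="node", values="auc")
    subjects = subjects[subjects["subject_id"].isin(glob.index)].set_index("subject_id")
    glob = glob.loc[subjects.index]
    nodal = {m: t.loc[subjects.index] for m, t in nodal.items()}
    return glob, nodal, subjects.reset_index()


def _covariates(subjects: pd.DataFrame) -> pd.DataFrame:
    cov = subjects[["age", "sex", "education"]].copy()
    cov["sex"] = (cov["sex"] == "M").astype(float)
    return cov


def stage_stats(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    stats_dir = outdir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    # structural: threshold-wise comparison per channel from stored curves
    curves = pd.read_csv(_require(outdir / "metrics" / "curves_long.csv", "metrics"))
    struct = curves[curves["kind"] == "structural_group"]
    rows = []
    for channel in cfg.channels:
        per_group = {}
        for group in ("patient", "control"):
            sub = struct[struct["entity_id"] == f"{channel}:{group}"]
            per_group[group] = sub.pivot(index="threshold", columns="metric", values="value")
        avail = [m for m in GLOBAL_METRICS if m in per_group["patient"].columns]
        cmp_df = threshold_wise_comparison(
            per_group["patient"], per_group["control"], tuple(avail)
        )
        cmp_df.insert(0, "channel", channel)
        rows.append(cmp_df)
    p_struct = stats_dir / "structural_comparison.csv"
    pd.concat(rows, ignore_index=True).to_csv(p_struct, index=False)
    outputs.append(p_struct)
    # functional: covariate-adjusted group tests on AUCs
    glob, nodal, subjects = _functional_auc_tables(outdir)
    groups = subjects["group"].to_numpy()
    cov = _covariates(subjects)
    from .group_inference import adjusted_group_test

    grows = []
    for metric in glob.columns:
        if metric == "connected_fraction":
            continue
        res = adjusted_group_test(glob[metric].to_numpy(), groups, cov, metric=metric)
        grows.append(
            {
                "metric": metric,
                "t_value": res.t_statistic,
                "p_value": res.p_value,
                **{f"mean_{k}": v for k, v in res.group_means.items()},
            }
        )
    gdf = pd.DataFrame(grows)
    gdf["adjusted_p"], gdf["significant"] = bh_fdr(gdf["p_value"].to_numpy(), q=cfg.fdr_q)
    p_glob = stats_dir / "functional_global_tests.csv"
    gdf.to_csv(p_glob, index=False)
    outputs.append(p_glob)
    for metric, table in nodal.items():
        ndf = nodal_group_tests(table, groups, cov, q=cfg.fdr_q)
        p_nodal = stats_dir / f"functional_nodal_{metric}_tests.csv"
        ndf.to_csv(p_nodal, index=False)
        outputs.append(p_nodal)
    # partial correlations with MoCA in patients
    pat = subjects["group"].to_numpy() == "patient"
    moca = subjects.loc[pat, "moca"].to_numpy(dtype=float)
    cov_p = cov[pat]
    prows = []
    for metric in glob.columns:
        if metric == "connected_fraction":
            continue
        r = partial_correlation(
            glob[metric].to_numpy()[pat], moca, cov_p, metric=metric
        )
        prows.append({"scope": "global", "metric": metric, "r": r.r_partial, "p": r.p_value})
    node_table = load_node_table()
    for metric, table in nodal.items():
        for node in table.columns:
            r = partial_correlation(table[node].to_numpy()[pat], moca, cov_p)
            prows.append(
                {
                    "scope": "nodal",
                    "metric": f"{metric}:{node_table.name_of(int(node))}",
                    "r": r.r_partial,
                    "p": r.p_value,
                }
            )
    pdf = pd.DataFrame(prows)
    adj = np.full(len(pdf), np.nan)
    sig = np.zeros(len(pdf), dtype=bool)
    for scope in ("global", "nodal"):
        m = (pdf["scope"] == scope).to_numpy()
        if m.any():
            adj[m], sig[m] = bh_fdr(pdf.loc[m, "p"].to_numpy(), q=cfg.fdr_q)
    pdf["adjusted_p"], pdf["significant"] = adj, sig
    p_pc = stats_dir / "moca_partial_correlations.csv"
    pdf.to_csv(p_pc, index=False)
    outputs.append(p_pc)
    outputs.append(write_manifest(outdir, "stats", cfg, [], outputs))
    return outputs


def stage_predict(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    pred_dir = outdir / "predict"
    pred_dir.mkdir(parents=True, exist_ok=True)
    pc_path = _require(outdir / "stats" / "moca_partial_correlations.csv", "stats")
    pdf = pd.read_csv(pc_path)
    glob, nodal, subjects = _functional_auc_tables(outdir)
    node_table = load_node_table()
    pat = subjects["group"].to_numpy() == "patient"
    feature_table = glob.loc[glob.index[pat]].copy()
    for metric, table in nodal.items():
        for node in table.columns:
            feature_table[f"{metric}:{node_table.name_of(int(node))}"] = table[node].loc[
                feature_table.index
            ]
    results = [
        PartialCorrelationResult(
            metric=row.metric, r_partial=row.r, p_value=row.p, n=int(pat.sum()),
            scope=row.scope,
        )
        for row in pdf.itertuples(index=False)
    ]
    moca = subjects.loc[pat, "moca"].to_numpy(dtype=float)
    fs = select_features(
        results,
        feature_table,
        mode=cfg.prediction_mode,
        q=cfg.fdr_q,
        fallback_top_k=cfg.fallback_top_k,
    )
    woa = WoaConfig(
        population=cfg.woa_population, iterations=cfg.woa_iterations, seed=cfg.seed
    )
    result = predict_moca_loo(fs, moca, woa, nested=cfg.nested_tuning)
    preds = pd.DataFrame(
        {
            "subject_id": feature_table.index,
            "actual": result.actual,
            "predicted": result.predicted,
            "fold_C": [hp[0] for hp in result.fold_hyperparams],
            "fold_sigma": [hp[1] for hp in result.fold_hyperparams],
        }
    )
    p_pred = pred_dir / "predictions.csv"
    preds.to_csv(p_pred, index=False, float_format=FLOAT_FMT)
    p_met = pred_dir / "prediction_metrics.json"
    p_met.write_text(
        json.dumps(
            {
                "features": fs.names,
                "selection_rule": fs.selection_rule,
                "mode": cfg.prediction_mode,
                "tuning": result.mode,
                "seed": cfg.seed,
                **result.metrics_dict(),
            },
            indent=2,
        )
    )
    outputs = [p_pred, p_met]
    outputs.append(write_manifest(outdir, "predict", cfg, [pc_path], outputs))
    return outputs


def run_pipeline(cfg: PipelineConfig, stages: tuple = STAGES) -> Path:
    """Run the requested stages in order into cfg.outdir; returns the run dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "simulate": stage_simulate,
        "build-networks": stage_build_networks,
        "metrics": stage_metrics,
        "stats": stage_stats,
        "predict": stage_predict,
    }
    for stage in stages:
        if stage not in stage_fns:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        logger.info("running stage %s", stage)
        stage_fns[stage](cfg, outdir)
    return outdir


__all__ = [
    "PipelineConfig",
    "NodeTable",
    "load_node_table",
    "run_pipeline",
    "stage_simulate",
    "stage_build_networks",
    "stage_metrics",
    "stage_stats",
    "stage_predict",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list",
    "read_edge_list_binary",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "MissingUpstreamError",
]
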