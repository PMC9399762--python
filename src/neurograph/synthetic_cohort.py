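"""Synthetic cohorts with the statistical structure the network analysis assumes.

Two measurement streams are emulated for a patient group and a healthy
control group:

* regional diffusion-kurtosis values (channels MK/AK/RK/KA) drawn, per
  group, from a multivariate normal whose correlation matrix is block
  modular — ``within_module_r`` inside each community, ``between_module_r``
  elsewhere.  The patient group uses an attenuated within-module
  correlation, so its group-level structural covariance network has lower
  clustering than the control network.
* BOLD-like regional time series from a one-factor-per-module model:
  each region loads on its module's latent time course plus independent
  noise, giving an analytic within-module correlation
  loading^2 / (loading^2 + noise_var).  Patient loadings are attenuated.

MoCA scores are an affine function of planted features plus Gaussian noise,
rounded and clipped to the 0-30 scale, with group intercepts placed on the
two sides of the clinical cutoff (<26 impaired).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nodes import N_REGIONS, load_node_table

logger = logging.getLogger(__name__)

CHANNELS = ("MK", "AK", "RK", "KA")

#: per-channel (mean, SD) of regional kurtosis values; dimensionless
CHANNEL_LEVELS = {
    "MK": (0.94, 0.10),
    "AK": (0.71, 0.08),
    "RK": (1.12, 0.14),
    "KA": (0.34, 0.05),
}

GROUPS = ("patient", "control")


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults mirror the study conditions: 45 patients vs 37 controls,
    90 AAL regions, 230 retained fMRI timepoints, ages 30-65."""

    n_patients: int = 45
    n_controls: int = 37
    n_regions: int = N_REGIONS
    n_modules: int = 5
    # structural covariance targets per group; patients attenuated
    within_module_r: dict = field(
        default_factory=lambda: {"control": 0.6, "patient": 0.3}
    )
    between_module_r: float = 0.1
    # functional factor model
    n_timepoints: int = 230
    sampling_interval: float = 2.0  # seconds (TR)
    factor_loading: float = 0.7
    noise_sd: float = 1.0
    patient_loading_attenuation: float = 0.7
    affected_modules: tuple | None = None  # None -> all modules attenuated
    # MoCA generation
    moca_effect: tuple = ()
    moca_noise_sd: float = 1.0
    moca_intercept: dict = field(
        default_factory=lambda: {"patient": 22.0, "control": 27.5}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 3 or self.n_controls < 3:
            raise ValueError("need at least 3 subjects per group")
        if not (1 <= self.n_modules <= self.n_regions):
            raise ValueError("n_modules must be in [1, n_regions]")
        for g, r in self.within_module_r.items():
            if abs(r) >= 1:
                raise ValueError(f"|within_module_r[{g}]| must be < 1, got {r}")
        if abs(self.between_module_r) >= 1:
            raise ValueError("|between_module_r| must be < 1")
        if self.n_timepoints < 30:
            raise ValueError(f"n_timepoints must be >= 30, got {self.n_timepoints}")
        if self.noise_sd < 0 or self.moca_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class RegionalChannelTable:
    """Subjects x 90 regional kurtosis values for one DKI channel and group."""

    channel: str
    group: str
    values: pd.DataFrame  # index subject_id, columns region names
    repaired: bool = False  # correlation target was projected to nearest PD

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_REGIONS:
            raise ValueError(
                f"expected {N_REGIONS} region columns, got {self.values.shape[1]}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("regional channel table contains non-finite values")


@dataclass
class RoiTimeSeries:
    """T x 90 regional time series for one subject."""

    subject_id: str
    series: np.ndarray
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != N_REGIONS:
            raise ValueError(f"series must be T x {N_REGIONS}")
        if self.series.shape[0] < 30:
            raise ValueError("need at least 30 timepoints")
        if np.any(self.series.std(axis=0) == 0):
            raise ValueError("every regional series must have nonzero variance")


def module_labels(n_regions: int, n_modules: int) -> np.ndarray:
    """Community label per region (contiguous near-equal blocks)."""
    sizes = [len(b) for b in np.array_split(np.arange(n_regions), n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


def modular_correlation(
    n_regions: int, n_modules: int, within_r: float, between_r: float
) -> np.ndarray:
    """Block-modular correlation matrix: within_r inside blocks, between_r outside."""
    labels = module_labels(n_regions, n_modules)
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, within_r, between_r)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped nearest positive-definite correlation matrix.

    Returns (matrix, repaired_flag); the flag is False when the input was
    already positive definite.
    """
    w, v = np.linalg.eigh(corr)
    if w.min() > eps:
        return corr, False
    w_clipped = np.clip(w, eps, None)
    fixed = (v * w_clipped) @ v.T
    # renormalize to unit diagonal so it stays a correlation matrix
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def _group_sizes(cfg: GeneratorConfig) -> dict:
    return {"patient": cfg.n_patients, "control": cfg.n_controls}


def generate_structural_cohort(
    cfg: GeneratorConfig,
) -> dict[tuple[str, str], RegionalChannelTable]:
    """One subjects x 90 kurtosis table per (channel, group).

    Values are multivariate normal with the group's block-modular
    correlation target; a non-positive-definite target is repaired to the
    nearest positive-definite matrix and flagged.  Deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    region_names = load_node_table().names[: cfg.n_regions]
    rng = np.random.default_rng(cfg.seed)
    out: dict[tuple[str, str], RegionalChannelTable] = {}
    for group in GROUPS:
        corr = modular_correlation(
            cfg.n_regions, cfg.n_modules, cfg.within_module_r[group], cfg.between_module_r
        )
        corr, repaired = nearest_positive_definite(corr)
        if repaired:
            warnings.warn(
                f"requested correlation structure for group {group!r} was not "
                "positive definite; repaired by eigenvalue clipping",
                stacklevel=2,
            )
        chol = np.linalg.cholesky(corr)
        n = _group_sizes(cfg)[group]
        ids = [f"{'P' if group == 'patient' else 'C'}{i:03d}" for i in range(1, n + 1)]
        for channel in CHANNELS:
            mean, sd = CHANNEL_LEVELS[channel]
            z = rng.standard_normal((n, cfg.n_regions)) @ chol.T
            values = pd.DataFrame(mean + sd * z, index=ids, columns=region_names)
            values.index.name = "subject_id"
            out[(channel, group)] = RegionalChannelTable(
                channel=channel, group=group, values=values, repaired=repaired
            )
    return out


def _demographics(rng: np.random.Generator, group: str, n: int) -> pd.DataFrame:
    # Age moments match the reported cohorts, truncated to the 30-65 window
    mean, sd = (49.56, 8.02) if group == "patient" else (47.84, 6.71)
    age = np.clip(rng.normal(mean, sd, size=n), 30.0, 65.0).round(1)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    education = rng.integers(6, 19, size=n)
    return pd.DataFrame({"age": age, "sex": sex, "education": education})


def generate_functional_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Module-factor BOLD-like time series plus a subject table.

    Region i in module m has series loading_i * f_m(t) + noise, so the
    analytic within-module correlation is loading^2/(loading^2 + noise_sd^2).
    Patients' loadings in the affected modules (all modules by default) are
    multiplied by ``patient_loading_attenuation``.  The subject table carries
    demographics and a placeholder MoCA column filled by :func:`generate_moca`
    or directly by group-typical scores.
    """
    cfg.validate()
    region_names = load_node_table().names[: cfg.n_regions]
    labels = module_labels(cfg.n_regions, cfg.n_modules)
    affected = (
        set(range(cfg.n_modules)) if cfg.affected_modules is None else set(cfg.affected_modules)
    )
    rng = np.random.default_rng(cfg.seed + 1)
    series_list: list[RoiTimeSeries] = []
    records = []
    for group in GROUPS:
        n = _group_sizes(cfg)[group]
        demo = _demographics(rng, group, n)
        for i in range(n):
            sid = f"{'P' if group == 'patient' else 'C'}{i + 1:03d}"
            factors = rng.standard_normal((cfg.n_timepoints, cfg.n_modules))
            loadings = np.full(cfg.n_regions, cfg.factor_loading)
            if group == "patient":
                mask = np.isin(labels, list(affected))
                loadings[mask] *= cfg.patient_loading_attenuation
            noise = rng.standard_normal((cfg.n_timepoints, cfg.n_regions)) * cfg.noise_sd
            x = factors[:, labels] * loadings[None, :] + noise
            if cfg.noise_sd == 0 and cfg.factor_loading == 0:
                raise ValueError("all-zero series: set a nonzero loading or noise_sd")
            series_list.append(
                RoiTimeSeries(subject_id=sid, series=x, sampling_interval=cfg.sampling_interval)
            )
            records.append({"subject_id": sid, "group": group, **demo.iloc[i].to_dict()})
    subjects = pd.DataFrame(records)
    # group-typical MoCA around the clinical cutoff; overwrite with
    # generate_moca() when planted feature coupling is wanted
    rng_m = np.random.default_rng(cfg.seed + 2)
    base = subjects["group"].map(cfg.moca_intercept).to_numpy(dtype=float)
    moca = np.clip(np.rint(base + rng_m.normal(0, cfg.moca_noise_sd, len(subjects))), 0, 30)
    subjects["moca"] = moca.astype(int)
    _region_names_check = region_names  # label source kept for writers
    return series_list, subjects


def generate_moca(
    features: np.ndarray,
    cfg: GeneratorConfig,
    groups: np.ndarray | list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """MoCA scores linearly coupled to planted features.

    score = round(clip(intercept + features @ moca_effect + N(0, noise_sd), 0, 30)).
    ``groups`` selects per-subject intercepts from ``cfg.moca_intercept``
    (patients below, controls above the 26-point cutoff); without it the
    patient intercept is used for all rows.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    coefs = np.asarray(cfg.moca_effect, dtype=float)
    if features.shape[1] != coefs.size:
        raise ValueError(
            f"feature count {features.shape[1]} does not match moca_effect length {coefs.size}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    if groups is None:
        intercept = np.full(features.shape[0], cfg.moca_intercept["patient"])
    else:
        intercept = np.asarray([cfg.moca_intercept[g] for g in groups], dtype=float)
    raw = intercept + features @ coefs + rng.normal(0.0, cfg.moca_noise_sd, features.shape[0])
    return np.clip(np.rint(raw), 0, 30).astype(int)


def apply_inclusion_criteria(subjects: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study inclusion rules: patients kept iff 30 <= age <= 65 and MoCA < 26;
    controls kept iff MoCA > 26.  Returns (kept, exclusions-with-reasons)."""
    if subjects.empty:
        raise ValueError("subject table is empty")
    reasons = []
    keep = np.ones(len(subjects), dtype=bool)
    for i, row in enumerate(subjects.itertuples(index=False)):
        why = None
        if row.group == "patient":
            if not (30 <= row.age <= 65):
                why = f"age {row.age} outside 30-65"
            elif not (row.moca < 26):
                why = f"MoCA {row.moca} not < 26"
        else:
            if not (row.moca > 26):
                why = f"MoCA {row.moca} not > 26"
        if why is not None:
            keep[i] = False
            reasons.append({"subject_id": row.subject_id, "group": row.group, "reason": why})
            logger.info("excluded %s: %s", row.subject_id, why)
    kept = subjects[keep].reset_index(drop=True)
    if kept.empty:
        warnings.warn("inclusion criteria excluded every subject", stacklevel=2)
    return kept, pd.DataFrame(reasons, columns=["subject_id", "group", "reason"])


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of cfg with a different seed (convenience for seed sweeps)."""
    return replace(cfg, seed=seed)
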