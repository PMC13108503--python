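"""Synthetic cohorts with the statistical structure of an aging rs-fMRI study.

Two age groups are generated (defaults: 179 younger adults aged 18-34, 117
older adults aged 60-89). Each subject carries a latent connectivity state:
a true within-network correlation ``rho_w`` drawn from a group-specific
truncated normal (lower mean and larger spread in the older group) and a
shared true between-network correlation ``rho_b``. The latent segregation

    g = (rho_w - rho_b) / rho_w

mirrors the form of the measured system-segregation score, so generative
effect sizes on cognition have a direct interpretation, and measured SS acts
as an attenuated proxy mediator of group effects on cognition.

Per-subject BOLD runs are sampled from a zero-mean multivariate normal whose
correlation matrix has ``rho_w`` inside network blocks and ``rho_b`` between
blocks, plus diagonal white noise. Adding noise variance deflates every
off-diagonal correlation by the same factor, so the latent g of the
noise-free blocks is preserved exactly.

Cognitive composite indices are linear in (group, g, sex) plus Gaussian
noise; the head-motion covariate is a group-shifted log-normal percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .connectivity import RoiTimeSeries, concatenate_runs, pearson_adjacency
from .parcellation import Parcellation, default_parcellation
from .segregation import DEFAULT_THRESHOLDS, SegregationTransformer

__all__ = [
    "CognitionModel",
    "CohortSpec",
    "LatentSubjectState",
    "generate_cohort",
    "generate_timeseries",
    "simulate_ss_study",
    "write_cohort",
]

YOUNGER, OLDER = "younger", "older"


@dataclass(frozen=True)
class CognitionModel:
    """Linear generative model for one cognitive index.

    index = intercept + group_effect * 1[older] + seg_effect * g
            + sex_effect * 1[female] + N(0, resid_sd)
    """

    intercept: float
    group_effect: float
    seg_effect: float
    sex_effect: float
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")


def _default_cognition() -> dict[str, CognitionModel]:
    # executive and episodic decline with age; semantic improves (so measured
    # segregation acts as an inconsistent mediator there); episodic carries no
    # segregation effect (null-mediation control)
    return {
        "executive": CognitionModel(0.4, -1.1, 4.0, 0.0, 0.85),
        "semantic": CognitionModel(-0.3, 1.4, 4.0, -0.15, 0.85),
        "episodic": CognitionModel(0.3, -1.2, 0.0, 0.25, 0.85),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a two-group synthetic cohort.

    Correlation parameters live in [0, 1); ``rho_within`` means must not fall
    below ``rho_between_mean``. Proportions (sex, site, missingness) are per
    group in [0, 1]. ``noise_sd`` is the SD of white noise added on the
    diagonal of the block covariance (it deflates measured correlations
    uniformly and leaves latent g untouched).
    """

    n_young: int = 179
    n_old: int = 117
    age_range_young: tuple[float, float] = (18.0, 34.0)
    age_range_old: tuple[float, float] = (60.0, 89.0)
    sex_proportion_female: tuple[float, float] = (0.579, 0.547)  # (young, old)
    site_proportion: tuple[float, float] = (0.151, 0.291)  # P(site2) per group
    n_rois: int = 200
    n_networks: int = 7
    n_volumes_per_run: int = 200
    n_runs: int = 2
    rho_within_mean_young: float = 0.45
    rho_within_mean_old: float = 0.35
    rho_within_sd_young: float = 0.05
    rho_within_sd_old: float = 0.09
    rho_between_mean: float = 0.15
    noise_sd: float = 0.3
    cognition_coefficients: dict[str, CognitionModel] = field(
        default_factory=_default_cognition
    )
    missing_rate: float = 0.06
    motion_logmean: tuple[float, float] = (1.70, 2.05)  # (young, old), log-%
    motion_logsd: tuple[float, float] = (0.87, 0.90)

    # rho_w draws are truncated to this window so g stays defined and the
    # block matrix stays near-PSD
    rho_within_floor_margin: float = 0.01
    rho_within_cap: float = 0.95

    def __post_init__(self) -> None:
        if self.n_young <= 0 or self.n_old <= 0:
            raise ValueError("group sizes must be positive")
        for lo, hi in (self.age_range_young, self.age_range_old):
            if not hi > lo:
                raise ValueError("age ranges must be non-degenerate")
        for rho in (
            self.rho_within_mean_young,
            self.rho_within_mean_old,
            self.rho_between_mean,
        ):
            if not 0 <= rho < 1:
                raise ValueError("correlation parameters must lie in [0, 1)")
        if (
            min(self.rho_within_mean_young, self.rho_within_mean_old)
            < self.rho_between_mean
        ):
            raise ValueError("rho_within means must be >= rho_between_mean")
        for sd in (self.rho_within_sd_young, self.rho_within_sd_old, self.noise_sd):
            if sd < 0:
                raise ValueError("SD parameters must be non-negative")
        for p in (*self.sex_proportion_female, *self.site_proportion,
                  self.missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        if self.n_volumes_per_run < 2 or self.n_runs < 1:
            raise ValueError("need >= 2 volumes per run and >= 1 run")


@dataclass(frozen=True)
class LatentSubjectState:
    """Ground-truth generative state of one subject."""

    subject: str
    index: int
    group: str
    rho_within: float
    rho_between: float
    sex: str
    site: str
    age: float

    @property
    def g(self) -> float:
        """Latent segregation (rho_w - rho_b) / rho_w; defined for rho_w > 0."""
        if self.rho_within <= 0:
            raise ValueError("latent segregation undefined for rho_within <= 0")
        return (self.rho_within - self.rho_between) / self.rho_within


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[pd.DataFrame, list[LatentSubjectState]]:
    """Draw a phenotype table and per-subject latent states.

    Deterministic given (spec, seed); cohort draws come from the "cohort"
    substream and missingness from the "missing" substream, so toggling
    missingness never perturbs the cohort itself.
    """
    rng = substream(seed, "cohort")
    groups = [YOUNGER] * spec.n_young + [OLDER] * spec.n_old
    n = len(groups)
    is_old = np.array([g == OLDER for g in groups])

    lo_y, hi_y = spec.age_range_young
    lo_o, hi_o = spec.age_range_old
    ages = np.where(
        is_old,
        rng.uniform(lo_o, hi_o, size=n),
        rng.uniform(lo_y, hi_y, size=n),
    )
    p_female = np.where(is_old, *reversed(spec.sex_proportion_female))
    sexes = np.where(rng.uniform(size=n) < p_female, "female", "male")
    p_site2 = np.where(is_old, *reversed(spec.site_proportion))
    sites = np.where(rng.uniform(size=n) < p_site2, "site2", "site1")

    floor = spec.rho_between_mean + spec.rho_within_floor_margin
    rho_w = np.empty(n)
    rho_w[~is_old] = _truncnorm_rvs(
        spec.rho_within_mean_young, spec.rho_within_sd_young,
        floor, spec.rho_within_cap, int((~is_old).sum()), rng,
    )
    rho_w[is_old] = _truncnorm_rvs(
        spec.rho_within_mean_old, spec.rho_within_sd_old,
        floor, spec.rho_within_cap, int(is_old.sum()), rng,
    )
    g = (rho_w - spec.rho_between_mean) / rho_w

    mu, sig = spec.motion_logmean, spec.motion_logsd
    motion = np.exp(
        np.where(is_old, mu[1], mu[0])
        + np.where(is_old, sig[1], sig[0]) * rng.standard_normal(n)
    )

    states = [
        LatentSubjectState(
            subject=f"sub-{i + 1:04d}",
            index=i,
            group=groups[i],
            rho_within=float(rho_w[i]),
            rho_between=spec.rho_between_mean,
            sex=str(sexes[i]),
            site=str(sites[i]),
            age=float(ages[i]),
        )
        for i in range(n)
    ]

    pheno = pd.DataFrame(
        {
            "subject": [s.subject for s in states],
            "age": np.round(ages, 2),
            "age_group": groups,
            "sex": sexes,
            "site": sites,
            "motion_pct": np.round(motion, 3),
        }
    )
    grp_lo = np.where(is_old, lo_o, lo_y)
    grp_rng = np.where(is_old, hi_o - lo_o, hi_y - lo_y)
    pheno["group_relative_age"] = (pheno["age"] - grp_lo) / grp_rng

    is_female = (sexes == "female").astype(float)
    for name, cm in spec.cognition_coefficients.items():
        pheno[name] = (
            cm.intercept
            + cm.group_effect * is_old
            + cm.seg_effect * g
            + cm.sex_effect * is_female
            + cm.resid_sd * rng.standard_normal(n)
        )

    if spec.missing_rate > 0:
        miss_rng = substream(seed, "missing")
        for name in spec.cognition_coefficients:
            mask = miss_rng.uniform(size=n) < spec.missing_rate
            pheno.loc[mask, name] = np.nan

    return pheno, states


def block_correlation_matrix(
    labels: np.ndarray, rho_within: float, rho_between: float
) -> np.ndarray:
    """Correlation matrix with rho_within inside blocks, rho_between across."""
    same = labels[:, None] == labels[None, :]
    R = np.where(same, rho_within, rho_between)
    np.fill_diagonal(R, 1.0)
    return R


def nearest_psd(A: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    vals, vecs = np.linalg.eigh(A)
    if vals.min() >= 0:
        return A
    vals = np.clip(vals, eps, None)
    return (vecs * vals) @ vecs.T


def generate_timeseries(
    state: LatentSubjectState,
    parcellation: Parcellation,
    spec: CohortSpec,
    seed: int,
) -> list[RoiTimeSeries]:
    """Sample the subject's runs from the block-covariance model.

    Each run is an i.i.d. draw of ``n_volumes_per_run`` volumes from
    ``N(0, R + noise_sd^2 I)`` where R is the subject's block correlation
    matrix. Draws come from the "timeseries" substream keyed by the subject
    index and run number, independent of the cohort substream.
    """
    if parcellation.n_rois != spec.n_rois:
        raise ValueError(
            f"parcellation has {parcellation.n_rois} ROIs, spec expects {spec.n_rois}"
        )
    labels = parcellation.labels_array()
    R = block_correlation_matrix(labels, state.rho_within, state.rho_between)
    cov = R + spec.noise_sd**2 * np.eye(spec.n_rois)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = nearest_psd(cov)
        try:
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(spec.n_rois))
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            raise RuntimeError(
                f"covariance for {state.subject} not PSD after repair"
            ) from err
    runs = []
    for r in range(spec.n_runs):
        rng = substream(seed, "timeseries", state.index, r)
        z = rng.standard_normal((spec.n_volumes_per_run, spec.n_rois))
        runs.append(
            RoiTimeSeries(z @ L.T, parcellation.roi_names, run_id=f"run-{r + 1}")
        )
    return runs


def simulate_ss_study(
    spec: CohortSpec,
    seed: int,
    parcellation: Parcellation | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    keep_from: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[LatentSubjectState]]:
    """Generate a cohort and carry every subject through to measured SS.

    Returns (phenotype table, tidy SS table with columns
    subject/threshold/scope/Bw/Bb/SS, latent states). The per-run TR window
    is ``keep_from .. n_volumes_per_run``, mirroring the trimming applied to
    real runs.
    """
    parc = parcellation or default_parcellation(spec.n_rois, spec.n_networks)
    pheno, states = generate_cohort(spec, seed)
    seg = SegregationTransformer(parc, thresholds)
    frames = []
    for state in states:
        runs = generate_timeseries(state, parc, spec, seed)
        ts = concatenate_runs(runs, keep_from, spec.n_volumes_per_run)
        W = pearson_adjacency(ts)
        frames.append(seg.profiles([W.weights], subjects=[state.subject]))
    ss_long = pd.concat(frames, ignore_index=True)
    return pheno, ss_long, states


def write_cohort(
    spec: CohortSpec,
    seed: int,
    outdir,
    parcellation: Parcellation | None = None,
    write_timeseries: bool = True,
) -> pd.DataFrame:
    """Materialize a cohort on disk: phenotype CSV, parcellation CSV, run TSVs."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    parc = parcellation or default_parcellation(spec.n_rois, spec.n_networks)
    pheno, states = generate_cohort(spec, seed)
    pheno.to_csv(out / "phenotype.csv", index=False)
    parc.to_frame().to_csv(out / "parcellation.csv", index=False)
    if write_timeseries:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for state in states:
            for run in generate_timeseries(state, parc, spec, seed):
                run.to_frame().to_csv(
                    ts_dir / f"{state.subject}_{run.run_id}.tsv",
                    sep="\t", index=False, float_format="%.6f",
                )
    return pheno


def null_cognition_spec(spec: CohortSpec | None = None) -> CohortSpec:
    """Copy of a spec with all group/segregation/sex effects on cognition zeroed."""
    base = spec or CohortSpec()
    null = {
        k: replace(cm, group_effect=0.0, seg_effect=0.0, sex_effect=0.0)
        for k, cm in base.cognition_coefficients.items()
    }
    return replace(base, cognition_coefficients=null)
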