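"""End-to-end orchestration: config -> staged tidy tables with provenance.

Stages run in analysis order — cohort (simulate or load), connectivity +
segregation sweep, group statistics, within-group correlations with
range-restriction correction, mediation sweep, classification — and each
writes one tidy CSV into the output directory. A manifest records the config
hash, master seed and package version; stages whose output already exists
under the same config hash are reused instead of recomputed.
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
from .classification import nested_cv_logistic
from .connectivity import RoiTimeSeries, concatenate_runs, pearson_adjacency
from .mediation import mediation_sweep
from .parcellation import Parcellation, default_parcellation
from .range_restriction import (
    bivariate_restriction_correction,
    pooled_unrestricted_sd,
    thorndike_case2,
)
from .segregation import DEFAULT_THRESHOLDS, GLOBAL_SCOPE, SegregationTransformer
from .simulate import CognitionModel, CohortSpec, simulate_ss_study
from .stats import ThresholdSweepResult, rank_anova, spearman_partial

log = logging.getLogger("netseg.pipeline")

__all__ = ["RunConfig", "run_pipeline", "sensitivity_subset"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input mode.

    Synthetic mode generates the cohort from ``cohort``; real mode reads a
    time-series directory (``<subject>_run-<k>.tsv``), a parcellation table
    and a phenotype table.
    """

    outdir: str = "netseg-output"
    seed: int = 0
    synthetic: bool = True
    cohort: CohortSpec = field(default_factory=CohortSpec)
    timeseries_dir: str | None = None
    parcellation_path: str | None = None
    phenotype_path: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    min_k: int = 3
    indices: tuple[str, ...] = ("executive", "semantic", "episodic")
    keep_from: int = 5
    keep_to: int | None = None  # default: run length of the cohort spec
    n_boot: int = 5000
    ci_level: float = 0.95
    outer_k: int = 5
    inner_k: int = 5
    test_size: float = 0.3

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if not self.thresholds:
            raise ValueError("threshold grid is empty")
        for t in self.thresholds:
            if not 0 < t <= 1:
                raise ValueError(f"threshold {t} outside (0, 1]")
        real_paths = [self.timeseries_dir, self.parcellation_path,
                      self.phenotype_path]
        if self.synthetic and any(real_paths):
            raise ValueError("synthetic mode must not set real-input paths")
        if not self.synthetic and not all(real_paths):
            raise ValueError("real mode needs timeseries, parcellation and "
                             "phenotype paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            c = dict(raw["cohort"])
            if "cognition_coefficients" in c:
                c["cognition_coefficients"] = {
                    k: CognitionModel(**v) if isinstance(v, dict)
                    else CognitionModel(*v)
                    for k, v in c["cognition_coefficients"].items()
                }
            for key in ("age_range_young", "age_range_old",
                        "sex_proportion_female", "site_proportion",
                        "motion_logmean", "motion_logsd"):
                if key in c:
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortSpec(**c)
        for key in ("thresholds", "indices"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in sorted(obj.items())}
            return obj

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _derive_columns(pheno: pd.DataFrame) -> pd.DataFrame:
    """Numeric codings and the within-group age covariate."""
    out = pheno.copy()
    out["age_group_older"] = (out["age_group"] == "older").astype(int)
    out["sex_female"] = (out["sex"] == "female").astype(int)
    if "group_relative_age" not in out.columns:
        grp = out.groupby("age_group")["age"]
        lo, span = grp.transform("min"), grp.transform(lambda a: a.max() - a.min())
        out["group_relative_age"] = np.where(span > 0, (out["age"] - lo) / span, 0.5)
    return out


class _Stages:
    """Staged execution with manifest-keyed caching."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()

    def _load_manifest(self) -> dict:
        fresh = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "version": __version__,
            "stages": {},
        }
        if self.manifest_path.exists():
            old = json.loads(self.manifest_path.read_text())
            if (old.get("config_hash") == fresh["config_hash"]
                    and old.get("seed") == fresh["seed"]):
                return old
        return fresh

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def run(self, name: str, filename: str, producer) -> pd.DataFrame:
        path = self.out / filename
        if name in self.manifest["stages"] and path.exists():
            log.info("stage %s: cached (%s)", name, path)
            return pd.read_csv(path)
        log.info("stage %s: computing", name)
        df = producer()
        df.to_csv(path, index=False)
        self.manifest["stages"][name] = {
            "file": filename,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest()[:16],
        }
        self._save_manifest()
        return df


def _load_real_inputs(config: RunConfig):
    parc = Parcellation.from_csv(config.parcellation_path)
    pheno = pd.read_csv(config.phenotype_path)
    ts_dir = Path(config.timeseries_dir)
    seg = SegregationTransformer(parc, config.thresholds)
    frames = []
    for subject in pheno["subject"]:
        run_files = sorted(ts_dir.glob(f"{subject}_run-*.tsv"))
        if not run_files:
            raise FileNotFoundError(f"no runs found for {subject} in {ts_dir}")
        runs = [RoiTimeSeries.from_file(f, run_id=f.stem) for f in run_files]
        keep_to = config.keep_to or min(r.n_volumes for r in runs)
        ts = concatenate_runs(runs, config.keep_from, keep_to)
        W = pearson_adjacency(ts)
        frames.append(seg.profiles([W.weights], subjects=[subject]))
    return pheno, pd.concat(frames, ignore_index=True)


def _stage_inputs(config: RunConfig, stages: _Stages):
    cache_p = stages.out / "phenotype.csv"
    cache_s = stages.out / "ss_long.csv"
    cached = {"inputs", "inputs_ss"} <= set(stages.manifest["stages"])
    if cached and cache_p.exists() and cache_s.exists():
        log.info("stage inputs: cached")
        return pd.read_csv(cache_p), pd.read_csv(cache_s)
    if config.synthetic:
        pheno, ss_long, _ = simulate_ss_study(
            config.cohort, config.seed, thresholds=config.thresholds,
            keep_from=config.keep_from,
        )
    else:
        pheno, ss_long = _load_real_inputs(config)
    stages.run("inputs", "phenotype.csv", lambda: pheno)
    stages.run("inputs_ss", "ss_long.csv", lambda: ss_long)
    return pheno, ss_long


def _group_stats(pheno: pd.DataFrame, ss_long: pd.DataFrame,
                 config: RunConfig) -> pd.DataFrame:
    """Rank-ordered two-way ANOVA (group + sex) per scope and threshold."""
    d = _derive_columns(pheno)
    merged = ss_long.merge(
        d[["subject", "age_group", "sex"]], on="subject", how="inner"
    )
    rows = []
    for scope, sub in merged.groupby("scope", sort=False):
        per_t = {}
        for t, cell in sub.groupby("threshold"):
            cell = cell.dropna(subset=["SS"])
            res = rank_anova(cell["SS"], cell["age_group"], cell["sex"])
            per_t[float(t)] = res
            means = cell.groupby("age_group")["SS"].mean()
            rows.append({
                "scope": scope, "threshold": float(t), "F": res.statistic,
                "df1": res.df[0], "df2": res.df[1], "p": res.pvalue,
                "older_higher": bool(means.get("older", np.nan)
                                     > means.get("younger", np.nan)),
            })
        sweep = ThresholdSweepResult(per_t, alpha=config.alpha,
                                     min_k=config.min_k)
        for r in rows:
            if r["scope"] == scope:
                r["consistent"] = sweep.consistent
    return pd.DataFrame(rows)


def _correlations(pheno: pd.DataFrame, ss_long: pd.DataFrame,
                  config: RunConfig,
                  extra_covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Within-group Spearman partials (covariates: sex, within-group age),
    with Thorndike range-restriction corrections appended."""
    d = _derive_columns(pheno)
    rows = []
    for scope, sub in ss_long.groupby("scope", sort=False):
        for t, cell in sub.groupby("threshold"):
            ss = cell.set_index("subject")["SS"]
            merged = d.set_index("subject").join(ss, how="inner").reset_index()
            pooled_ss = merged.dropna(subset=["SS"])
            groups = {g: v for g, v in pooled_ss.groupby("age_group")}
            if len(groups) < 2:
                continue
            sd_pool = {
                "SS": pooled_unrestricted_sd(
                    *[v["SS"] for v in groups.values()]
                )
            }
            for index in config.indices:
                both = [v[index].dropna() for v in groups.values()]
                sd_pool[index] = (
                    pooled_unrestricted_sd(*both)
                    if all(len(b) >= 2 for b in both) else np.nan
                )
            for gname, gdf in groups.items():
                for index in config.indices:
                    frame = gdf.dropna(subset=["SS", index])
                    covs = [frame["sex_female"], frame["group_relative_age"]]
                    covs += [frame[c] for c in extra_covariates]
                    try:
                        res = spearman_partial(frame["SS"], frame[index], covs)
                    except ValueError:
                        continue
                    s_ss = frame["SS"].std(ddof=1)
                    row = {
                        "group": gname, "scope": scope, "threshold": float(t),
                        "index": index, "rs": res.statistic, "p": res.pvalue,
                        "n": len(frame),
                    }
                    try:
                        if index == "episodic":
                            corr = bivariate_restriction_correction(
                                res.statistic, s_ss, sd_pool["SS"],
                                frame[index].std(ddof=1), sd_pool[index],
                                len(frame),
                            )
                        else:
                            corr = thorndike_case2(
                                res.statistic, s_ss, sd_pool["SS"], len(frame)
                            )
                        row["r_adj"], row["p_adj"] = corr.r_adj, corr.p_adj
                    except ValueError:
                        row["r_adj"] = row["p_adj"] = np.nan
                    rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    # sweep-level consistency per (group, scope, index)
    key = ["group", "scope", "index"]
    sig = out.assign(is_sig=out["p"] < config.alpha).groupby(key)["is_sig"].sum()
    out["consistent"] = out.set_index(key).index.map(
        (sig >= config.min_k).to_dict()
    )
    return out


def _classification(pheno: pd.DataFrame, ss_long: pd.DataFrame,
                    config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    d = _derive_columns(pheno)
    glob = ss_long[ss_long["scope"] == GLOBAL_SCOPE]
    wide = glob.pivot_table(index="subject", columns="threshold", values="SS")
    wide.columns = [f"SS_t{t:.2f}" for t in wide.columns]
    frame = d.set_index("subject").join(wide).reset_index()
    cog = list(config.indices)
    sets = {"cognition": cog, "cognition+SS": cog + list(wide.columns)}
    comp = nested_cv_logistic(
        frame, sets, label_col="age_group", outer_k=config.outer_k,
        inner_k=config.inner_k, test_size=config.test_size, seed=config.seed,
    )
    summary = comp.test_metrics.merge(comp.fold_metrics.groupby(
        "feature_set")[["auc", "acc", "bacc"]].mean().add_prefix("cv_"),
        on="feature_set")
    return comp.fold_metrics.assign(kind="outer_fold"), summary.merge(
        comp.paired_tests.assign(feature_set=comp.feature_sets[0]),
        on="feature_set", how="left",
    )


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages; returns the result tables keyed by stage name."""
    stages = _Stages(config)
    pheno, ss_long = _stage_inputs(config, stages)

    group_stats = stages.run(
        "group_stats", "group_stats.csv",
        lambda: _group_stats(pheno, ss_long, config),
    )
    correlations = stages.run(
        "correlations", "correlations.csv",
        lambda: _correlations(pheno, ss_long, config),
    )
    mediation = stages.run(
        "mediation", "mediation.csv",
        lambda: mediation_sweep(
            _derive_columns(pheno), ss_long, config.indices,
            thresholds=list(config.thresholds),
            n_boot=config.n_boot, ci_level=config.ci_level, seed=config.seed,
            alpha=config.alpha, min_k=config.min_k,
        ),
    )
    fold_metrics, class_summary = None, None

    def _cls_fold():
        nonlocal fold_metrics, class_summary
        fold_metrics, class_summary = _classification(pheno, ss_long, config)
        return fold_metrics

    folds = stages.run("classification_folds", "classification_folds.csv",
                       _cls_fold)
    summary = stages.run(
        "classification", "classification_summary.csv",
        lambda: class_summary if class_summary is not None
        else _classification(pheno, ss_long, config)[1],
    )
    return {
        "phenotype": pheno,
        "ss_long": ss_long,
        "group_stats": group_stats,
        "correlations": correlations,
        "mediation": mediation,
        "classification_folds": folds,
        "classification_summary": summary,
    }


def sensitivity_subset(
    config: RunConfig,
    drop_site: str,
    add_motion_covariate: bool = False,
    min_per_group: int = 10,
) -> dict[str, pd.DataFrame]:
    """Re-run correlations and mediation excluding one site.

    Optionally adds the motion covariate; SS values are reused from the
    primary run's cache (stage isolation: only inferential tables change).
    Emits side-by-side comparison tables against the primary run. Refuses if
    the subset leaves fewer than ``min_per_group`` subjects in either group.
    """
    primary = run_pipeline(config)
    pheno, ss_long = primary["phenotype"], primary["ss_long"]
    keep = pheno[pheno["site"] != drop_site]
    counts = keep["age_group"].value_counts()
    if len(counts) < 2 or counts.min() < min_per_group:
        raise ValueError(
            f"dropping site {drop_site!r} leaves fewer than {min_per_group} "
            "subjects in an age group"
        )
    ss_keep = ss_long[ss_long["subject"].isin(keep["subject"])]
    extra = ("motion_pct",) if add_motion_covariate else ()
    med_cov = ["sex_female", "group_relative_age", *extra]

    corr = _correlations(keep, ss_keep, config, extra_covariates=extra)
    med = mediation_sweep(
        _derive_columns(keep), ss_keep, config.indices,
        covariates=med_cov, thresholds=list(config.thresholds),
        n_boot=config.n_boot, ci_level=config.ci_level, seed=config.seed,
        alpha=config.alpha, min_k=config.min_k,
    )

    key = ["group", "scope", "threshold", "index"]
    corr_cmp = primary["correlations"].merge(
        corr, on=key, suffixes=("_primary", "_sensitivity")
    )
    med_key = ["threshold", "index", "path"]
    med_cmp = primary["mediation"].merge(
        med, on=med_key, suffixes=("_primary", "_sensitivity")
    )
    out = Path(config.outdir) / f"sensitivity-drop-{drop_site}"
    out.mkdir(parents=True, exist_ok=True)
    corr.to_csv(out / "correlations.csv", index=False)
    med.to_csv(out / "mediation.csv", index=False)
    corr_cmp.to_csv(out / "correlations_comparison.csv", index=False)
    med_cmp.to_csv(out / "mediation_comparison.csv", index=False)
    return {
        "correlations": corr,
        "mediation": med,
        "correlations_comparison": corr_cmp,
        "mediation_comparison": med_cmp,
    }
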