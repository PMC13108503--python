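"""Simple (model-4) mediation with percentile-bootstrap indirect effects.

Tests whether a mediator M (here: global system segregation at one sparsity
threshold) transmits part of the effect of a binary predictor X (age group)
on an outcome Y (a cognitive composite), adjusting for covariates:

    M = i1 + a X   + f'cov            (path a)
    Y = i2 + c' X + b M + g'cov       (paths b, c')
    Y = i3 + c X  + h'cov             (total effect c)

All three are OLS fits on the listwise-complete sample, so the decomposition
c = c' + a*b holds exactly. The indirect effect a*b gets a percentile
bootstrap confidence interval over subjects (resampled with replacement,
unstratified). Standardized ("partially standardized") effects scale M and Y
to unit SD on the analysis sample while leaving the binary X untouched.

A significant indirect effect whose sign matches the direct effect is a
classical mediation; an opposite sign marks an inconsistent (suppression-
style) mediation, where the mediated pathway attenuates the total effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from ._rng import substream
from .stats import ThresholdSweepResult, TestResult, threshold_consistency

__all__ = [
    "MediationResult",
    "MediationModel",
    "group_relative_age",
    "mediate",
    "mediation_sweep",
]

CLASSICAL, INCONSISTENT, NONE = "classical", "inconsistent", "none"


def group_relative_age(age, group_min: float, group_range: float):
    """Normalize age to [0, 1] within the subject's own age group.

    Removes the between-group age gap so that age can serve as a within-group
    covariate alongside the group factor.
    """
    if group_range <= 0:
        raise ValueError("group_range must be positive")
    age = np.asarray(age, dtype=float)
    rel = (age - group_min) / group_range
    if ((rel < -1e-12) | (rel > 1 + 1e-12)).any():
        raise ValueError("age outside its group's [min, min + range] bounds")
    out = np.clip(rel, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _ols(X: np.ndarray, y: np.ndarray):
    """Coefficients, SEs and two-sided p-values for y ~ X (X includes 1s)."""
    n, p = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular design matrix") from err
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * sps.t.sf(np.abs(t), dof)
    return beta, se, pvals


@dataclass
class MediationResult:
    """Paths and bootstrap CI of one mediation fit.

    ``paths`` maps each of a, b, c, c_prime, indirect to
    (estimate, standardized estimate, p-value); the indirect effect's
    "p-value" slot holds NaN (inference is by its CI).
    """

    paths: dict[str, tuple[float, float, float]]
    indirect_ci: tuple[float, float]
    indirect_ci_standardized: tuple[float, float]
    classification: str
    n_used: int
    n_dropped: int
    n_boot: int
    ci_level: float

    def estimate(self, path: str) -> float:
        return self.paths[path][0]

    @property
    def indirect(self) -> float:
        return self.paths["indirect"][0]


class MediationModel(BaseEstimator):
    """Percentile-bootstrap mediation estimator (scikit-learn style).

    Parameters
    ----------
    n_boot : int
        Bootstrap resamples for the indirect-effect CI (>= 1000).
    ci_level : float
        Two-sided confidence level in (0, 1).
    seed : int or None
        Master seed; bootstrap draws come from its "bootstrap" substream, so
        the CI is bit-reproducible for a fixed seed.

    Attributes (after ``fit``)
    --------------------------
    a_, b_, c_, c_prime_, indirect_ : float
    indirect_ci_ : (low, high)
    boot_indirect_ : ndarray of bootstrap indirect effects
    result_ : MediationResult
    """

    def __init__(self, n_boot: int = 5000, ci_level: float = 0.95,
                 seed: int | None = None):
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.seed = seed

    def fit(self, data: pd.DataFrame, x: str, m: str, y: str, covariates=()):
        if self.n_boot < 1000:
            raise ValueError("n_boot must be >= 1000")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        covariates = list(covariates)
        cols = [x, m, y, *covariates]
        df = data[cols].apply(pd.to_numeric, errors="raise").dropna()
        n = len(df)
        n_dropped = len(data) - n
        xv = df[x].to_numpy(float)
        ux = np.unique(xv)
        if len(ux) != 2:
            raise ValueError("X must be strictly binary on the analysis sample")
        xv = (xv == ux[1]).astype(float)  # 0/1 coding, higher level = 1
        mv, yv = df[m].to_numpy(float), df[y].to_numpy(float)
        C = df[covariates].to_numpy(float) if covariates else np.empty((n, 0))

        ones = np.ones((n, 1))
        Dm = np.hstack([ones, xv[:, None], C])                 # M ~ X + cov
        Dy = np.hstack([ones, xv[:, None], mv[:, None], C])    # Y ~ X + M + cov
        beta_a, _, p_a = _ols(Dm, mv)
        beta_y, _, p_y = _ols(Dy, yv)
        beta_c, _, p_c = _ols(Dm, yv)                          # Y ~ X + cov
        a, b = float(beta_a[1]), float(beta_y[2])
        c_prime, c = float(beta_y[1]), float(beta_c[1])
        indirect = a * b

        rng = (substream(self.seed, "bootstrap") if self.seed is not None
               else np.random.default_rng())
        boot = self._bootstrap_indirect(rng, xv, mv, yv, C)

        lo_q = (1 - self.ci_level) / 2
        ci = (float(np.quantile(boot, lo_q)),
              float(np.quantile(boot, 1 - lo_q)))

        sd_m, sd_y = np.std(mv, ddof=1), np.std(yv, ddof=1)
        if sd_m == 0 or sd_y == 0:
            raise ValueError("mediator or outcome has zero variance")
        std = {
            "a": a / sd_m,
            "b": b * sd_m / sd_y,
            "c": c / sd_y,
            "c_prime": c_prime / sd_y,
            "indirect": indirect / sd_y,
        }
        ci_std = (ci[0] / sd_y, ci[1] / sd_y)

        excludes_zero = ci[0] > 0 or ci[1] < 0
        if excludes_zero and np.sign(indirect) == np.sign(c_prime):
            label = CLASSICAL
        elif excludes_zero:
            label = INCONSISTENT
        else:
            label = NONE

        self.a_, self.b_, self.c_, self.c_prime_ = a, b, c, c_prime
        self.indirect_ = indirect
        self.indirect_ci_ = ci
        self.boot_indirect_ = boot
        self.result_ = MediationResult(
            paths={
                "a": (a, std["a"], float(p_a[1])),
                "b": (b, std["b"], float(p_y[2])),
                "c": (c, std["c"], float(p_c[1])),
                "c_prime": (c_prime, std["c_prime"], float(p_y[1])),
                "indirect": (indirect, std["indirect"], float("nan")),
            },
            indirect_ci=ci,
            indirect_ci_standardized=ci_std,
            classification=label,
            n_used=n,
            n_dropped=n_dropped,
            n_boot=self.n_boot,
            ci_level=self.ci_level,
        )
        return self

    def _bootstrap_indirect(self, rng, xv, mv, yv, C) -> np.ndarray:
        """Batched OLS over bootstrap resamples; returns a*b per resample."""
        n = len(xv)
        Dm = np.hstack([np.ones((n, 1)), xv[:, None], C])
        Dy = np.hstack([Dm, mv[:, None]])  # M column last: b = last coef
        out = np.empty(self.n_boot)
        filled = 0
        chunk = min(self.n_boot, max(1, int(2e7 // (n * Dy.shape[1]))))
        while filled < self.n_boot:
            want = min(chunk, self.n_boot - filled)
            idx = rng.integers(0, n, size=(want, n))
            # drop degenerate resamples where X is constant
            idx = idx[xv[idx].std(axis=1) > 0]
            if idx.size == 0:
                continue
            idx = idx[: self.n_boot - filled]
            Am = Dm[idx]                       # (B, n, p)
            Ay = Dy[idx]                       # (B, n, p + 1)
            AmT, AyT = Am.transpose(0, 2, 1), Ay.transpose(0, 2, 1)
            beta_a = np.linalg.solve(AmT @ Am, AmT @ mv[idx][..., None])
            beta_b = np.linalg.solve(AyT @ Ay, AyT @ yv[idx][..., None])
            ab = beta_a[:, 1, 0] * beta_b[:, -1, 0]
            out[filled : filled + len(ab)] = ab
            filled += len(ab)
        return out


def mediate(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates=(),
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> MediationResult:
    """One model-4 mediation fit; see :class:`MediationModel`."""
    model = MediationModel(n_boot=n_boot, ci_level=ci_level, seed=seed)
    return model.fit(data, x=x, m=m, y=y, covariates=covariates).result_


def mediation_sweep(
    data: pd.DataFrame,
    ss_long: pd.DataFrame,
    indices,
    x: str = "age_group_older",
    covariates=("sex_female", "group_relative_age"),
    thresholds=None,
    scope: str = "global",
    n_boot: int = 5000,
    ci_level: float = 0.95,
    seed: int | None = None,
    alpha: float = 0.05,
    min_k: int = 3,
) -> pd.DataFrame:
    """Mediation at every sparsity threshold for every cognitive index.

    ``data`` must carry one row per subject (keyed by ``subject``) with the
    predictor, outcomes and covariates; ``ss_long`` is the tidy SS table.
    Returns a tidy table with one row per (threshold, index, path) holding
    estimate, standardized estimate B, CI bounds for the indirect effect,
    p-values for regression paths, the mediation classification, and the
    sweep-level consistency flag of the indirect effect per index.
    """
    sub = ss_long[ss_long["scope"] == scope]
    if thresholds is None:
        thresholds = sorted(sub["threshold"].unique())
    rows = []
    consistency: dict[str, bool] = {}
    for index in indices:
        per_threshold: dict[float, TestResult] = {}
        for t in thresholds:
            ss_t = (
                sub[np.isclose(sub["threshold"], t)]
                .set_index("subject")["SS"]
                .rename("SS")
            )
            merged = data.set_index("subject").join(ss_t, how="inner").reset_index()
            res = mediate(
                merged, x=x, m="SS", y=index, covariates=covariates,
                n_boot=n_boot, ci_level=ci_level, seed=seed,
            )
            lo, hi = res.indirect_ci
            sig = lo > 0 or hi < 0
            per_threshold[float(t)] = TestResult(
                "ab", res.indirect, (float(res.n_used),),
                0.0 if sig else 1.0,  # CI-based pseudo-p for the consistency rule
            )
            for path, (est, std, p) in res.paths.items():
                rows.append(
                    {
                        "threshold": float(t),
                        "index": index,
                        "path": path,
                        "estimate": est,
                        "B": std,
                        "ci_low": lo if path == "indirect" else np.nan,
                        "ci_high": hi if path == "indirect" else np.nan,
                        "p": p,
                        "classification": res.classification,
                        "n": res.n_used,
                    }
                )
        consistency[index] = threshold_consistency(
            ThresholdSweepResult(per_threshold, alpha=alpha, min_k=min_k)
        )
    out = pd.DataFrame(rows)
    out["indirect_consistent"] = out["index"].map(consistency)
    return out
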