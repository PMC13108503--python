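"""Composite cognitive indices and group-level inference.

The inferential toolkit mirrors a rank-based analysis plan: Levene and
Shapiro-Wilk act as gates selecting nonparametric procedures; group
differences are tested with a rank-ordered two-way ANOVA (group + sex,
additive, type II); brain-behaviour associations use Spearman partial
correlations; demographics use uncorrected Pearson chi-squares and
Mann-Whitney U. Conclusions across the sparsity sweep are drawn only through
the >= 3-significant-thresholds consistency rule, never from a single
threshold's p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ThresholdSweepResult",
    "build_composite",
    "levene_center_median",
    "shapiro_wilk",
    "rank_anova",
    "spearman_partial",
    "robust_group_regression",
    "chi_square_2x2",
    "mann_whitney",
    "variance_ratio",
    "threshold_consistency",
]


@dataclass(frozen=True)
class TestResult:
    """One test statistic with df, p, and effect direction.

    ``direction`` is +1 / -1 / 0 oriented so that, for two-group tests,
    positive means the second group level (sorted order) scores higher.
    """

    __test__ = False  # keep pytest from collecting the Test* name

    name: str
    statistic: float
    df: tuple[float, ...]
    pvalue: float
    direction: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isnan(self.pvalue) or 0 <= self.pvalue <= 1):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ThresholdSweepResult:
    """Per-threshold results plus the multi-threshold consistency summary."""

    results: dict[float, TestResult]
    alpha: float = 0.05
    min_k: int = 3
    n_significant: int = field(init=False)
    consistent: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.results:
            raise ValueError("empty threshold sweep")
        self.n_significant = sum(
            1 for r in self.results.values() if r.pvalue < self.alpha
        )
        self.consistent = self.n_significant >= self.min_k


def threshold_consistency(
    sweep: ThresholdSweepResult | dict[float, TestResult],
    alpha: float = 0.05,
    min_k: int = 3,
) -> bool:
    """True iff at least ``min_k`` thresholds reach p < alpha.

    This is the only sanctioned way to call a sweep-level effect significant;
    it guards against conclusions driven by a single sparsity choice.
    """
    if isinstance(sweep, ThresholdSweepResult):
        sweep = sweep.results
    return sum(1 for r in sweep.values() if r.pvalue < alpha) >= min_k


# ---------------------------------------------------------------------------
# composite cognitive indices
# ---------------------------------------------------------------------------

def build_composite(
    scores: pd.DataFrame,
    index_def: dict[str, int],
    groups: pd.Series,
    logger=None,
) -> pd.Series:
    """Mean of z-scored test scores, with age-group-mean imputation.

    Each test in ``index_def`` (test name -> orientation sign, -1 for tests
    where larger raw values mean worse performance, e.g. completion times) is
    z-scored over the full sample, sign-flipped where inverse, and missing
    entries are replaced by the subject's age-group mean of that test's
    z-scores. Subjects missing every test of the index get a missing
    composite. Zero-variance tests contribute 0 for everyone.
    """
    if not index_def:
        raise ValueError("index definition references no tests")
    missing_cols = set(index_def) - set(scores.columns)
    if missing_cols:
        raise ValueError(f"tests absent from score table: {sorted(missing_cols)}")
    groups = pd.Series(groups, index=scores.index)

    observed = scores[list(index_def)].apply(
        pd.to_numeric, errors="coerce"
    ).notna()
    zcols = {}
    for test, sign in index_def.items():
        if sign not in (-1, 1):
            raise ValueError(f"orientation for {test!r} must be +1 or -1")
        x = pd.to_numeric(scores[test], errors="coerce")
        sd = x.std(ddof=1)
        if not sd or np.isnan(sd):
            if logger is not None:
                logger.warning("test %r has zero variance; contributes 0", test)
            z = pd.Series(np.where(x.notna(), 0.0, np.nan), index=x.index)
        else:
            z = sign * (x - x.mean()) / sd
        # age-group-mean imputation in z space
        z = z.fillna(z.groupby(groups).transform("mean"))
        zcols[test] = z

    zmat = pd.DataFrame(zcols)
    composite = zmat.mean(axis=1, skipna=False)
    all_missing = ~observed.any(axis=1)
    if all_missing.any() and logger is not None:
        logger.warning(
            "%d subject(s) missing all tests of the index", int(all_missing.sum())
        )
    composite[all_missing] = np.nan
    return composite


# ---------------------------------------------------------------------------
# distributional gates
# ---------------------------------------------------------------------------

def _two_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    a, b = (values[groups == lv] for lv in levels)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    return a, b, levels


def levene_center_median(values, groups) -> TestResult:
    """Brown-Forsythe variant of Levene's homogeneity-of-variance test."""
    a, b, _ = _two_groups(values, groups)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("no variance in either group")
    stat, p = sps.levene(a, b, center="median")
    return TestResult("F", float(stat), (1.0, float(len(a) + len(b) - 2)), float(p),
                      direction=float(np.sign(np.var(b, ddof=1) - np.var(a, ddof=1))))


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (gate for rank-based procedures)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("no variance in sample")
    stat, p = sps.shapiro(x)
    return TestResult("W", float(stat), (float(len(x)),), float(p))


# ---------------------------------------------------------------------------
# rank-based group inference
# ---------------------------------------------------------------------------

def _dummies(col: pd.Series) -> np.ndarray:
    """Drop-first dummy coding with deterministic (sorted) level order."""
    levels = sorted(pd.unique(col))
    if len(levels) < 2:
        raise ValueError("factor has a single level")
    return np.column_stack([(col == lv).to_numpy(float) for lv in levels[1:]])


def rank_anova(y, factor, covariate) -> TestResult:
    """Rank-ordered two-way ANOVA: F for ``factor`` adjusting for ``covariate``.

    y is replaced by mid-ranks over the listwise-complete analysis sample and
    fit with an additive linear model on factor + covariate (no interaction).
    The reported F is the type II main effect of the factor — for the
    additive model, the partial F comparing the full model against the model
    without the factor — with df (1, n - 3) for binary factor and covariate.
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "f": np.asarray(factor), "c": np.asarray(covariate)})
    df = df.dropna()
    n = len(df)
    if df["y"].nunique() < 2:
        raise ValueError("outcome is constant")
    for lv in pd.unique(df["f"]):
        if not np.isfinite(df.loc[df["f"] == lv, "y"]).any():
            raise ValueError(f"no usable outcome values in group {lv!r}")
    r = sps.rankdata(df["y"])  # mid-ranks

    Xf = _dummies(df["f"])
    Xc = _dummies(df["c"])
    ones = np.ones((n, 1))
    full = np.hstack([ones, Xf, Xc])
    reduced = np.hstack([ones, Xc])
    rss_full = _rss(full, r)
    rss_red = _rss(reduced, r)
    df_num = Xf.shape[1]
    df_den = n - full.shape[1]
    if df_den <= 0:
        raise ValueError("not enough observations for the model")
    F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    p = float(sps.f.sf(F, df_num, df_den))
    beta = np.linalg.lstsq(full, r, rcond=None)[0]
    return TestResult("F", float(F), (float(df_num), float(df_den)), p,
                      direction=float(np.sign(beta[1])))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def spearman_partial(x, y, covariates=()) -> TestResult:
    """Spearman partial correlation via double residualization of mid-ranks.

    All variables are rank-transformed; ranked x and ranked y are each
    regressed on the ranked covariates (with intercept) and the Pearson
    correlation of the residuals is reported, with a t-approximation p-value
    on df = n - 2 - #covariates. With no covariates this reduces exactly to
    the ordinary Spearman correlation.
    """
    cols = {"x": np.asarray(x, float), "y": np.asarray(y, float)}
    covariates = list(covariates)
    for i, c in enumerate(covariates):
        cols[f"c{i}"] = np.asarray(c, float)
    df = pd.DataFrame(cols).dropna()
    n = len(df)
    k = len(covariates)
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete rows, have {n}")
    ranked = df.apply(sps.rankdata, axis=0)

    rx, ry = ranked["x"].to_numpy(), ranked["y"].to_numpy()
    Z = np.column_stack(
        [np.ones(n)] + [ranked[f"c{i}"].to_numpy() for i in range(k)]
    )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("a ranked variable is constant after residualization")
    rs = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    dof = n - 2 - k
    if abs(rs) == 1.0:
        p = 0.0
    else:
        t = rs * np.sqrt(dof / (1 - rs**2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return TestResult("rs", rs, (float(dof),), p, direction=float(np.sign(rs)))


def robust_group_regression(y, predictors: pd.DataFrame) -> pd.DataFrame:
    """Huber M-estimation of group effects (robustness check for rank tests).

    Fits y ~ intercept + dummy-coded predictors with iteratively reweighted
    least squares (Huber tuning constant 1.345, max 50 iterations, tol 1e-8).
    Returns a coefficient table with columns coef, se, p and a ``converged``
    flag column (constant across rows).
    """
    import statsmodels.api as sm

    df = pd.DataFrame(predictors).copy()
    df["__y"] = np.asarray(y, dtype=float)
    df = df.dropna()
    yv = df.pop("__y").to_numpy()
    parts, names = [np.ones((len(df), 1))], ["intercept"]
    for col in df.columns:
        if df[col].dtype == object or df[col].dtype.name == "category":
            levels = sorted(pd.unique(df[col]))
            for lv in levels[1:]:
                parts.append((df[col] == lv).to_numpy(float)[:, None])
                names.append(f"{col}[{lv}]")
        else:
            parts.append(df[col].to_numpy(float)[:, None])
            names.append(str(col))
    X = np.hstack(parts)
    if len(yv) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.RLM(yv, X, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(maxiter=50, tol=1e-8)
    params_hist = res.fit_history.get("params", [])
    converged = True
    if len(params_hist) >= 50:
        last, prev = np.asarray(params_hist[-1]), np.asarray(params_hist[-2])
        converged = bool(np.max(np.abs(last - prev)) < 1e-6)
    t = res.params / res.bse
    p = 2 * sps.norm.sf(np.abs(t))
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": p, "converged": converged},
        index=names,
    )


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def chi_square_2x2(table, continuity: bool = False) -> TestResult:
    """Uncorrected (by default) Pearson chi-square on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=continuity)
    return TestResult("chi2", float(stat), (float(dof),), float(p))


def mann_whitney(values, groups) -> TestResult:
    """Two-sided Mann-Whitney U with mid-rank tie correction."""
    a, b, levels = _two_groups(values, groups)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    # direction: positive if second (sorted) group level tends higher
    direction = float(np.sign(res.statistic - len(a) * len(b) / 2)) * -1
    return TestResult("U", float(res.statistic),
                      (float(len(a)), float(len(b))), float(res.pvalue),
                      direction=direction)


def variance_ratio(values, groups) -> TestResult:
    """One-way dispersion comparison (Levene with mean centering), df (1, N-2)."""
    a, b, _ = _two_groups(values, groups)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("no variance in either group")
    stat, p = sps.levene(a, b, center="mean")
    return TestResult("F", float(stat), (1.0, float(len(a) + len(b) - 2)), float(p),
                      direction=float(np.sign(np.var(b, ddof=1) - np.var(a, ddof=1))))
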