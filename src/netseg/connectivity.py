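"""From ROI time series to thresholded binary graphs.

The weighted graph for a subject is the zero-lag Pearson correlation matrix
of the concatenated resting-state runs, with negative correlations and the
diagonal set to zero. Binarization is proportional ("sparsity") thresholding:
at threshold *t* the ``round(t * P)`` strongest positive correlations form
edges, where ``P = N(N-1)/2`` counts all unique ROI pairs.

Also computes the between-subject head-motion covariate: the percentage of
volumes flagged by standardized DVARS > 1.5 or framewise displacement
FD > 0.5 mm, averaged across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RoiTimeSeries",
    "WeightedAdjacency",
    "BinaryAdjacency",
    "MotionSeries",
    "concatenate_runs",
    "pearson_adjacency",
    "proportional_threshold",
    "percent_flagged_volumes",
    "ConnectivityTransformer",
]

#: motion flagging rule: standardized DVARS > 1.5 OR FD > 0.5 mm
DVARS_FLAG = 1.5
FD_FLAG_MM = 0.5


@dataclass
class RoiTimeSeries:
    """One run (or concatenation of runs) of BOLD signal, volumes x ROIs."""

    data: np.ndarray
    roi_names: tuple[str, ...]
    run_id: str = "run-1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_names = tuple(map(str, self.roi_names))
        if self.data.ndim != 2:
            raise ValueError("time series must be 2-D (volumes x ROIs)")
        if self.data.shape[0] < 2:
            raise ValueError("time series needs at least 2 volumes")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_names)} ROI names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(self.roi_names))

    @classmethod
    def from_file(cls, path, run_id: str | None = None) -> "RoiTimeSeries":
        """Read a tab/comma-separated volumes x ROIs table with a header row."""
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df.to_numpy(float), tuple(df.columns), run_id or str(path))


@dataclass
class WeightedAdjacency:
    """Symmetric nonnegative weight matrix with a zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("adjacency must be exactly symmetric")
        if np.diagonal(w).any():
            raise ValueError("diagonal must be exactly zero")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative (negatives removed)")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        """P: number of unique off-diagonal ROI pairs."""
        n = self.n_rois
        return n * (n - 1) // 2


@dataclass
class BinaryAdjacency:
    """0/1 graph obtained at one proportional threshold."""

    adjacency: np.ndarray
    threshold: float
    n_edges: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
        if not np.array_equal(a, a.T) or np.diagonal(a).any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(np.uint8)
        self.n_edges = int(np.triu(self.adjacency, 1).sum())

    @property
    def n_rois(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class MotionSeries:
    """Per-volume FD (mm) and standardized DVARS for one run."""

    fd: np.ndarray
    dvars: np.ndarray
    run_id: str = "run-1"

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.fd.shape != self.dvars.shape or self.fd.ndim != 1:
            raise ValueError("fd and dvars must be 1-D and equal length")
        if self.fd.size == 0:
            raise ValueError("empty motion series")
        if (self.fd < 0).any():
            raise ValueError("FD must be non-negative")


def concatenate_runs(
    runs: list[RoiTimeSeries], keep_from: int = 5, keep_to: int = 200
) -> RoiTimeSeries:
    """Trim each run to TRs ``keep_from..keep_to`` (1-based, inclusive) and stack.

    The default window 5-200 drops non-steady-state volumes and equalizes run
    lengths; two 200-volume runs yield a 392-volume concatenated series.
    """
    if not runs:
        raise ValueError("no runs given")
    if keep_from < 1 or keep_to < keep_from:
        raise ValueError(f"invalid keep range [{keep_from}, {keep_to}]")
    names = runs[0].roi_names
    for r in runs[1:]:
        if r.roi_names != names:
            raise ValueError("runs have mismatched ROI names")
    for r in runs:
        if keep_to > r.n_volumes:
            raise ValueError(
                f"keep range [{keep_from}, {keep_to}] exceeds run "
                f"{r.run_id!r} length {r.n_volumes}"
            )
    data = np.vstack([r.data[keep_from - 1 : keep_to] for r in runs])
    return RoiTimeSeries(data, names, run_id="+".join(r.run_id for r in runs))


def pearson_adjacency(ts: RoiTimeSeries) -> WeightedAdjacency:
    """Zero-lag Pearson correlations, negatives and diagonal zeroed."""
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        rois = [ts.roi_names[i] for i in dead]
        raise ValueError(f"zero-variance ROI columns: {rois}")
    r = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    w = np.clip(r, 0.0, None)
    w = np.minimum(w, w.T)  # enforce exact symmetry against fp asymmetry
    return WeightedAdjacency(w)


def _round_half_away(x: float) -> int:
    """round() with halves away from zero, platform-independent."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _ranked_pairs(W: WeightedAdjacency):
    """Upper-triangle pair indices ordered by descending weight, then pair index.

    Returns (rows, cols, order, weights) where ``order`` ranks all P pairs;
    only strictly positive weights are eligible to become edges.
    """
    iu, ju = np.triu_indices(W.n_rois, k=1)
    w = W.weights[iu, ju]
    order = np.lexsort((np.arange(w.size), -w))  # weight desc, pair index asc
    return iu, ju, order, w


def proportional_threshold(W: WeightedAdjacency, t: float) -> BinaryAdjacency:
    """Keep the ``round(t * P)`` strongest positive weights as edges.

    P counts all unique off-diagonal pairs (19,900 for 200 ROIs). The quota is
    rounded half-away-from-zero; if fewer strictly positive weights exist than
    the quota, only those become edges. Ties are broken by descending weight
    then ascending (row, column) pair index, so the edge set is deterministic.
    """
    if not 0 < t <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    iu, ju, order, w = _ranked_pairs(W)
    quota = _round_half_away(t * W.n_pairs)
    k = min(quota, int((w > 0).sum()))
    adj = np.zeros_like(W.weights, dtype=np.uint8)
    if k > 0:
        sel = order[:k]
        adj[iu[sel], ju[sel]] = 1
        adj |= adj.T
    return BinaryAdjacency(adj, threshold=float(t))


def percent_flagged_volumes(motion: list[MotionSeries]) -> float:
    """Mean across runs of the % of volumes with DVARS > 1.5 or FD > 0.5 mm."""
    if not motion:
        raise ValueError("no motion series given")
    per_run = [
        100.0 * np.mean((m.dvars > DVARS_FLAG) | (m.fd > FD_FLAG_MM)) for m in motion
    ]
    return float(np.mean(per_run))


class ConnectivityTransformer(BaseEstimator, TransformerMixin):
    """Subject-level time series -> weighted adjacency matrices.

    ``transform`` takes a list with one entry per subject, each entry either a
    single volumes x ROIs array / :class:`RoiTimeSeries` or a list of runs to
    be trimmed and concatenated first, and returns an array of shape
    ``(n_subjects, n_rois, n_rois)``.

    Parameters
    ----------
    keep_from, keep_to : int
        1-based inclusive TR window applied to each run before concatenation.
        Ignored for subjects passed as a single pre-concatenated series.
    """

    def __init__(self, keep_from: int = 5, keep_to: int = 200):
        self.keep_from = keep_from
        self.keep_to = keep_to

    def fit(self, X, y=None):
        return self

    def _as_series(self, subject) -> RoiTimeSeries:
        if isinstance(subject, RoiTimeSeries):
            return subject
        if isinstance(subject, np.ndarray):
            names = tuple(f"ROI_{i + 1}" for i in range(subject.shape[1]))
            return RoiTimeSeries(subject, names)
        runs = [
            r
            if isinstance(r, RoiTimeSeries)
            else RoiTimeSeries(r, tuple(f"ROI_{i + 1}" for i in range(r.shape[1])))
            for r in subject
        ]
        return concatenate_runs(runs, self.keep_from, self.keep_to)

    def transform(self, X) -> np.ndarray:
        mats = [pearson_adjacency(self._as_series(s)).weights for s in X]
        return np.stack(mats)
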