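"""Binarized system segregation, globally and per subnetwork.

System segregation (SS) measures the relative excess of within-network over
between-network connectivity in a binarized graph:

    SS = (Bw - Bb) / Bw

where ``Bw`` is the proportion of *possible* within-network edges that
survived thresholding and ``Bb`` the proportion of possible between-network
edges that survived. For the global score, within-pairs are all ROI pairs
sharing a network label and between-pairs all others. For a single
subnetwork's score, within-pairs lie inside that network and between-pairs
bridge it to any other network.

SS is undefined (recorded as missing) when ``Bw = 0``, which can occur at the
sparsest thresholds on small graphs; downstream statistics exclude missing
cells pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import (
    BinaryAdjacency,
    WeightedAdjacency,
    _ranked_pairs,
    _round_half_away,
)
from .parcellation import Parcellation

__all__ = [
    "DEFAULT_THRESHOLDS",
    "GLOBAL_SCOPE",
    "SegregationProfile",
    "system_segregation",
    "subnetwork_segregation",
    "segregation_sweep",
    "SegregationTransformer",
]

#: default sparsity grid: 0.05 to 0.50 in steps of 0.05
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.05, 2))

#: scope label for the whole-graph score
GLOBAL_SCOPE = "global"


def _segregation_from_counts(
    surv_within: float, n_within: int, surv_between: float, n_between: int
) -> tuple[float, float, float]:
    """(Bw, Bb, SS) from surviving/possible edge counts; SS is nan if Bw = 0."""
    bw = surv_within / n_within if n_within else 0.0
    bb = surv_between / n_between if n_between else 0.0
    ss = (bw - bb) / bw if bw > 0 else float("nan")
    return bw, bb, ss


def _check_dims(n_rois: int, parc: Parcellation) -> None:
    if n_rois != parc.n_rois:
        raise ValueError(f"graph has {n_rois} ROIs but parcellation {parc.n_rois}")


def system_segregation(B: BinaryAdjacency, parc: Parcellation) -> float:
    """Global SS of a binarized graph; nan when no within-network edge survives."""
    _check_dims(B.n_rois, parc)
    labels = parc.labels_array()
    iu, ju = np.triu_indices(B.n_rois, k=1)
    edge = B.adjacency[iu, ju].astype(bool)
    same = labels[iu] == labels[ju]
    _, _, ss = _segregation_from_counts(
        int((edge & same).sum()), int(same.sum()),
        int((edge & ~same).sum()), int((~same).sum()),
    )
    return ss


def subnetwork_segregation(
    B: BinaryAdjacency, parc: Parcellation, network: str
) -> float:
    """SS of one named network: its internal pairs vs its bridges to all others."""
    _check_dims(B.n_rois, parc)
    if network not in parc.networks:
        raise ValueError(f"unknown network {network!r}; known: {list(parc.networks)}")
    labels = parc.labels_array()
    code = list(parc.networks).index(network)
    iu, ju = np.triu_indices(B.n_rois, k=1)
    edge = B.adjacency[iu, ju].astype(bool)
    in_i = (labels[iu] == code).astype(int) + (labels[ju] == code).astype(int)
    within = in_i == 2
    bridge = in_i == 1
    _, _, ss = _segregation_from_counts(
        int((edge & within).sum()), int(within.sum()),
        int((edge & bridge).sum()), int(bridge.sum()),
    )
    return ss


@dataclass
class SegregationProfile:
    """Per-subject SS across thresholds and scopes, with Bw/Bb kept for audit.

    ``table`` is tidy long-format with columns
    ``subject, threshold, scope, Bw, Bb, SS`` where scope is ``"global"`` or a
    network label and SS is NaN where undefined.
    """

    subject: str
    table: pd.DataFrame

    def value(self, threshold: float, scope: str = GLOBAL_SCOPE) -> float:
        m = self.table[
            np.isclose(self.table["threshold"], threshold)
            & (self.table["scope"] == scope)
        ]
        if m.empty:
            raise KeyError(f"no cell for threshold={threshold}, scope={scope!r}")
        return float(m["SS"].iloc[0])


def segregation_sweep(
    W: WeightedAdjacency,
    parc: Parcellation,
    thresholds=DEFAULT_THRESHOLDS,
    subject: str = "subject",
) -> SegregationProfile:
    """Global and per-network SS at every threshold of the sparsity sweep.

    Equivalent to binarizing at each threshold and calling the two score
    functions, but computed from a single ranked ordering of the pairs:
    because the edge set at a smaller quota is a prefix of the edge set at a
    larger one (same deterministic tie-break), surviving-edge counts per pair
    class are prefix sums over the ranked pairs.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {t}")
    _check_dims(W.n_rois, parc)

    labels = parc.labels_array()
    iu, ju, order, w = _ranked_pairs(W)
    n_pos = int((w > 0).sum())
    li, lj = labels[iu][order], labels[ju][order]

    # per-class membership of the ranked pairs; prefix sums give surviving
    # counts for any quota k
    same = li == lj
    classes: dict[str, tuple[np.ndarray, np.ndarray]] = {
        GLOBAL_SCOPE: (same, ~same)
    }
    for code, net in enumerate(parc.networks):
        hits = (li == code).astype(int) + (lj == code).astype(int)
        classes[net] = (hits == 2, hits == 1)

    cum = {
        scope: (np.concatenate(([0], np.cumsum(wi))),
                np.concatenate(([0], np.cumsum(bi))))
        for scope, (wi, bi) in classes.items()
    }
    possible = {s: (int(wi.sum()), int(bi.sum())) for s, (wi, bi) in classes.items()}

    P = W.n_pairs
    rows = []
    for t in thresholds:
        k = min(_round_half_away(t * P), n_pos)
        for scope in classes:
            nw, nb = possible[scope]
            bw, bb, ss = _segregation_from_counts(
                int(cum[scope][0][k]), nw, int(cum[scope][1][k]), nb
            )
            rows.append((subject, float(t), scope, bw, bb, ss))
    table = pd.DataFrame(
        rows, columns=["subject", "threshold", "scope", "Bw", "Bb", "SS"]
    )
    return SegregationProfile(subject, table)


class SegregationTransformer(BaseEstimator, TransformerMixin):
    """Weighted adjacency matrices -> SS feature matrix for a subject stack.

    ``transform`` accepts an array of shape ``(n_subjects, n_rois, n_rois)``
    (or a list of :class:`WeightedAdjacency`) and returns a matrix of shape
    ``(n_subjects, n_scopes * n_thresholds)`` whose columns follow
    :meth:`get_feature_names_out` — global first, then each network, each
    across the threshold grid.

    Parameters
    ----------
    parcellation : Parcellation
        ROI-to-network membership; must match the adjacency dimension.
    thresholds : sequence of float
        Proportional thresholds in (0, 1]; default is the 0.05..0.50 grid.
    """

    def __init__(
        self,
        parcellation: Parcellation,
        thresholds=DEFAULT_THRESHOLDS,
    ):
        self.parcellation = parcellation
        self.thresholds = tuple(thresholds)

    @property
    def _scopes(self) -> list[str]:
        return [GLOBAL_SCOPE, *self.parcellation.networks]

    def fit(self, X, y=None):
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [f"SS_{s}_t{t:.2f}" for s in self._scopes for t in self.thresholds]
        )

    def profiles(self, X, subjects=None) -> pd.DataFrame:
        """Tidy long-format SS table for a stack of weighted adjacencies."""
        mats = [x if isinstance(x, WeightedAdjacency) else WeightedAdjacency(x)
                for x in X]
        if subjects is None:
            subjects = [f"sub-{i + 1:04d}" for i in range(len(mats))]
        frames = [
            segregation_sweep(m, self.parcellation, self.thresholds, subject=s).table
            for m, s in zip(mats, subjects)
        ]
        return pd.concat(frames, ignore_index=True)

    def transform(self, X) -> np.ndarray:
        long = self.profiles(X)
        wide = long.pivot_table(
            index="subject", columns=["scope", "threshold"], values="SS",
            sort=False, dropna=False,
        )
        cols = [(s, float(t)) for s in self._scopes for t in self.thresholds]
        # preserve input subject order (pivot sorts lexically)
        order = pd.unique(long["subject"])
        return wide.loc[order, cols].to_numpy(float)
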