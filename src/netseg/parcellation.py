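"""ROI-to-network parcellation.

A :class:`Parcellation` assigns each cortical region of interest (ROI) to
exactly one functional network. The analysis convention is the 7-network
scheme (visual, somatomotor, dorsal attention, ventral attention, limbic,
frontoparietal, default mode) with 200 ROIs named
``7Networks_<hemi>_<network>_<k>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical 7-network short labels, in conventional order
SEVEN_NETWORKS = ("Vis", "SMN", "DAN", "VAN", "Lim", "FPN", "DMN")

# per-hemisphere ROI counts used by the default 200-ROI table (sum = 100)
_DEFAULT_SIZES = {
    "Vis": 15,
    "SMN": 16,
    "DAN": 13,
    "VAN": 12,
    "Lim": 10,
    "FPN": 13,
    "DMN": 21,
}


@dataclass(frozen=True)
class Parcellation:
    """Ordered ROI names plus a map from ROI to network label.

    Invariants enforced at construction: every ROI has exactly one label,
    at least two networks, and every network has at least two ROIs.
    """

    roi_names: tuple[str, ...]
    roi_networks: tuple[str, ...]
    networks: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.roi_networks):
            raise ValueError("roi_names and roi_networks must have equal length")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("duplicate ROI names")
        nets = tuple(dict.fromkeys(self.roi_networks))  # stable order
        if len(nets) < 2:
            raise ValueError("parcellation needs at least 2 networks")
        counts = pd.Series(self.roi_networks).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"networks with < 2 ROIs: {list(small.index)}")
        object.__setattr__(self, "networks", nets)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def labels_array(self) -> np.ndarray:
        """Integer network code per ROI (codes index into ``self.networks``)."""
        code = {net: i for i, net in enumerate(self.networks)}
        return np.array([code[n] for n in self.roi_networks], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"roi": self.roi_names, "network": self.roi_networks})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        """Build from a table with columns ``roi`` and ``network``."""
        missing = {"roi", "network"} - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        return cls(tuple(df["roi"].astype(str)), tuple(df["network"].astype(str)))

    @classmethod
    def from_csv(cls, path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep=None, engine="python"))


def default_parcellation(n_rois: int = 200, n_networks: int = 7) -> Parcellation:
    """A default ROI-to-network table following the 7-network naming scheme.

    For the standard 200-ROI / 7-network case, ROIs are named
    ``7Networks_{LH,RH}_<net>_<k>`` with fixed per-network sizes. This is a
    synthetic default assignment generated in code — it follows the published
    naming convention and realistic network sizes but is not the published
    atlas ordering, which is irrelevant for simulated cohorts where membership
    defines the generative blocks. For real data, load the atlas's own
    membership table via :meth:`Parcellation.from_csv`.

    Other (n_rois, n_networks) combinations distribute ROIs as evenly as
    possible over generically named networks — useful for small test graphs.
    """
    if n_rois == 200 and n_networks == 7:
        names, nets = [], []
        for hemi in ("LH", "RH"):
            for net in SEVEN_NETWORKS:
                for k in range(1, _DEFAULT_SIZES[net] + 1):
                    names.append(f"7Networks_{hemi}_{net}_{k}")
                    nets.append(net)
        return Parcellation(tuple(names), tuple(nets))

    if n_networks < 2 or n_rois < 2 * n_networks:
        raise ValueError("need >= 2 networks and >= 2 ROIs per network")
    labels = (
        list(SEVEN_NETWORKS[:n_networks])
        if n_networks <= 7
        else [f"Net{i + 1}" for i in range(n_networks)]
    )
    base, rem = divmod(n_rois, n_networks)
    names, nets = [], []
    for i, net in enumerate(labels):
        size = base + (1 if i < rem else 0)
        for k in range(1, size + 1):
            names.append(f"{net}_{k}")
            nets.append(net)
    return Parcellation(tuple(names), tuple(nets))
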