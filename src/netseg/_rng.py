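"""Named random substreams derived from one master seed.

Every source of randomness in the package draws from a substream keyed by a
stage name, so that e.g. regenerating bootstrap draws never perturbs the
cohort, and vice versa.
"""

from __future__ import annotations

import numpy as np

# fixed stream ids; order is part of the reproducibility contract
_STREAMS = {
    "cohort": 0,
    "timeseries": 1,
    "bootstrap": 2,
    "folds": 3,
    "missing": 4,
}


def substream(master_seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Return a Generator for a named substream of ``master_seed``.

    ``extra`` indices (e.g. a subject index) further split the stream so that
    per-subject draws are independent and order-insensitive.
    """
    if stream not in _STREAMS:
        raise KeyError(f"unknown stream {stream!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(_STREAMS[stream], *map(int, extra))
    )
    return np.random.default_rng(ss)
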