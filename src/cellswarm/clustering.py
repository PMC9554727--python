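"""Force-mode coding, model clustering and aggregation.

Each learned model is summarized by an 8-bit code marking which of the
eight (force x angular-mode) components are active, in the order

    {ar0, ar1, ar2, align0, align1, align2, drag0, drag1}.

Models sharing a code form a cluster; the largest cluster is averaged
coefficient-wise and lightly re-thresholded into a candidate species
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import ForceLibrary, MODE_NAMES
from .regression import CellModel


def force_mode_code(w: np.ndarray, library: ForceLibrary) -> str:
    """8-bit force-mode code of a coefficient vector, e.g. '10111010'.

    Bit m is 1 iff some nonzero coefficient activates mode m.  Shifted
    cosine terms (1 + cos n th) with n >= 1 activate both mode 0 and
    mode n of their block.
    """
    w = np.asarray(w)
    if w.shape != (library.size,):
        raise ValueError("coefficient length does not match library")
    bits = [0] * len(MODE_NAMES)
    for idx in np.flatnonzero(w):
        for mode in library.terms[idx].modes:
            bits[mode] = 1
    return "".join(map(str, bits))


def partition_by_code(models: list[CellModel], library: ForceLibrary
                      ) -> tuple[dict[str, list[int]], str]:
    """Group model indices by force-mode code; return (clusters, largest).

    The largest cluster breaks ties toward the smallest numeric code.
    """
    if not models:
        raise ValueError("no models to partition")
    clusters: dict[str, list[int]] = {}
    for k, mdl in enumerate(models):
        clusters.setdefault(force_mode_code(mdl.w, library), []).append(k)
    largest = min(clusters, key=lambda c: (-len(clusters[c]), int(c, 2)))
    return clusters, largest


@dataclass
class AggregateModel:
    """Averaged, re-thresholded coefficients of one model cluster."""

    w: np.ndarray
    code: str
    members: list[int]

    @property
    def size(self) -> int:
        return len(self.members)


def aggregate_cluster(models: list[CellModel], members: list[int],
                      library: ForceLibrary, lambda_log: float = 4.0
                      ) -> AggregateModel:
    """Uniform coefficient average over a cluster, then drop entries more
    than ``lambda_log`` orders of magnitude below the largest."""
    if not members:
        raise ValueError("cannot aggregate an empty cluster")
    W = np.stack([models[k].w for k in members])
    wbar = W.mean(axis=0)
    mx = np.max(np.abs(wbar))
    if mx > 0:
        wbar[np.abs(wbar) < 10.0 ** (-lambda_log) * mx] = 0.0
    return AggregateModel(w=wbar, code=force_mode_code(wbar, library),
                          members=list(members))
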