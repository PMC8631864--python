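"""Preferred information-flow direction and index.

Given a non-negative effective-connectivity matrix G, the preferred
direction between regions i and j is

    P[i, j] = G[i, j] / (G[i, j] + G[j, i]),

with the 0/0 case defined as 0.5 (no information either way).  P[i, j] > 0.5
means region i predominantly sends information to region j.  The per-region
preferred-flow index is the mean of P[i, j] over all j != i; values above
0.5 flag net senders, below 0.5 net receivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gca import EffectiveConnectivity

__all__ = ["PreferredFlow", "preferred_direction", "preferred_index", "edge_features"]


@dataclass
class PreferredFlow:
    """Antisymmetric preferred-direction matrix plus the per-node index.

    ``p_matrix[i, j] + p_matrix[j, i] == 1`` off the diagonal; the diagonal
    is stored as 0.5 and excluded from the index.
    """

    p_matrix: np.ndarray
    index: np.ndarray
    region_ids: np.ndarray = None
    source_params: dict = None

    def __post_init__(self) -> None:
        self.p_matrix = np.asarray(self.p_matrix, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        n = self.p_matrix.shape[0]
        if self.p_matrix.shape != (n, n):
            raise ValueError("p_matrix must be square")
        if self.index.shape != (n,):
            raise ValueError("index length must match p_matrix")
        if np.any(self.p_matrix < 0) or np.any(self.p_matrix > 1):
            raise ValueError("p_matrix entries must lie in [0, 1]")
        if self.region_ids is None:
            self.region_ids = np.arange(1, n + 1)
        self.region_ids = np.asarray(self.region_ids, dtype=int)

    @property
    def n_regions(self) -> int:
        return self.p_matrix.shape[0]


def preferred_direction(g, region_ids=None, source_params=None) -> PreferredFlow:
    """Convert an effective-connectivity matrix into a PreferredFlow.

    Accepts an :class:`EffectiveConnectivity` or a bare non-negative square
    matrix.  Scale-invariant: multiplying g by any c > 0 leaves the result
    unchanged.
    """
    if isinstance(g, EffectiveConnectivity):
        if region_ids is None:
            region_ids = g.region_ids
        if source_params is None:
            source_params = g.params.to_dict()
        g = g.g
    g = np.asarray(g, dtype=float)
    n = g.shape[0]
    if g.shape != (n, n):
        raise ValueError("g must be square")
    if np.any(g < 0):
        raise ValueError("g must be non-negative")
    total = g + g.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, g / np.where(total > 0, total, 1.0), 0.5)
    np.fill_diagonal(p, 0.5)
    # enforce exact antisymmetry against floating-point round-off
    iu = np.triu_indices(n, 1)
    p[(iu[1], iu[0])] = 1.0 - p[iu]
    index = preferred_index(p)
    return PreferredFlow(p_matrix=p, index=index, region_ids=region_ids,
                         source_params=source_params)


def preferred_index(p_matrix: np.ndarray) -> np.ndarray:
    """Per-node mean preferred direction over all other nodes."""
    p = np.asarray(p_matrix, dtype=float)
    n = p.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions for a flow index")
    return (p.sum(axis=1) - np.diag(p)) / (n - 1)


def edge_features(p_matrix, region_ids=None):
    """Flatten the strict upper triangle into a feature vector.

    The lower triangle is redundant (``P[j, i] = 1 - P[i, j]``), so only the
    ``N (N - 1) / 2`` upper-triangle entries are carried into statistics and
    machine learning.  Returns ``(values, names)`` with names like
    ``"region_3->region_7"`` using region labels.
    """
    if isinstance(p_matrix, PreferredFlow):
        if region_ids is None:
            region_ids = p_matrix.region_ids
        p_matrix = p_matrix.p_matrix
    p = np.asarray(p_matrix, dtype=float)
    n = p.shape[0]
    if region_ids is None:
        region_ids = np.arange(1, n + 1)
    iu = np.triu_indices(n, 1)
    values = p[iu]
    names = [f"region_{region_ids[i]}->region_{region_ids[j]}"
             for i, j in zip(*iu)]
    return values, names
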