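"""Model/Results front end.

``InformationFlow`` is built from a subject's regional time series; its
``fit()`` estimates the directed-connectivity matrix and the preferred-flow
measures and returns an ``InformationFlowResults`` carrying them together
with a ``summary()`` table.  ``GroupFlowComparison`` is built from two
groups of fitted flows and its ``fit()`` runs the edge- and node-wise
FDR-corrected tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gca import GcaParams, EffectiveConnectivity, connectivity_matrix
from .flow import PreferredFlow, preferred_direction, edge_features
from .inference import StatReport, edgewise_test, nodewise_test
from .timeseries import RegionTimeSeries

__all__ = ["InformationFlow", "InformationFlowResults",
           "GroupFlowComparison", "GroupFlowResults"]


class InformationFlow:
    """Directed information-flow model for one subject's regional series.

    Parameters
    ----------
    data : RegionTimeSeries or T x N array
    tr : float, required when ``data`` is a bare array
    params : GcaParams, estimator configuration
    """

    def __init__(self, data, tr: float = None, region_ids=None,
                 params: GcaParams = None):
        if isinstance(data, RegionTimeSeries):
            self.ts = data
        else:
            if tr is None:
                raise ValueError("tr (seconds) is required with array input")
            self.ts = RegionTimeSeries(data=np.asarray(data, dtype=float),
                                       tr=tr, region_ids=region_ids)
        self.params = params if params is not None else GcaParams()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, tr: float,
                       params: GcaParams = None) -> "InformationFlow":
        """Columns are regions (headers parsed as integer region ids where
        possible), rows are time points."""
        try:
            ids = [int(c) for c in frame.columns]
        except (TypeError, ValueError):
            ids = list(range(1, frame.shape[1] + 1))
        return cls(frame.to_numpy(dtype=float), tr=tr, region_ids=ids,
                   params=params)

    def fit(self) -> "InformationFlowResults":
        conn = connectivity_matrix(self.ts, self.params)
        flow = preferred_direction(conn)
        return InformationFlowResults(self, conn, flow)


class InformationFlowResults:
    """Fitted connectivity and preferred-flow measures for one subject."""

    def __init__(self, model: InformationFlow, connectivity: EffectiveConnectivity,
                 flow: PreferredFlow):
        self.model = model
        self.connectivity = connectivity
        self.flow = flow

    @property
    def gca_matrix(self) -> np.ndarray:
        return self.connectivity.g

    @property
    def preferred_matrix(self) -> np.ndarray:
        return self.flow.p_matrix

    @property
    def index(self) -> np.ndarray:
        return self.flow.index

    def edge_feature_frame(self) -> pd.DataFrame:
        values, names = edge_features(self.flow)
        return pd.DataFrame({"edge": names, "preferred_direction": values})

    def summary(self) -> str:
        ids = self.connectivity.region_ids
        lines = [
            "Information flow results",
            "=" * 52,
            f"regions: {self.connectivity.n_regions}   "
            f"timepoints used: {self.connectivity.n_timepoints_used}   "
            f"TR: {self.model.ts.tr:g} s",
            f"estimator: {self.connectivity.params.kernel} "
            f"(p={self.connectivity.params.order}, "
            f"residuals={self.connectivity.params.residual_mode})",
            "-" * 52,
            f"{'region':>8} {'flow index':>12} {'role':>10}",
        ]
        for rid, idx in zip(ids, self.flow.index):
            role = "sender" if idx > 0.5 else ("receiver" if idx < 0.5 else "neutral")
            lines.append(f"{rid:>8} {idx:>12.4f} {role:>10}")
        return "\n".join(lines)


class GroupFlowComparison:
    """Edge- and node-wise group comparison of preferred-flow measures."""

    def __init__(self, flows_a: list, flows_b: list, level: float = 0.05,
                 variant: str = "student",
                 group_labels=("group_a", "group_b")):
        self.flows_a = list(flows_a)
        self.flows_b = list(flows_b)
        self.level = level
        self.variant = variant
        self.group_labels = tuple(group_labels)

    def fit(self) -> "GroupFlowResults":
        edges = edgewise_test(self.flows_a, self.flows_b, self.level, self.variant)
        nodes = nodewise_test(self.flows_a, self.flows_b, self.level, self.variant)
        return GroupFlowResults(self, edges, nodes)


class GroupFlowResults:
    def __init__(self, model: GroupFlowComparison, edge_report: StatReport,
                 node_report: StatReport):
        self.model = model
        self.edge_report = edge_report
        self.node_report = node_report

    def summary(self) -> str:
        la, lb = self.model.group_labels
        lines = [
            "Group information-flow comparison",
            "=" * 52,
            f"{la}: n={len(self.model.flows_a)}   {lb}: n={len(self.model.flows_b)}",
            f"test: {self.model.variant} t, BH-FDR q < {self.model.level:g}",
            f"significant edges: {self.edge_report.n_significant} / "
            f"{len(self.edge_report.table)}",
            f"significant nodes: {self.node_report.n_significant} / "
            f"{len(self.node_report.table)}",
        ]
        sig = self.edge_report.table[self.edge_report.table["significant"]]
        for _, row in sig.head(15).iterrows():
            lines.append(
                f"  {row['id']}: t={row['t']:.2f} q={row['q']:.4f} "
                f"({row['direction']} in {lb})")
        return "\n".join(lines)
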