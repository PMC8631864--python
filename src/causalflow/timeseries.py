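"""Core in-memory containers for regional BOLD time series and confounds."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionTimeSeries:
    """A T x N matrix of per-region mean BOLD signal.

    Parameters
    ----------
    data : ndarray, shape (T, N)
        One column per region, one row per acquired volume.
    tr : float
        Sampling interval (repetition time) in seconds.
    region_ids : ndarray of int, shape (N,)
        Unique integer region labels, ascending.
    subject_id : str
        Free-form subject identifier.
    """

    data: np.ndarray
    tr: float
    region_ids: np.ndarray = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if self.region_ids is None:
            self.region_ids = np.arange(1, self.data.shape[1] + 1)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.region_ids.shape != (self.data.shape[1],):
            raise ValueError("region_ids length must match number of columns")
        if len(np.unique(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def require_min_timepoints(self, minimum: int = 50) -> "RegionTimeSeries":
        if self.n_timepoints < minimum:
            raise ValueError(
                f"time series has {self.n_timepoints} volumes; at least {minimum} required"
            )
        return self

    def copy_with(self, data: np.ndarray) -> "RegionTimeSeries":
        return RegionTimeSeries(
            data=np.array(data, dtype=float),
            tr=self.tr,
            region_ids=self.region_ids.copy(),
            subject_id=self.subject_id,
        )


@dataclass
class ConfoundMatrix:
    """T x K nuisance design (motion expansion, global/WM/CSF signals, ...)."""

    data: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("confound data must be a T x K matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("confounds contain non-finite values")
        if not self.names:
            self.names = [f"confound_{k}" for k in range(self.data.shape[1])]
        if len(self.names) != self.data.shape[1]:
            raise ValueError("names length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]
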