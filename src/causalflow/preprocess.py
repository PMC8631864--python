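"""Signal preparation: atlas extraction, nuisance regression, band-pass filtering.

The pipeline consumes spatially normalized 4D images (or precomputed region
matrices); registration steps are out of scope.  The processing order is
nuisance regression first, then band-pass filtering.
"""

from __future__ import annotations

import numpy as np

from .timeseries import ConfoundMatrix, RegionTimeSeries

__all__ = [
    "extract_region_signals",
    "expand_motion_24",
    "regress_confounds",
    "bandpass",
]


def _as_array(img):
    """Accept a nibabel spatial image or a bare ndarray."""
    if hasattr(img, "get_fdata"):
        return np.asanyarray(img.dataobj)
    return np.asarray(img)


def extract_region_signals(image4d, label_volume, tr: float = 3.0,
                           subject_id: str = "") -> RegionTimeSeries:
    """Average the 4D signal over each atlas label.

    Parameters
    ----------
    image4d : nibabel image or ndarray, shape (X, Y, Z, T)
    label_volume : nibabel image or ndarray of int, shape (X, Y, Z)
        0 marks background; each positive integer is a region.
    tr : float
        Repetition time in seconds attached to the result.

    Returns
    -------
    RegionTimeSeries
        Regions ordered by ascending label id.
    """
    data = _as_array(image4d).astype(float)
    labels = _as_array(label_volume)
    if data.ndim != 4:
        raise ValueError("image4d must be 4-dimensional (X, Y, Z, T)")
    if labels.ndim != 3:
        raise ValueError("label_volume must be 3-dimensional")
    if labels.shape != data.shape[:3]:
        raise ValueError(
            f"voxel grid mismatch: image {data.shape[:3]} vs labels {labels.shape}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        if np.any(labels != np.round(labels)):
            raise ValueError("label volume must contain integer labels")
        labels = labels.astype(int)
    if np.any(labels < 0):
        raise ValueError("labels must be non-negative (0 = background)")

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label volume contains no nonzero regions")

    T = data.shape[3]
    flat = data.reshape(-1, T)
    flat_labels = labels.reshape(-1)
    out = np.empty((T, ids.size))
    for k, lab in enumerate(ids):
        mask = flat_labels == lab
        if not mask.any():  # pragma: no cover - unique() guarantees presence
            raise ValueError(f"label {lab} has no voxels")
        out[:, k] = flat[mask].mean(axis=0)
    return RegionTimeSeries(data=out, tr=tr, region_ids=ids, subject_id=subject_id)


def expand_motion_24(motion6: np.ndarray) -> ConfoundMatrix:
    """Expand 6 rigid-body motion parameters to the 24-parameter set.

    Columns are ordered ``[m, dm, m**2, dm**2]`` where ``dm`` is the backward
    temporal difference with the first row set to zero.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion matrix must have exactly 6 columns")
    dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    out = np.hstack([m, dm, m**2, dm**2])
    names = (
        [f"motion_{k}" for k in range(6)]
        + [f"motion_diff_{k}" for k in range(6)]
        + [f"motion_sq_{k}" for k in range(6)]
        + [f"motion_diff_sq_{k}" for k in range(6)]
    )
    return ConfoundMatrix(data=out, names=names)


def regress_confounds(ts: RegionTimeSeries, confounds: ConfoundMatrix | None,
                      include_trend: bool = True) -> RegionTimeSeries:
    """Replace each region's series by its least-squares residual.

    The design is ``[intercept, linear trend (optional), confound columns]``.
    Rank-deficient designs (e.g. duplicated columns) are handled by the
    minimum-norm least-squares solution, so residuals are well defined.
    """
    T = ts.n_timepoints
    cols = [np.ones(T)]
    if include_trend:
        cols.append(np.linspace(-1.0, 1.0, T))
    if confounds is not None:
        if confounds.n_timepoints != T:
            raise ValueError(
                f"confound rows ({confounds.n_timepoints}) != time points ({T})"
            )
        cols.append(confounds.data)
    design = np.column_stack(cols)
    if design.shape[1] > T:
        raise ValueError("confound design has more columns than time points")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return ts.copy_with(resid)


def bandpass(ts: RegionTimeSeries, low_hz: float = 0.01,
             high_hz: float = 0.1) -> RegionTimeSeries:
    """Ideal (rectangular) frequency-domain band-pass filter.

    Discrete Fourier coefficients whose bin-center frequency ``f`` satisfies
    ``low_hz <= f <= high_hz`` are kept; all others (including DC) are zeroed
    before the inverse transform, so the output is mean-free.  Applying the
    filter twice equals applying it once.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4g}"
        )
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=ts.tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(ts.data, axis=0)
    spec[~keep, :] = 0.0
    filtered = np.fft.irfft(spec, n=T, axis=0)
    return ts.copy_with(filtered)
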