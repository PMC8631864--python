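"""Text/NIfTI serialization of the pipeline's objects.

Region-by-time matrices travel as TSV with regions as columns (header =
region ids); square matrices as TSV with a region-id header; reports as CSV
and JSON.  Numeric text is written with 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import RegionTimeSeries

FLOAT_FMT = "%.12g"

PHENOTYPE_COLUMNS = ["subject_id", "group", "age", "sex",
                     "mem", "ef", "abeta", "tau", "ptau"]


def write_timeseries_tsv(ts: RegionTimeSeries, path) -> None:
    frame = pd.DataFrame(ts.data, columns=[str(r) for r in ts.region_ids])
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_timeseries_tsv(path, tr: float, subject_id: str = "") -> RegionTimeSeries:
    frame = pd.read_csv(path, sep="\t")
    try:
        ids = [int(c) for c in frame.columns]
    except ValueError as exc:
        raise ValueError(f"{path}: header must contain integer region ids") from exc
    data = frame.to_numpy()
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells present")
    return RegionTimeSeries(data=data.astype(float), tr=tr, region_ids=ids,
                            subject_id=subject_id or Path(path).stem)


def write_matrix_tsv(matrix: np.ndarray, region_ids, path) -> None:
    frame = pd.DataFrame(np.asarray(matrix, dtype=float),
                         columns=[str(r) for r in region_ids])
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix_tsv(path) -> tuple:
    frame = pd.read_csv(path, sep="\t")
    data = frame.to_numpy()
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells present")
    if data.shape[0] != data.shape[1]:
        raise ValueError(
            f"{path}: expected a square matrix, got {data.shape[0]} rows x "
            f"{data.shape[1]} header columns")
    ids = [int(c) for c in frame.columns]
    return data.astype(float), ids


def read_phenotype_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in frame.columns:
            raise ValueError(f"{path}: required column {col!r} is missing")
    return frame


def write_phenotype_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    raise TypeError(f"not JSON serializable: {type(value)}")


def save_nifti(img, path) -> None:
    import nibabel as nib

    nib.save(img, str(path))


def load_nifti(path):
    import nibabel as nib

    return nib.load(str(path))
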