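"""End-to-end orchestration: inputs -> prep -> connectivity -> flow ->
group statistics -> classification/prediction, with a provenance manifest.

Three input modes:

* ``synthetic``  — generate a ground-truth cohort (no filtering applied:
  the generative process is already band-limited white-driven and filtering
  would blur the planted directions).
* ``matrices``   — read per-subject region-by-time TSVs plus a phenotype CSV.
* ``images``     — read per-subject 4D NIfTI + label volume (+ optional
  confound table), extract, regress, band-pass, then proceed as above.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from .gca import GcaParams
from .flow import edge_features
from .model import InformationFlow, GroupFlowComparison
from .prediction import (FeatureSelectionError, lasso_predict, loocv_svc,
                         nested_loocv_svc, select_significant_features)
from .preprocess import bandpass, extract_region_signals, regress_confounds
from .synthetic import CohortSpec, default_cohort_spec, generate_cohort
from .timeseries import ConfoundMatrix

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults mirror the analysis protocol
    (band 0.01-0.1 Hz, FDR level 0.05, LOOCV, lag-1 kernel GCA)."""

    mode: str = "synthetic"
    output_dir: str = "causalflow_out"
    seed: int = 0
    # synthetic mode
    n_regions: int = 12
    n_per_group: tuple = (10, 10)
    T: int = 140
    tr: float = 3.0
    effect_multiplier: float = 3.0
    # matrices / images mode
    phenotype_csv: str = None
    matrices_dir: str = None
    image_table_csv: str = None
    group_labels: tuple = ("HC", "EMCI")
    # estimation
    lag: int = 1
    kernel: str = "product_gaussian"
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    fdr_level: float = 0.05
    test_variant: str = "student"
    positive_class: str = "HC"
    svc_kernel: str = "linear"
    selection: str = "pooled"  # or "nested"
    prediction_mode: str = "in_sample"
    outcome_columns: tuple = ("mem", "ef", "abeta", "tau", "ptau")

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "matrices", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("FDR level must lie in (0, 1)")
        if self.selection not in ("pooled", "nested"):
            raise ValueError(f"unknown selection {self.selection!r}")

    def gca_params(self) -> GcaParams:
        return GcaParams(order=self.lag, kernel=self.kernel)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_subjects(config: PipelineConfig, out: Path):
    """Return (list of RegionTimeSeries, phenotype DataFrame)."""
    if config.mode == "synthetic":
        spec = default_cohort_spec(n_per_group=config.n_per_group, T=config.T,
                                   seed=config.seed,
                                   multiplier=config.effect_multiplier,
                                   n_regions=config.n_regions)
        from .synthetic import default_network
        net = default_network(n_regions=config.n_regions)
        series, table, truth = generate_cohort(spec, net)
        ts_dir = out / "timeseries"
        ts_dir.mkdir(parents=True, exist_ok=True)
        for ts in series:
            cfio.write_timeseries_tsv(ts, ts_dir / f"{ts.subject_id}.tsv")
        cfio.write_phenotype_csv(table, out / "phenotype.csv")
        cfio.write_json(truth, out / "ground_truth.json")
        return series, table

    if config.phenotype_csv is None:
        raise ValueError(f"mode {config.mode!r} requires phenotype_csv")
    table = cfio.read_phenotype_csv(config.phenotype_csv)

    series = []
    if config.mode == "matrices":
        if config.matrices_dir is None:
            raise ValueError("matrices mode requires matrices_dir")
        mdir = Path(config.matrices_dir)
        for sid in table["subject_id"]:
            path = mdir / f"{sid}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing matrix for subject {sid}: {path}")
            series.append(cfio.read_timeseries_tsv(path, tr=config.tr,
                                                   subject_id=str(sid)))
        return series, table

    # images mode
    if config.image_table_csv is None:
        raise ValueError("images mode requires image_table_csv")
    itab = pd.read_csv(config.image_table_csv)
    for col in ("subject_id", "image", "labels"):
        if col not in itab.columns:
            raise ValueError(f"image table missing column {col!r}")
    by_sid = itab.set_index(itab["subject_id"].astype(str))
    for sid in table["subject_id"].astype(str):
        if sid not in by_sid.index:
            raise ValueError(f"no image row for subject {sid}")
        row = by_sid.loc[sid]
        ts = extract_region_signals(cfio.load_nifti(row["image"]),
                                    cfio.load_nifti(row["labels"]),
                                    tr=config.tr, subject_id=sid)
        confounds = None
        if "confounds" in itab.columns and isinstance(row.get("confounds"), str):
            cframe = pd.read_csv(row["confounds"],
                                 sep="\t" if row["confounds"].endswith(".tsv") else ",")
            confounds = ConfoundMatrix(data=cframe.to_numpy(dtype=float),
                                       names=list(cframe.columns))
        ts = regress_confounds(ts, confounds, include_trend=True)
        ts = bandpass(ts, config.band_low_hz, config.band_high_hz)
        series.append(ts)
    return series, table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under the output
    directory.  Returns a result bundle with the in-memory objects and the
    manifest.  Deterministic stages are bit-identical across reruns with
    the same configuration."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}, "outputs": {},
                "versions": _versions()}
    bundle = {"manifest": manifest}

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}

    def stage_done(name):
        rec = manifest["stages"][name]
        rec["seconds"] = round(time.time() - rec["t_start"], 3)
        del rec["t_start"]

    stage("inputs")
    series, table = _load_subjects(config, out)
    bundle["phenotype"] = table
    labels = table["group"].astype(str).to_numpy()
    la, lb = config.group_labels
    present = set(labels)
    if not {la, lb} <= present:
        raise ValueError(f"expected groups {la!r} and {lb!r}, found {sorted(present)}")
    stage_done("inputs")

    stage("connectivity")
    params = config.gca_params()
    results = [InformationFlow(ts, params=params).fit() for ts in series]
    conn_dir = out / "connectivity"
    flow_dir = out / "flow"
    conn_dir.mkdir(exist_ok=True)
    flow_dir.mkdir(exist_ok=True)
    for ts, res in zip(series, results):
        cfio.write_matrix_tsv(res.gca_matrix, res.connectivity.region_ids,
                              conn_dir / f"{ts.subject_id}_gca.tsv")
        cfio.write_matrix_tsv(res.preferred_matrix, res.connectivity.region_ids,
                              flow_dir / f"{ts.subject_id}_preferred.tsv")
    cfio.write_json(params.to_dict(), conn_dir / "params.json")
    index_frame = pd.DataFrame(
        np.vstack([r.index for r in results]),
        columns=[f"region_{r}" for r in results[0].connectivity.region_ids])
    index_frame.insert(0, "subject_id", [ts.subject_id for ts in series])
    index_frame.to_csv(flow_dir / "index.tsv", sep="\t", index=False,
                       float_format=cfio.FLOAT_FMT)
    bundle["results"] = results
    stage_done("connectivity")

    stage("group_stats")
    flows = [r.flow for r in results]
    flows_a = [f for f, g in zip(flows, labels) if g == la]
    flows_b = [f for f, g in zip(flows, labels) if g == lb]
    comparison = GroupFlowComparison(flows_a, flows_b, level=config.fdr_level,
                                     variant=config.test_variant,
                                     group_labels=(la, lb)).fit()
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    comparison.edge_report.table.to_csv(stats_dir / "edgewise.csv", index=False)
    comparison.node_report.table.to_csv(stats_dir / "nodewise.csv", index=False)
    cfio.write_json({
        "significant_edges": comparison.edge_report.significant_ids(),
        "significant_nodes": comparison.node_report.significant_ids(),
        "level": config.fdr_level,
        "variant": config.test_variant,
    }, stats_dir / "summary.json")
    bundle["comparison"] = comparison
    stage_done("group_stats")

    stage("classification")
    clf_dir = out / "classify"
    clf_dir.mkdir(exist_ok=True)
    keep = (labels == la) | (labels == lb)
    edge_matrix = np.vstack([edge_features(f)[0] for f in flows])[keep]
    _, edge_names = edge_features(flows[0])
    node_matrix = np.vstack([f.index for f in flows])[keep]
    node_names = [f"region_{r}" for r in flows[0].region_ids]
    used_labels = labels[keep]
    bundle["classification"] = {}
    for feat_kind, matrix, names, report in (
            ("direction", edge_matrix, edge_names, comparison.edge_report),
            ("index", node_matrix, node_names, comparison.node_report)):
        record = _classify(config, matrix, names, report, used_labels)
        bundle["classification"][feat_kind] = record
        cfio.write_json(record["json"], clf_dir / f"{feat_kind}.json")
        if record.get("folds") is not None:
            record["folds"].to_csv(clf_dir / f"{feat_kind}_folds.csv", index=False)
    stage_done("classification")

    stage("prediction")
    pred_dir = out / "predict"
    pred_dir.mkdir(exist_ok=True)
    bundle["prediction"] = {}
    sub_table = table.loc[keep].reset_index(drop=True)
    for outcome in config.outcome_columns:
        if outcome not in sub_table.columns:
            continue
        y = pd.to_numeric(sub_table[outcome], errors="coerce").to_numpy()
        if np.sum(np.isfinite(y)) < 10 or np.nanstd(y) == 0:
            continue
        rep = lasso_predict(edge_matrix, y, mode=config.prediction_mode,
                            outcome_name=outcome, seed=config.seed,
                            feature_names=edge_names)
        bundle["prediction"][outcome] = rep
        cfio.write_json({
            "outcome": outcome, "r": rep.r, "p": rep.p,
            "n_selected": rep.n_selected, "mode": rep.mode,
            "alpha": rep.alpha,
        }, pred_dir / f"{outcome}.json")
        pd.DataFrame({"predicted": rep.predicted, "actual": rep.actual}).to_csv(
            pred_dir / f"{outcome}_predictions.csv", index=False)
    stage_done("prediction")

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    cfio.write_json(manifest, out / "manifest.json")
    return bundle


def _classify(config: PipelineConfig, matrix, names, report, labels) -> dict:
    """One classification run (pooled or nested selection); degrades to a
    'skipped' record when no feature survives selection."""
    try:
        if config.selection == "nested":
            clf = nested_loocv_svc(matrix, labels, level=config.fdr_level,
                                   variant=config.test_variant,
                                   positive_label=config.positive_class,
                                   kernel=config.svc_kernel)
        else:
            selected, sel_names = select_significant_features(report, matrix, names)
            clf = loocv_svc(selected, labels,
                            positive_label=config.positive_class,
                            kernel=config.svc_kernel, feature_names=sel_names)
    except FeatureSelectionError as exc:
        return {"json": {"status": "skipped", "reason": str(exc)}, "folds": None}
    return {
        "json": {
            "status": "ok",
            "confusion": {"tp": clf.tp, "fn": clf.fn, "tn": clf.tn, "fp": clf.fp},
            "positive_label": clf.positive_label,
            "metrics": clf.metrics,
            "n_features": len(clf.feature_names),
            "feature_names": clf.feature_names,
            "selection": config.selection,
        },
        "folds": clf.fold_predictions,
        "report": clf,
    }


def _versions() -> dict:
    out = {}
    for pkg in ("causalflow", "numpy", "scipy", "pandas", "scikit-learn",
                "statsmodels", "nibabel"):
        try:
            out[pkg] = importlib.metadata.version(pkg)
        except importlib.metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
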