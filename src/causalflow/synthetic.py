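"""Ground-truth-known synthetic cohorts for end-to-end validation.

Real resting-state cohorts of this kind are access-controlled, so every
downstream stage is exercised on simulated data with a known directed
generative process: a stationary VAR(1) with optional centered-quadratic
edge terms,

    x_t[j] = sum_i A[i, j] * x_{t-1}[i]                (linear edges)
           + sum_i Q[i, j] * (x_{t-1}[i] - mu_i)^2     (quadratic edges)
           + eps_t[j],   eps ~ iid N(0, innovation_sd^2),

sampled every TR seconds with a burn-in discarded.  Lag is fixed at 1 to
match the estimator default.  No hemodynamic convolution is applied by
default (an optional moving-average flag approximates BOLD sluggishness);
the analyzed signals are band-limited anyway and ground-truth direction
must stay unambiguous.

Two-group cohorts modify selected couplings in group B by a multiplier.
Effect edges are planted on *reciprocally* coupled pairs: with a one-way
edge the reverse-direction causality floors at zero and the preferred
direction saturates at 1 in both groups, which would erase the very group
contrast the pipeline measures.  Outcome variables are linear functions of
the group's population (large-T plug-in) preferred-flow features plus
Gaussian noise, so prediction tests measure estimator and model jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gca import linear_gca
from .flow import preferred_direction
from .timeseries import RegionTimeSeries

__all__ = [
    "GroundTruthNetwork",
    "OutcomeModel",
    "CohortSpec",
    "default_network",
    "default_cohort_spec",
    "simulate_subject_timeseries",
    "population_flow",
    "generate_cohort",
    "emit_image_fixture",
]

OUTCOME_COLUMNS = ("mem", "ef", "abeta", "tau", "ptau")


@dataclass
class GroundTruthNetwork:
    """Directed coupling structure of the generative VAR(1).

    ``coupling[i, j]`` is the weight of the lag-1 influence of region i on
    region j; the diagonal holds the autoregressive terms.  ``quadratic``
    flags edges whose contribution is the centered square of the source.
    Stationarity of the linearized system (quadratic edges have zero slope
    at the operating point) is required: spectral radius < bound.
    """

    n_regions: int
    coupling: np.ndarray
    quadratic: np.ndarray = None
    innovation_sd: float = 1.0
    spectral_radius_bound: float = 0.95

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.n_regions, self.n_regions):
            raise ValueError("coupling must be n_regions x n_regions")
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("coupling has non-finite entries")
        if self.quadratic is None:
            self.quadratic = np.zeros_like(self.coupling, dtype=bool)
        self.quadratic = np.asarray(self.quadratic, dtype=bool)
        if self.quadratic.shape != self.coupling.shape:
            raise ValueError("quadratic mask shape mismatch")
        if np.any(self.quadratic.diagonal()):
            raise ValueError("diagonal terms must be linear")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")
        if not (0 < self.spectral_radius_bound < 1):
            raise ValueError("spectral_radius_bound must lie in (0, 1)")
        if np.any(np.abs(np.diag(self.coupling)) >= 1):
            raise ValueError("autoregressive diagonal terms must satisfy |a| < 1")
        if self.spectral_radius() >= self.spectral_radius_bound:
            raise ValueError(
                f"non-stationary network: linearized spectral radius "
                f"{self.spectral_radius():.3f} >= bound {self.spectral_radius_bound}"
            )

    def spectral_radius(self) -> float:
        linear = np.where(self.quadratic, 0.0, self.coupling)
        return float(np.max(np.abs(np.linalg.eigvals(linear))))

    def with_effects(self, effect_edges) -> "GroundTruthNetwork":
        """Return a copy with ``coupling[i, j] *= multiplier`` per effect edge."""
        coupling = self.coupling.copy()
        for i, j, mult in effect_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"effect edge ({i}, {j}) outside the network")
            if mult < 0:
                raise ValueError("effect multipliers must be >= 0")
            coupling[i, j] *= mult
        return GroundTruthNetwork(
            n_regions=self.n_regions, coupling=coupling,
            quadratic=self.quadratic.copy(),
            innovation_sd=self.innovation_sd,
            spectral_radius_bound=self.spectral_radius_bound,
        )


@dataclass
class OutcomeModel:
    """Outcome = sum_k weight_k * true_preferred_direction(edge_k) + noise."""

    edges: list
    weights: list
    noise_sd: float = 0.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class CohortSpec:
    """Design of a two-group synthetic cohort (defaults mirror the study
    protocol: 40 controls vs 49 patients, 140 volumes at TR = 3 s)."""

    n_per_group: tuple = (40, 49)
    T: int = 140
    tr: float = 3.0
    effect_edges: list = field(default_factory=list)
    outcome_models: dict = field(default_factory=dict)
    seed: int = 0
    group_labels: tuple = ("HC", "EMCI")

    def __post_init__(self) -> None:
        if self.T < 50:
            raise ValueError("T must be >= 50")
        if len(self.n_per_group) != 2 or min(self.n_per_group) < 1:
            raise ValueError("n_per_group must be two positive counts")
        for _, _, mult in self.effect_edges:
            if mult < 0:
                raise ValueError("effect multipliers must be >= 0")


def default_network(n_regions: int = 12, ar: float = 0.3,
                    reciprocal_pairs=((0, 1), (2, 3), (4, 5)),
                    reciprocal_weight: float = 0.25,
                    extra_edges=((6, 7, 0.4), (8, 9, 0.35)),
                    quadratic_edges=(),
                    innovation_sd: float = 1.0) -> GroundTruthNetwork:
    """A small stationary network with reciprocally coupled pairs (which
    carry the group effects), a few one-way edges and optional quadratic
    edges; remaining regions are driven by their own AR term only."""
    A = np.eye(n_regions) * ar
    quad = np.zeros((n_regions, n_regions), dtype=bool)
    for i, j in reciprocal_pairs:
        if i < n_regions and j < n_regions:
            A[i, j] = reciprocal_weight
            A[j, i] = reciprocal_weight
    for i, j, w in extra_edges:
        if i < n_regions and j < n_regions:
            A[i, j] = w
    for i, j, w in quadratic_edges:
        A[i, j] = w
        quad[i, j] = True
    return GroundTruthNetwork(n_regions=n_regions, coupling=A, quadratic=quad,
                              innovation_sd=innovation_sd)


def default_cohort_spec(n_per_group=(40, 49), T: int = 140, seed: int = 0,
                        multiplier: float = 3.0,
                        n_regions: int = None) -> CohortSpec:
    """Study-shaped cohort: group effects on the three reciprocal pairs and
    five outcomes driven by the affected edges.  When ``n_regions`` is
    given, effect edges and outcome models referencing regions beyond it
    are dropped so the spec stays valid for small networks."""
    effect_edges = [(0, 1, multiplier), (2, 3, multiplier), (4, 5, multiplier)]
    outcomes = {
        "mem": OutcomeModel(edges=[(0, 1), (2, 3)], weights=[-2.0, -1.0],
                            noise_sd=0.2, intercept=1.5),
        "ef": OutcomeModel(edges=[(2, 3), (4, 5)], weights=[-1.5, -1.0],
                           noise_sd=0.2, intercept=1.2),
        "abeta": OutcomeModel(edges=[(0, 1)], weights=[120.0],
                              noise_sd=25.0, intercept=120.0),
        "tau": OutcomeModel(edges=[(2, 3)], weights=[-80.0],
                            noise_sd=20.0, intercept=130.0),
        "ptau": OutcomeModel(edges=[(4, 5)], weights=[-40.0],
                             noise_sd=10.0, intercept=60.0),
    }
    if n_regions is not None:
        effect_edges = [(i, j, m) for i, j, m in effect_edges
                        if i < n_regions and j < n_regions]
        outcomes = {name: m for name, m in outcomes.items()
                    if all(i < n_regions and j < n_regions
                           for i, j in m.edges)}
    return CohortSpec(n_per_group=tuple(n_per_group), T=T,
                      effect_edges=effect_edges, outcome_models=outcomes,
                      seed=seed)


def simulate_subject_timeseries(net: GroundTruthNetwork, T: int, tr: float,
                                seed: int, burn_in: int = 200,
                                smooth: bool = False,
                                subject_id: str = "") -> RegionTimeSeries:
    """Simulate one subject's T x N series; deterministic given the seed."""
    if T < 50:
        raise ValueError("T must be >= 50")
    if burn_in < 200:
        raise ValueError("burn-in must be >= 200 steps")
    rng = np.random.default_rng(seed)
    n = net.n_regions
    linear = np.where(net.quadratic, 0.0, net.coupling)
    quad = np.where(net.quadratic, net.coupling, 0.0)
    has_quad = bool(net.quadratic.any())
    total = burn_in + T
    eps = rng.normal(0.0, net.innovation_sd, size=(total, n))
    x = np.zeros((total, n))
    state = np.zeros(n)
    for t in range(total):
        drive = state @ linear
        if has_quad:
            drive = drive + (state**2) @ quad
        state = drive + eps[t]
        x[t] = state
    out = x[burn_in:]
    if smooth:
        # crude BOLD sluggishness: 3-point moving average
        kernel = np.array([0.25, 0.5, 0.25])
        out = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, out)
    return RegionTimeSeries(data=out, tr=tr,
                            region_ids=np.arange(1, n + 1),
                            subject_id=subject_id)


def population_flow(net: GroundTruthNetwork, plug_in_T: int = 6000,
                    seed: int = 123456) -> np.ndarray:
    """Population preferred-direction matrix via a large-T plug-in.

    One long realization is simulated and pairwise linear GCA computed; at
    this length sampling noise in the ratio is negligible for the linear
    couplings that carry the group effects.
    """
    ts = simulate_subject_timeseries(net, plug_in_T, tr=1.0, seed=seed)
    n = net.n_regions
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                g[i, j] = linear_gca(ts.data[:, i], ts.data[:, j], p=1)
    return preferred_direction(g).p_matrix


def generate_cohort(spec: CohortSpec, net: GroundTruthNetwork = None):
    """Generate a two-group cohort.

    Returns ``(series_list, cohort_table, ground_truth)``: per-subject time
    series, a phenotype DataFrame (subject_id, group, age, sex + outcome
    columns), and the ground-truth record needed for test assertions.
    """
    if net is None:
        net = default_network()
    net_b = net.with_effects(spec.effect_edges)
    for name, model in spec.outcome_models.items():
        for i, j in model.edges:
            if not (0 <= i < net.n_regions and 0 <= j < net.n_regions):
                raise ValueError(
                    f"outcome {name!r} references undefined edge ({i}, {j})")

    rng = np.random.default_rng(spec.seed)
    pop_p = {0: population_flow(net), 1: population_flow(net_b)}

    series, rows = [], []
    label_a, label_b = spec.group_labels
    n_a, n_b = spec.n_per_group
    # demographic generators loosely match the study's age/sex structure
    age_params = {0: (75.1, 6.31), 1: (72.2, 6.72)}
    female_rate = {0: 22 / 40, 1: 25 / 49}
    counter = 0
    for group, n_subj, network in ((0, n_a, net), (1, n_b, net_b)):
        for _ in range(n_subj):
            counter += 1
            sid = f"sub-{counter:03d}"
            subj_seed = int(rng.integers(0, 2**31 - 1))
            ts = simulate_subject_timeseries(network, spec.T, spec.tr,
                                             seed=subj_seed, subject_id=sid)
            series.append(ts)
            row = {
                "subject_id": sid,
                "group": label_a if group == 0 else label_b,
                "age": float(rng.normal(*age_params[group])),
                "sex": "F" if rng.random() < female_rate[group] else "M",
            }
            for col in OUTCOME_COLUMNS:
                row[col] = np.nan
            for name, model in spec.outcome_models.items():
                feats = np.array([pop_p[group][i, j] for i, j in model.edges])
                value = model.intercept + float(np.dot(model.weights, feats))
                if model.noise_sd > 0:
                    value += float(rng.normal(0.0, model.noise_sd))
                row[name] = value
            rows.append(row)

    table = pd.DataFrame(rows)
    ground_truth = {
        "coupling_group_a": net.coupling.tolist(),
        "coupling_group_b": net_b.coupling.tolist(),
        "quadratic_mask": net.quadratic.astype(int).tolist(),
        "effect_edges": [list(e) for e in spec.effect_edges],
        "outcome_models": {
            name: {"edges": [list(e) for e in m.edges],
                   "weights": list(m.weights),
                   "noise_sd": m.noise_sd,
                   "intercept": m.intercept}
            for name, m in spec.outcome_models.items()
        },
        "population_preferred_a": pop_p[0].tolist(),
        "population_preferred_b": pop_p[1].tolist(),
        "seed": spec.seed,
    }
    return series, table, ground_truth


def emit_image_fixture(ts: RegionTimeSeries, voxels_per_region: int,
                       noise_sd: float = 0.0, seed: int = 0):
    """Write a region series into a synthetic 4D image plus label volume.

    Region ``k`` occupies a contiguous block of ``voxels_per_region`` voxels
    (optionally with iid Gaussian voxel noise); with zero noise a round trip
    through :func:`causalflow.preprocess.extract_region_signals` recovers
    the input exactly.  Returns ``(image4d, label_volume)`` as nibabel
    images with identity affine.
    """
    import nibabel as nib

    if voxels_per_region < 1:
        raise ValueError("voxels_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    T, N = ts.data.shape
    data = np.zeros((N, voxels_per_region, 1, T))
    labels = np.zeros((N, voxels_per_region, 1), dtype=np.int16)
    for k in range(N):
        block = np.tile(ts.data[:, k], (voxels_per_region, 1))  # (v, T)
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=block.shape)
        data[k, :, 0, :] = block
        labels[k, :, 0] = ts.region_ids[k]
    affine = np.eye(4)
    return (nib.Nifti1Image(data, affine),
            nib.Nifti1Image(labels, affine))


def ground_truth_to_json(ground_truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth, fh, indent=2)
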