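"""Synthetic ensembles, energy series, score tables and melting curves.

Every generator plants a known ground truth and returns it alongside the
data, so each downstream stage of the pipeline — superposition, mobility
profiles, PC landscapes and well occupancy, sigma-scores, classification,
clustering, Tm calling — can be tested quantitatively without MD output.

The ensemble generator emulates a multi-replicate Cα trajectory of a small
globular protein: a smooth helix-like base geometry with 3.8 A inter-residue
spacing, zero-mean Gaussian collective modes with specified amplitudes,
optional two-state dynamics along one collective coordinate (a two-state
Markov chain with exactly controllable stationary occupancy — the synthetic
analogue of a trajectory hopping between two free-energy wells), and
isotropic per-residue Gaussian noise.  All randomness flows from a single
integer seed through one spawned stream per replicate, so replicate blocks
are individually deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rasdyn.classify_cluster import ScoreTable
from rasdyn.thermostability import MeltingCurve
from rasdyn.trajectory_io import TrajectoryEnsemble

_ORTHO_TOL = 1e-8


@dataclass
class ModeDef:
    """One collective mode: a unit displacement field with a Gaussian amplitude."""

    direction: np.ndarray  # (n_residues, 3), unit Frobenius norm
    amplitude: float  # SD of the mode coordinate, Angstrom

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.amplitude < 0:
            raise ValueError("mode amplitude must be >= 0")


@dataclass
class TwoWellDef:
    """Two-state collective coordinate with controlled stationary occupancy.

    The coordinate alternates between positions ``center_i`` and
    ``center_ii`` (Angstrom along ``direction``) as a two-state Markov chain
    whose stationary probability of state II is ``occupancy_ii`` and whose
    mean dwell in state II is ``dwell`` frames.
    """

    direction: np.ndarray
    center_i: float = 0.0
    center_ii: float = 5.0
    occupancy_ii: float = 0.3
    dwell: float = 50.0

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if not 0.0 <= self.occupancy_ii <= 1.0:
            raise ValueError(f"occupancy_ii must be in [0, 1], got {self.occupancy_ii}")
        if self.dwell < 1:
            raise ValueError("mean dwell must be >= 1 frame")


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic replicate ensemble."""

    n_residues: int = 169
    n_replicates: int = 3
    n_frames: int = 400
    base_coords: np.ndarray | None = None  # None -> ideal helix-like chain
    modes: list = field(default_factory=list)
    twowell: TwoWellDef | None = None
    noise: float | np.ndarray = 0.0  # per-axis SD, scalar or per-residue
    seed: int = 0
    variant_id: str = "synthetic"
    nucleotide: str = "GDP"

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        noise = np.broadcast_to(np.asarray(self.noise, dtype=float), (self.n_residues,))
        if (noise < 0).any():
            raise ValueError("noise SDs must be >= 0")
        directions = [m.direction for m in self.modes]
        if self.twowell is not None:
            directions.append(self.twowell.direction)
        for i, d in enumerate(directions):
            if d.shape != (self.n_residues, 3):
                raise ValueError(f"direction {i} has shape {d.shape}, expected ({self.n_residues}, 3)")
            if abs(np.linalg.norm(d) - 1.0) > 1e-6:
                raise ValueError(f"direction {i} is not unit-normalized")
        flat = np.array([d.ravel() for d in directions])
        if len(flat) > 1:
            gram = flat @ flat.T
            off = gram - np.eye(len(flat))
            if np.abs(off).max() > 1e-6:
                raise ValueError("mode/two-well directions must be mutually orthonormal")


@dataclass
class GroundTruth:
    """Planted quantities returned by every generator."""

    occupancy_ii: float | None = None
    twowell_states: np.ndarray | None = None  # (n_replicates, n_frames) bool
    rmsf: np.ndarray | None = None  # planted per-residue RMSF, Angstrom
    mode_directions: np.ndarray | None = None  # (k, n_residues, 3)
    energy_mean: float | None = None
    energy_sd: float | None = None
    tm: float | None = None
    group_labels: dict | None = None

    def to_json(self, path: str) -> None:
        payload = {}
        for key, value in self.__dict__.items():
            if value is None:
                continue
            payload[key] = value.tolist() if isinstance(value, np.ndarray) else value
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def ideal_chain(n_residues: int) -> np.ndarray:
    """Cα positions on a smooth helix-like curve with ~3.8 A spacing.

    Radius 2.3 A, rise 1.5 A and 100 degrees of twist per residue give the
    canonical alpha-helical Cα-Cα distance without requiring an input PDB.
    """
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def random_orthonormal_modes(
    n_residues: int, k: int, seed: int = 0, region: tuple[int, int] | None = None
) -> np.ndarray:
    """k mutually orthonormal displacement fields, optionally region-restricted.

    ``region`` is an inclusive 1-based residue range; outside it the
    displacement is zero.
    """
    rng = np.random.default_rng(seed)
    if region is None:
        support = np.arange(n_residues)
    else:
        lo, hi = region
        support = np.arange(lo - 1, hi)
    dim = support.size * 3
    if k > dim:
        raise ValueError("more modes requested than degrees of freedom in the region")
    q, _ = np.linalg.qr(rng.normal(size=(dim, k)))
    modes = np.zeros((k, n_residues, 3))
    for j in range(k):
        modes[j, support, :] = q[:, j].reshape(support.size, 3)
    return modes


def _ca_atom_table(n_residues: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resid": np.arange(1, n_residues + 1),
            "resname": ["ALA"] * n_residues,
            "name": ["CA"] * n_residues,
            "element": ["C"] * n_residues,
        }
    )


def _markov_states(rng, n_frames: int, occupancy_ii: float, dwell: float) -> np.ndarray:
    """Two-state chain with stationary P(II) = occupancy_ii, mean II dwell ~ dwell."""
    p = occupancy_ii
    if p <= 0.0:
        return np.zeros(n_frames, dtype=bool)
    if p >= 1.0:
        return np.ones(n_frames, dtype=bool)
    p_leave_ii = 1.0 / dwell
    p_leave_i = p / (1.0 - p) / dwell
    if p_leave_i > 1.0:  # very skewed occupancy with short dwell: rescale both rates
        scale = 1.0 / p_leave_i
        p_leave_i, p_leave_ii = 1.0, p_leave_ii * scale
    states = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    states[0] = u[0] < p  # stationary start: exact marginal occupancy
    for t in range(1, n_frames):
        if states[t - 1]:
            states[t] = u[t] >= p_leave_ii
        else:
            states[t] = u[t] < p_leave_i
    return states


def generate_ensemble(spec: EnsembleSpec) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Synthesize a replicate Cα ensemble with planted modes, wells and noise.

    Frame coordinates are ``base + sum_k a_k(t) v_k + c(t) w + noise`` where
    ``a_k`` are zero-mean Gaussians of the specified mode amplitudes,
    ``c(t)`` hops between the two well centers as a Markov chain with the
    specified stationary occupancy, and the noise is isotropic per residue.
    Identical spec (including seed) gives identical output.
    """
    spec.validate()
    base = ideal_chain(spec.n_residues) if spec.base_coords is None else np.asarray(spec.base_coords, float)
    if base.shape != (spec.n_residues, 3):
        raise ValueError(f"base_coords shape {base.shape} != ({spec.n_residues}, 3)")
    noise = np.broadcast_to(np.asarray(spec.noise, dtype=float), (spec.n_residues,))

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    coords = np.empty((spec.n_replicates, spec.n_frames, spec.n_residues, 3))
    states_all = np.zeros((spec.n_replicates, spec.n_frames), dtype=bool)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        block = np.broadcast_to(base, (spec.n_frames, spec.n_residues, 3)).copy()
        for mode in spec.modes:
            a = rng.normal(0.0, mode.amplitude, size=spec.n_frames)
            block += a[:, None, None] * mode.direction[None, :, :]
        if spec.twowell is not None:
            tw = spec.twowell
            states = _markov_states(rng, spec.n_frames, tw.occupancy_ii, tw.dwell)
            c = np.where(states, tw.center_ii, tw.center_i)
            block += c[:, None, None] * tw.direction[None, :, :]
            states_all[r] = states
        if noise.any():
            block += rng.normal(size=block.shape) * noise[None, :, None]
        coords[r] = block

    # planted per-residue RMSF: mode + well + noise variances about the mean
    var = 3.0 * noise**2
    for mode in spec.modes:
        var = var + mode.amplitude**2 * (mode.direction**2).sum(axis=1)
    if spec.twowell is not None:
        tw = spec.twowell
        var_c = tw.occupancy_ii * (1 - tw.occupancy_ii) * (tw.center_ii - tw.center_i) ** 2
        var = var + var_c * (tw.direction**2).sum(axis=1)

    ensemble = TrajectoryEnsemble(
        variant_id=spec.variant_id,
        nucleotide=spec.nucleotide,
        coords=coords,
        atoms=_ca_atom_table(spec.n_residues),
    )
    truth = GroundTruth(
        occupancy_ii=None if spec.twowell is None else spec.twowell.occupancy_ii,
        twowell_states=states_all if spec.twowell is not None else None,
        rmsf=np.sqrt(var),
        mode_directions=np.array([m.direction for m in spec.modes]) if spec.modes else None,
    )
    return ensemble, truth


def generate_energy_series(
    mean: float, sd: float, n: int, autocorr: float = 0.0, seed: int = 0
) -> np.ndarray:
    """AR(1) per-frame interaction-energy series with given stationary moments.

    ``autocorr`` is the lag-1 autocorrelation (0 gives white noise); the
    stationary mean and SD equal the arguments exactly.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= autocorr < 1.0:
        raise ValueError("autocorr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n, float(mean))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - autocorr**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = autocorr * x[t - 1] + eps[t]
    return mean + x


def generate_melting_curve(
    tm: float,
    steepness: float = 0.5,
    baseline_low: float = 0.85,
    baseline_high: float = 1.05,
    slope_low: float = 0.0,
    slope_high: float = 0.0,
    noise_sd: float = 0.0,
    t_range: tuple[float, float] = (20.0, 95.0),
    step: float = 0.5,
    seed: int = 0,
    variant_id: str = "synthetic",
    state: str = "GDP",
) -> MeltingCurve:
    """Logistic unfolding transition between two baselines plus Gaussian noise.

    ``steepness`` is the logistic rate (1/degC).  With flat baselines and no
    noise the first derivative of the curve peaks exactly at ``tm``.
    """
    lo, hi = t_range
    if not lo <= tm <= hi:
        raise ValueError(f"tm={tm} outside temperature range {t_range}")
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    t = np.arange(lo, hi + step / 2, step)
    f = 1.0 / (1.0 + np.exp(-steepness * (t - tm)))
    low_line = baseline_low + slope_low * (t - lo)
    high_line = baseline_high + slope_high * (t - hi)
    y = low_line * (1 - f) + high_line * f
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return MeltingCurve(temperatures=t, ratio=y, variant_id=variant_id, state=state)


def generate_score_table(
    n_variants: int,
    n_metrics: int = 8,
    planted_groups: int = 3,
    effect_size: float = 6.0,
    seed: int = 0,
    states: tuple = ("GDP", "GTP"),
) -> tuple[ScoreTable, GroundTruth]:
    """Score table with variants drawn around separated group centroids.

    Group centroids are mutually orthogonal directions in metric space
    scaled to ``effect_size`` WT-SD units; variant values add unit-SD noise
    (the WT reference SD).  A designated WT row sits exactly at the global
    reference centroid (the origin), and the WT statistics are the planted
    reference (mean 0, SD 1, median 0 per metric).
    """
    if planted_groups < 1:
        raise ValueError("planted_groups must be >= 1")
    if n_variants < planted_groups:
        raise ValueError("need at least one variant per planted group")
    rng = np.random.default_rng(seed)
    if planted_groups > 1:
        if planted_groups > n_metrics:
            raise ValueError("cannot place more orthogonal group centroids than metrics")
        q, _ = np.linalg.qr(rng.normal(size=(n_metrics, planted_groups)))
        centroids = effect_size * q.T  # (groups, metrics), pairwise distance effect*sqrt(2)
    else:
        centroids = np.zeros((1, n_metrics))
    labels = np.arange(n_variants) % planted_groups
    variant_ids = [f"V{i + 1:03d}" for i in range(n_variants)]
    metric_names = [f"m{j + 1}" for j in range(n_metrics)]

    rows, index = [], []
    for state in states:
        values = centroids[labels] + rng.normal(size=(n_variants, n_metrics))
        for vid, row in zip(variant_ids, values):
            rows.append(row)
            index.append((vid, state))
        rows.append(np.zeros(n_metrics))
        index.append(("WT", state))
    values_df = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["variant", "nucleotide"]), columns=metric_names
    )
    wt_stats = pd.DataFrame(
        {
            "mean": 0.0,
            "sd": 1.0,
            "median": 0.0,
        },
        index=pd.MultiIndex.from_product([list(states), metric_names], names=["nucleotide", "metric"]),
    )
    table = ScoreTable(values=values_df, wt_stats=wt_stats)
    truth = GroundTruth(group_labels={vid: int(g) for vid, g in zip(variant_ids, labels)})
    return table, truth
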