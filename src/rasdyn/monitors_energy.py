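"""Biophysical distance monitors and simplified ligand interaction energy.

Ten literature-derived residue-pair distances track the conformational
hallmarks of GTPase activity: Switch-2/helix-3 hydrogen-bond coupling
(Q61-D92, E62-H95), p-loop-to-Switch-2 opening (A11-Q61, G12-Q61),
Switch-1/Switch-2 coordination (I36-A59, Y32-Y40, Y32-A59) and the
nucleotide/Mg2+ coordination network around T35 (G12-T35, Q61-T35, S17-T35).
Each monitor's per-frame distance is summarized by its median and scored in
WT standard deviations from the WT median.

Ligand-protein interaction energy is a direct pairwise nonbonded sum —
Coulomb plus Lennard-Jones with CHARMM-style combining rules and the CHARMM
switching function between 10 and 12 A — an approximation to a simulation
engine's pair-interaction energy, not a lattice-sum (PME) recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rasdyn.trajectory_io import BACKBONE_ATOMS, TrajectoryEnsemble

#: Coulomb conversion constant, kcal*A/(mol*e^2)
COULOMB_CONST = 332.0716

THEMES = (
    "switch2-helix-coupling",
    "p-loop-switch2",
    "switch1-switch2-coordination",
    "nucleotide-mg-coordination",
)


@dataclass(frozen=True)
class MonitorDef:
    """One residue-pair distance monitor.

    ``rule`` selects the representative point at each end: ``"sidechain"``
    (centroid of side-chain heavy atoms, Cα for glycine or when no
    side-chain atoms are present, as in Cα-only ensembles), ``"ca"``, or a
    pair of atom names like ``("NE2", "OD1")``.
    """

    name: str
    res_a: int
    res_b: int
    theme: str
    rule: object = "sidechain"

    def __post_init__(self) -> None:
        if self.res_a == self.res_b:
            raise ValueError(f"monitor {self.name}: residues must differ")
        if self.theme not in THEMES:
            raise ValueError(f"monitor {self.name}: unknown theme {self.theme!r}")


#: The default KRAS monitor set: ten experimentally characterized pairs.
KRAS_MONITORS = (
    MonitorDef("Q61_D92", 61, 92, "switch2-helix-coupling"),
    MonitorDef("E62_H95", 62, 95, "switch2-helix-coupling"),
    MonitorDef("A11_Q61", 11, 61, "p-loop-switch2"),
    MonitorDef("G12_Q61", 12, 61, "p-loop-switch2"),
    MonitorDef("I36_A59", 36, 59, "switch1-switch2-coordination"),
    MonitorDef("Y32_Y40", 32, 40, "switch1-switch2-coordination"),
    MonitorDef("Y32_A59", 32, 59, "switch1-switch2-coordination"),
    MonitorDef("G12_T35", 12, 35, "nucleotide-mg-coordination"),
    MonitorDef("Q61_T35", 61, 35, "nucleotide-mg-coordination"),
    MonitorDef("S17_T35", 17, 35, "nucleotide-mg-coordination"),
)


def monitors_to_csv(monitors, path: str) -> None:
    pd.DataFrame(
        [
            {
                "name": m.name,
                "res_a": m.res_a,
                "res_b": m.res_b,
                "rule": m.rule if isinstance(m.rule, str) else f"{m.rule[0]}:{m.rule[1]}",
                "theme": m.theme,
            }
            for m in monitors
        ]
    ).to_csv(path, index=False)


def monitors_from_csv(path: str) -> tuple:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        rule = row["rule"]
        if isinstance(rule, str) and ":" in rule:
            rule = tuple(rule.split(":", 1))
        out.append(
            MonitorDef(
                name=str(row["name"]),
                res_a=int(row["res_a"]),
                res_b=int(row["res_b"]),
                theme=str(row["theme"]),
                rule=rule,
            )
        )
    return tuple(out)


def _representative_indices(atoms: pd.DataFrame, resid: int, rule, end: int, monitor: str) -> np.ndarray:
    res = atoms.index[atoms["resid"] == resid]
    if res.size == 0:
        raise ValueError(f"monitor {monitor}: residue {resid} not present in ensemble")
    sub = atoms.loc[res]
    if rule == "ca" or rule == "CA":
        idx = res[sub["name"] == "CA"]
    elif rule == "sidechain":
        heavy = (~sub["name"].isin(BACKBONE_ATOMS)) & (sub["element"].str.upper() != "H")
        idx = res[heavy]
        if idx.size == 0:  # glycine, or a Cα-only ensemble
            idx = res[sub["name"] == "CA"]
    elif isinstance(rule, (tuple, list)) and len(rule) == 2:
        idx = res[sub["name"] == rule[end]]
    else:
        raise ValueError(f"monitor {monitor}: unknown atom rule {rule!r}")
    if idx.size == 0:
        raise ValueError(f"monitor {monitor}: no representative atom for residue {resid} under rule {rule!r}")
    return idx.to_numpy()


@dataclass
class MonitorSeries:
    """Per-frame distances for a monitor set, pooled over replicates."""

    variant_id: str
    nucleotide: str
    values: pd.DataFrame  # pooled frames x monitor name, Angstrom
    n_replicates: int

    @property
    def medians(self) -> pd.Series:
        return self.values.median(axis=0)

    @property
    def sds(self) -> pd.Series:
        return self.values.std(axis=0, ddof=1)


def compute_monitors(ensemble: TrajectoryEnsemble, monitors=KRAS_MONITORS) -> MonitorSeries:
    """Euclidean distance between the two representative points, per frame."""
    frames = ensemble.frames()  # (n, n_atoms, 3)
    cols = {}
    for mon in monitors:
        ia = _representative_indices(ensemble.atoms, mon.res_a, mon.rule, 0, mon.name)
        ib = _representative_indices(ensemble.atoms, mon.res_b, mon.rule, 1, mon.name)
        pa = frames[:, ia, :].mean(axis=1)
        pb = frames[:, ib, :].mean(axis=1)
        cols[mon.name] = np.linalg.norm(pa - pb, axis=1)
    return MonitorSeries(
        variant_id=ensemble.variant_id,
        nucleotide=ensemble.nucleotide,
        values=pd.DataFrame(cols),
        n_replicates=ensemble.n_replicates,
    )


def monitor_sigma_score(mutant: MonitorSeries, wt: MonitorSeries) -> pd.Series:
    """(median_mut - median_WT) / SD_WT per monitor.

    Centers on the WT median but scales by the WT per-frame SD — the number
    of WT standard deviations separating the two medians.
    """
    sd = wt.sds
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"WT monitor distance SD is zero for {bad}")
    return (mutant.medians - wt.medians) / sd


def monitor_pc_correlation(series: MonitorSeries, projections: np.ndarray, n_pcs: int = 3) -> pd.DataFrame:
    """Pearson correlation of each monitor distance with the top PC projections.

    Rows are monitors, columns PC1..PCn.  Constant monitor series give NaN
    (flagged undefined) rather than an arbitrary value.
    """
    proj = np.asarray(projections, dtype=float)[:, :n_pcs]
    if proj.shape[0] != len(series.values):
        raise ValueError(
            f"frame count mismatch: {len(series.values)} monitor frames vs {proj.shape[0]} projections"
        )
    out = pd.DataFrame(index=series.values.columns, columns=[f"PC{k + 1}" for k in range(proj.shape[1])], dtype=float)
    for name in series.values.columns:
        d = series.values[name].to_numpy()
        for k in range(proj.shape[1]):
            p = proj[:, k]
            if d.std() == 0 or p.std() == 0:
                out.loc[name, f"PC{k + 1}"] = np.nan
            else:
                out.loc[name, f"PC{k + 1}"] = float(np.corrcoef(d, p)[0, 1])
    return out


@dataclass
class NonbondedParams:
    """Per-atom partial charges and Lennard-Jones parameters.

    ``table`` columns: ``atom_name``, ``residue_name``, ``charge`` (e),
    ``rmin_half`` (A), ``epsilon`` (kcal/mol, >= 0).  ``r_on``/``r_off``
    bound the switching region (default 10-12 A).
    """

    table: pd.DataFrame
    r_on: float = 10.0
    r_off: float = 12.0

    def __post_init__(self) -> None:
        required = {"atom_name", "residue_name", "charge", "rmin_half", "epsilon"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"parameter table must have columns {sorted(required)}")
        if (self.table["epsilon"] < 0).any():
            raise ValueError("epsilon must be >= 0")
        if not self.r_on < self.r_off:
            raise ValueError("r_on must be < r_off")
        self._lookup = {
            (str(r.residue_name), str(r.atom_name)): (float(r.charge), float(r.rmin_half), float(r.epsilon))
            for r in self.table.itertuples()
        }

    @classmethod
    def from_csv(cls, path: str, r_on: float = 10.0, r_off: float = 12.0) -> "NonbondedParams":
        return cls(table=pd.read_csv(path), r_on=r_on, r_off=r_off)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, resname: str, atom_name: str):
        key = (str(resname), str(atom_name))
        if key not in self._lookup:
            # wildcard residue entries allow generic atom-type tables
            key = ("*", str(atom_name))
        return self._lookup.get(key)


def switching_function(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM switching polynomial: 1 below r_on, 0 beyond r_off, C1 between."""
    r = np.asarray(r, dtype=float)
    s = np.zeros_like(r)
    s[r <= r_on] = 1.0
    mid = (r > r_on) & (r <= r_off)
    r2, ron2, roff2 = r[mid] ** 2, r_on**2, r_off**2
    s[mid] = (roff2 - r2) ** 2 * (roff2 + 2 * r2 - 3 * ron2) / (roff2 - ron2) ** 3
    return s


@dataclass
class EnergySeries:
    """Per-frame ligand-protein interaction energy, Coulomb + Lennard-Jones."""

    variant_id: str
    nucleotide: str
    coulomb: np.ndarray
    lj: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.coulomb + self.lj

    @property
    def mean(self) -> float:
        return float(self.total.mean())

    @property
    def sd(self) -> float:
        return float(self.total.std(ddof=1)) if self.total.size > 1 else 0.0

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "frame": np.arange(self.total.size),
                "energy": self.total,
                "coulomb": self.coulomb,
                "lj": self.lj,
            }
        ).to_csv(path, index=False)


def _gather_params(atoms: pd.DataFrame, indices: np.ndarray, params: NonbondedParams):
    q = np.empty(indices.size)
    rmin_half = np.empty(indices.size)
    eps = np.empty(indices.size)
    missing = []
    for j, i in enumerate(indices):
        row = atoms.iloc[i]
        got = params.lookup(row["resname"], row["name"])
        if got is None:
            missing.append(f"{row['resname']}:{row['name']}")
        else:
            q[j], rmin_half[j], eps[j] = got
    if missing:
        raise ValueError(f"missing nonbonded parameters for atoms: {sorted(set(missing))}")
    return q, rmin_half, eps


def compute_interaction_energy(
    ensemble: TrajectoryEnsemble,
    params: NonbondedParams,
    ligand_resnames=("GTP", "GDP", "MG"),
    protein_indices: np.ndarray | None = None,
    ligand_indices: np.ndarray | None = None,
) -> EnergySeries:
    """Pairwise protein-ligand nonbonded energy per frame.

    E_coul = sum C q_i q_j / r * S(r); E_LJ = sum eps_ij [(Rmin_ij/r)^12 -
    2 (Rmin_ij/r)^6] * S(r), with eps_ij the geometric mean, Rmin_ij the sum
    of Rmin/2 values, and S the CHARMM switching function — pairs beyond
    r_off contribute exactly zero.  Selections default to ligand = atoms
    whose residue name is in ``ligand_resnames`` (Mg2+ counted with the
    nucleotide), protein = everything else.
    """
    atoms = ensemble.atoms.reset_index(drop=True)
    if ligand_indices is None:
        ligand_indices = atoms.index[atoms["resname"].isin(ligand_resnames)].to_numpy()
    else:
        ligand_indices = np.asarray(ligand_indices)
    if protein_indices is None:
        protein_indices = atoms.index[~atoms.index.isin(ligand_indices)].to_numpy()
    else:
        protein_indices = np.asarray(protein_indices)
    if ligand_indices.size == 0:
        raise ValueError(f"no ligand atoms matched residue names {tuple(ligand_resnames)}")
    if np.intersect1d(ligand_indices, protein_indices).size:
        raise ValueError("protein and ligand selections overlap")

    qp, rp, ep = _gather_params(atoms, protein_indices, params)
    ql, rl, el = _gather_params(atoms, ligand_indices, params)
    qq = np.outer(qp, ql)
    rmin = rp[:, None] + rl[None, :]
    eps = np.sqrt(np.outer(ep, el))

    frames = ensemble.frames()
    n = frames.shape[0]
    e_coul = np.empty(n)
    e_lj = np.empty(n)
    for t in range(n):
        d = frames[t][protein_indices, None, :] - frames[t][None, ligand_indices, :]
        r = np.sqrt((d**2).sum(axis=-1))
        s = switching_function(r, params.r_on, params.r_off)
        within = s > 0
        rr = r[within]
        ss = s[within]
        e_coul[t] = float((COULOMB_CONST * qq[within] / rr * ss).sum())
        ratio6 = (rmin[within] / rr) ** 6
        e_lj[t] = float((eps[within] * (ratio6**2 - 2 * ratio6) * ss).sum())
    return EnergySeries(
        variant_id=ensemble.variant_id, nucleotide=ensemble.nucleotide, coulomb=e_coul, lj=e_lj
    )


def ingest_energy_series(path: str, variant_id: str = "", nucleotide: str = "GDP") -> EnergySeries:
    """Read an externally computed per-frame energy CSV.

    Accepts either the package's own export (frame, energy, coulomb, lj) or
    any two-column numeric (frame, energy) file; non-numeric rows raise with
    the 1-based data line number.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-numeric value at line {line}")
    if {"coulomb", "lj"}.issubset(df.columns):
        coulomb = numeric["coulomb"].to_numpy()
        lj = numeric["lj"].to_numpy()
    else:
        total = numeric.iloc[:, 1].to_numpy()
        coulomb = total
        lj = np.zeros_like(total)
    return EnergySeries(variant_id=variant_id, nucleotide=nucleotide, coulomb=coulomb, lj=lj)
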