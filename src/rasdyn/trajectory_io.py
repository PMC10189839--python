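"""Structure/trajectory I/O, atom selections, superposition and region maps.

Ensembles are held in memory as a dense coordinate array of shape
``(n_replicates, n_frames, n_atoms, 3)`` plus a pandas atom table, which is
sufficient for the 169-residue constructs this package targets.  File formats
(PDB topology/reference, DCD/XTC trajectories, multi-model PDB) are read and
written through MDAnalysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class FormatError(ValueError):
    """Raised when an input file is inconsistent with its topology."""


@dataclass(frozen=True)
class RegionMap:
    """Named inclusive 1-based residue ranges of the GTPase fold.

    The defaults bracket the mobile elements of KRAS 1-169: the
    phosphate-binding loop, the two Switch loops and the C-terminal
    allosteric lobe.  ``alignment_exclusions`` names the regions left out of
    least-squares fitting, by default the two Switches because their motion
    is the signal of interest rather than noise to be minimized.
    """

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "p_loop": (10, 17),
            "switch1": (25, 40),
            "switch2": (57, 75),
            "allosteric_lobe": (87, 166),
        }
    )
    alignment_exclusions: tuple[str, ...] = ("switch1", "switch2")

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"region {name!r}: invalid range ({lo}, {hi})")
        for name in self.alignment_exclusions:
            if name not in self.ranges:
                raise ValueError(f"alignment exclusion {name!r} is not a named region")

    def residues(self, name: str) -> np.ndarray:
        lo, hi = self.ranges[name]
        return np.arange(lo, hi + 1)

    def excluded_residues(self) -> np.ndarray:
        if not self.alignment_exclusions:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([self.residues(n) for n in self.alignment_exclusions]))


@dataclass
class TrajectoryEnsemble:
    """Replicate trajectory frames for one variant in one nucleotide state.

    Attributes
    ----------
    variant_id : str
        Variant label, e.g. ``"WT"`` or ``"G12D"``.
    nucleotide : str
        ``"GDP"`` or ``"GTP"``.
    coords : ndarray, shape (n_replicates, n_frames, n_atoms, 3)
        Cartesian coordinates in Angstrom.
    atoms : DataFrame
        One row per atom with columns ``resid`` (1-based), ``resname``,
        ``name``, ``element``.
    provenance : list of str
        Source file paths, when loaded from disk.
    """

    variant_id: str
    nucleotide: str
    coords: np.ndarray
    atoms: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[-1] != 3:
            raise ValueError("coords must have shape (n_replicates, n_frames, n_atoms, 3)")
        if self.coords.shape[2] != len(self.atoms):
            raise ValueError(
                f"coordinate array has {self.coords.shape[2]} atoms but atom table has {len(self.atoms)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.nucleotide not in ("GDP", "GTP"):
            raise ValueError(f"nucleotide must be 'GDP' or 'GTP', got {self.nucleotide!r}")

    @property
    def n_replicates(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        """Frames per replicate."""
        return self.coords.shape[1]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[2]

    @property
    def ca_mask(self) -> np.ndarray:
        return (self.atoms["name"] == "CA").to_numpy()

    @property
    def ca_resids(self) -> np.ndarray:
        return self.atoms.loc[self.atoms["name"] == "CA", "resid"].to_numpy()

    def frames(self) -> np.ndarray:
        """All frames pooled across replicates, shape (n_rep*n_frames, n_atoms, 3)."""
        return self.coords.reshape(-1, self.n_atoms, 3)

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, shape (n_replicates, n_frames, n_ca, 3)."""
        return self.coords[:, :, self.ca_mask, :]

    def with_coords(self, coords: np.ndarray) -> "TrajectoryEnsemble":
        return replace(self, coords=np.asarray(coords, dtype=float))


def _atoms_from_universe(universe) -> pd.DataFrame:
    ag = universe.atoms
    try:
        elements = [str(e) for e in ag.elements]
    except Exception:
        elements = [str(n)[0] for n in ag.names]
    return pd.DataFrame(
        {
            "resid": ag.resids.astype(int),
            "resname": [str(r) for r in ag.resnames],
            "name": [str(n) for n in ag.names],
            "element": elements,
        }
    )


def load_ensemble(
    topology_path: str,
    trajectory_paths,
    variant_id: str,
    nucleotide: str,
    chain: str | None = None,
) -> TrajectoryEnsemble:
    """Read one topology plus one trajectory file per replicate.

    Each trajectory file becomes one replicate block; all must have the same
    number of frames and match the topology's atom count.  ``chain`` keeps a
    single chain/segment (by segid or chainID) when the file has several.
    """
    import MDAnalysis as mda

    if not os.path.exists(topology_path):
        raise FileNotFoundError(topology_path)
    trajectory_paths = list(trajectory_paths)
    blocks = []
    atoms = None
    for path in trajectory_paths:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            u = mda.Universe(topology_path, path)
        except (ValueError, IOError, OSError) as exc:
            raise FormatError(f"cannot read trajectory {path!r} with topology {topology_path!r}: {exc}") from exc
        ag = u.atoms
        if chain is not None:
            ag = u.select_atoms(f"segid {chain}") or u.select_atoms(f"chainID {chain}")
        if atoms is None:
            atoms = _atoms_from_universe(u) if chain is None else _atoms_from_universe_subset(ag)
        frames = []
        try:
            for ts in u.trajectory:
                frames.append(ag.positions.astype(float).copy())
        except (ValueError, IOError, OSError) as exc:
            raise FormatError(f"truncated frame {len(frames)} in {path!r}: {exc}") from exc
        blocks.append(np.asarray(frames))
    n_frames = {b.shape[0] for b in blocks}
    if len(n_frames) != 1:
        raise FormatError(f"replicate trajectories have unequal frame counts: {sorted(n_frames)}")
    coords = np.stack(blocks)
    return TrajectoryEnsemble(
        variant_id=variant_id,
        nucleotide=nucleotide,
        coords=coords,
        atoms=atoms,
        provenance=[topology_path, *trajectory_paths],
    )


def _atoms_from_universe_subset(ag) -> pd.DataFrame:
    try:
        elements = [str(e) for e in ag.elements]
    except Exception:
        elements = [str(n)[0] for n in ag.names]
    return pd.DataFrame(
        {
            "resid": ag.resids.astype(int),
            "resname": [str(r) for r in ag.resnames],
            "name": [str(n) for n in ag.names],
            "element": elements,
        }
    )


def write_ensemble(ensemble: TrajectoryEnsemble, outdir: str, fmt: str = "dcd") -> dict:
    """Write topology (PDB, first frame) plus per-replicate trajectories.

    ``fmt`` is ``"dcd"`` or ``"pdb"`` (multi-model).  Returns the written
    paths as ``{"topology": ..., "trajectories": [...]}``.
    """
    import MDAnalysis as mda

    os.makedirs(outdir, exist_ok=True)
    n_atoms = ensemble.n_atoms
    u = mda.Universe.empty(n_atoms, n_residues=ensemble.atoms["resid"].nunique(), atom_resindex=pd.factorize(ensemble.atoms["resid"])[0], trajectory=True)
    u.add_TopologyAttr("names", ensemble.atoms["name"].tolist())
    resnames = ensemble.atoms.groupby("resid", sort=True)["resname"].first()
    u.add_TopologyAttr("resnames", resnames.tolist())
    u.add_TopologyAttr("resids", resnames.index.to_numpy())
    u.add_TopologyAttr("elements", ensemble.atoms["element"].tolist())
    u.atoms.positions = ensemble.coords[0, 0]

    base = f"{ensemble.variant_id}_{ensemble.nucleotide}"
    top_path = os.path.join(outdir, f"{base}_top.pdb")
    u.atoms.write(top_path)

    ext = "dcd" if fmt == "dcd" else "pdb"
    traj_paths = []
    for r in range(ensemble.n_replicates):
        path = os.path.join(outdir, f"{base}_rep{r + 1}.{ext}")
        with mda.Writer(path, n_atoms, multiframe=True) as w:
            for t in range(ensemble.n_frames):
                u.atoms.positions = ensemble.coords[r, t]
                w.write(u.atoms)
        traj_paths.append(path)
    return {"topology": top_path, "trajectories": traj_paths}


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation)`` such that ``mobile @ rotation.T +
    translation`` minimizes the RMSD to ``reference``.  Both inputs are
    ``(n, 3)`` with ``n >= 3``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise ValueError("need matched point sets of at least 3 points")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    h = (mobile - mu_m).T @ (reference - mu_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    return rot, trans


def superpose(
    ensemble: TrajectoryEnsemble,
    reference_coords: np.ndarray,
    region_map: RegionMap | None = None,
) -> TrajectoryEnsemble:
    """Rigid-body fit every frame onto a reference Cα conformation.

    The rotation/translation is computed on Cα atoms outside the region
    map's ``alignment_exclusions`` (by default the two Switch loops, whose
    mobility would otherwise contaminate the fit) and applied to all atoms.
    """
    region_map = region_map or RegionMap()
    reference_coords = np.asarray(reference_coords, dtype=float)
    ca_mask = ensemble.ca_mask
    ca_resids = ensemble.ca_resids
    if reference_coords.shape != (ca_resids.size, 3):
        raise ValueError(
            f"reference has shape {reference_coords.shape}, expected ({ca_resids.size}, 3) Cα coordinates"
        )
    excluded = set(region_map.excluded_residues().tolist())
    fit_sel = np.array([r not in excluded for r in ca_resids])
    if fit_sel.sum() < 3:
        raise ValueError("fewer than 3 Cα atoms available for fitting after region exclusion")
    ca_idx = np.flatnonzero(ca_mask)
    fit_idx = ca_idx[fit_sel]
    ref_fit = reference_coords[fit_sel]

    out = np.empty_like(ensemble.coords)
    for r in range(ensemble.n_replicates):
        for t in range(ensemble.n_frames):
            frame = ensemble.coords[r, t]
            rot, trans = kabsch_fit(frame[fit_idx], ref_fit)
            out[r, t] = frame @ rot.T + trans
    return ensemble.with_coords(out)


def assess_switch_resolution(atoms: pd.DataFrame, region_map: RegionMap | None = None) -> dict:
    """Flag each named region resolved/unresolved in a static structure.

    A region is unresolved iff any residue in its range lacks a Cα record —
    the situation in crystal structures where a mobile loop could not be
    assigned coordinates.
    """
    region_map = region_map or RegionMap()
    ca_resids = set(atoms.loc[atoms["name"] == "CA", "resid"].astype(int).tolist())
    flags = {}
    for name in region_map.ranges:
        wanted = region_map.residues(name)
        flags[name] = "resolved" if all(r in ca_resids for r in wanted) else "unresolved"
    return flags


def read_structure(path: str, chain: str | None = "A") -> tuple[np.ndarray, pd.DataFrame]:
    """Read a PDB structure; return (coords (n_atoms,3), atom table).

    Keeps one chain (default A) when the file has several; gap-aware — the
    atom table carries the author residue numbering so missing residues are
    simply absent rows.
    """
    import MDAnalysis as mda

    u = mda.Universe(path)
    ag = u.atoms
    if chain is not None:
        for sel in (f"chainID {chain}", f"segid {chain}"):
            try:
                sub = u.select_atoms(sel)
            except Exception:
                sub = None
            if sub is not None and len(sub) > 0:
                ag = sub
                break
    table = _atoms_from_universe_subset(ag)
    return ag.positions.astype(float).copy(), table
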