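"""Per-residue mobility, fluctuation-profile SSR, and RMSD to reference poses.

RMSF is computed per replicate from Cα atoms (each residue's root-mean-square
excursion about its replicate-mean position) and averaged across replicates.
The SSR statistic compares two per-residue RMSF profiles by the sum of
squared residuals; variants whose |SSR - SSR_WT| falls below a configurable
threshold (default 0.5 A^2) count as having WT-like flexibility.  RMSD
series measure how closely evenly-sampled frames match an external reference
conformation (e.g. a GAP- or GEF-bound crystal pose) after a Switch-excluded
least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rasdyn.trajectory_io import RegionMap, TrajectoryEnsemble, kabsch_fit


@dataclass
class RMSFProfile:
    """Replicate-averaged per-residue Cα fluctuation profile."""

    variant_id: str
    nucleotide: str
    residues: np.ndarray  # 1-based residue indices
    per_replicate: np.ndarray  # (n_replicates, n_residues)
    profile: np.ndarray  # replicate mean, (n_residues,)

    def region_mean(self, region_map: RegionMap, name: str) -> float:
        """Mean RMSF over one named region (e.g. a Switch loop)."""
        mask = np.isin(self.residues, region_map.residues(name))
        return float(self.profile[mask].mean())


def compute_rmsf(ensemble: TrajectoryEnsemble, aggregate: str = "mean") -> RMSFProfile:
    """Per-residue Cα RMSF, computed per replicate then aggregated.

    For replicate r, ``RMSF_i = sqrt(mean_t ||r_i(t) - <r_i>_r||^2)``.  The
    ensemble must already be superposed to a common frame.  ``aggregate`` is
    ``"mean"`` (default) or ``"median"`` across replicates.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF is undefined for single-frame replicates")
    ca = ensemble.ca_coords()  # (n_rep, n_frames, n_res, 3)
    mean = ca.mean(axis=1, keepdims=True)
    sq = ((ca - mean) ** 2).sum(axis=-1)  # (n_rep, n_frames, n_res)
    per_rep = np.sqrt(sq.mean(axis=1))  # (n_rep, n_res)
    if aggregate == "mean":
        profile = per_rep.mean(axis=0)
    elif aggregate == "median":
        profile = np.median(per_rep, axis=0)
    else:
        raise ValueError("aggregate must be 'mean' or 'median'")
    return RMSFProfile(
        variant_id=ensemble.variant_id,
        nucleotide=ensemble.nucleotide,
        residues=ensemble.ca_resids.copy(),
        per_replicate=per_rep,
        profile=profile,
    )


def rmsf_ssr(profile, reference_profile) -> float:
    """Sum of squared residuals between two per-residue RMSF profiles (A^2)."""
    a = profile.profile if isinstance(profile, RMSFProfile) else np.asarray(profile, float)
    b = (
        reference_profile.profile
        if isinstance(reference_profile, RMSFProfile)
        else np.asarray(reference_profile, float)
    )
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return float(((a - b) ** 2).sum())


def ssr_similarity(ssr_variant: float, ssr_wt: float, threshold: float = 0.5) -> str:
    """'similar' when |SSR_variant - SSR_WT| < threshold, else 'deviated'."""
    return "similar" if abs(ssr_variant - ssr_wt) < threshold else "deviated"


def mean_rmsf_profile(profiles) -> np.ndarray:
    """Across-variant average profile, the default SSR reference."""
    stack = np.array([p.profile if isinstance(p, RMSFProfile) else p for p in profiles])
    return stack.mean(axis=0)


@dataclass
class RMSDSeries:
    """RMSD of evenly sampled frames against one reference conformation."""

    variant_id: str
    nucleotide: str
    reference_name: str
    values: np.ndarray  # (n_replicates, n_samples)
    frame_indices: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0

    def pooled(self) -> np.ndarray:
        return self.values.ravel()


def even_sample_indices(n_frames: int, n_samples: int) -> np.ndarray:
    """Evenly strided frame indices including the first frame."""
    stride = max(1, n_frames // max(1, n_samples))
    idx = np.arange(0, n_frames, stride)
    return idx[:n_samples]


def compute_rmsd_to_reference(
    ensemble: TrajectoryEnsemble,
    reference_coords: np.ndarray,
    reference_resids: np.ndarray | None = None,
    region_map: RegionMap | None = None,
    n_samples: int = 100,
    selection_resids: np.ndarray | None = None,
    reference_name: str = "reference",
) -> RMSDSeries:
    """RMSD of evenly selected frames to an external reference pose.

    The fit is a Kabsch superposition on shared Cα atoms outside the region
    map's excluded Switch loops; the RMSD is then evaluated over
    ``selection_resids`` (default: all shared Cα).  Residue matching is
    gap-aware — only residue indices present in both structures are used, so
    references with unresolved loops are handled.
    """
    region_map = region_map or RegionMap()
    reference_coords = np.asarray(reference_coords, dtype=float)
    ens_resids = ensemble.ca_resids
    if reference_resids is None:
        if reference_coords.shape[0] != ens_resids.size:
            raise ValueError("reference length differs from ensemble; pass reference_resids for gap-aware mapping")
        reference_resids = ens_resids
    reference_resids = np.asarray(reference_resids)

    shared = np.intersect1d(ens_resids, reference_resids)
    if shared.size == 0:
        raise ValueError("no shared Cα residues between ensemble and reference")
    ens_pos = {r: i for i, r in enumerate(ens_resids)}
    ref_pos = {r: i for i, r in enumerate(reference_resids)}
    ens_idx = np.array([ens_pos[r] for r in shared])
    ref_idx = np.array([ref_pos[r] for r in shared])

    excluded = set(region_map.excluded_residues().tolist())
    fit_mask = np.array([r not in excluded for r in shared])
    if fit_mask.sum() < 3:
        raise ValueError("fewer than 3 shared Cα atoms available for fitting")
    if selection_resids is None:
        sel_mask = np.ones(shared.size, dtype=bool)
    else:
        sel_mask = np.isin(shared, np.asarray(selection_resids))
        if not sel_mask.any():
            raise ValueError("RMSD selection shares no residues with the reference")

    ca = ensemble.ca_coords()
    idx = even_sample_indices(ensemble.n_frames, n_samples)
    ref_shared = reference_coords[ref_idx]
    out = np.empty((ensemble.n_replicates, idx.size))
    for r in range(ensemble.n_replicates):
        for j, t in enumerate(idx):
            frame = ca[r, t][ens_idx]
            rot, trans = kabsch_fit(frame[fit_mask], ref_shared[fit_mask])
            fitted = frame @ rot.T + trans
            diff = fitted[sel_mask] - ref_shared[sel_mask]
            out[r, j] = np.sqrt((diff**2).sum(axis=1).mean())
    return RMSDSeries(
        variant_id=ensemble.variant_id,
        nucleotide=ensemble.nucleotide,
        reference_name=reference_name,
        values=out,
        frame_indices=idx,
    )
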