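"""PCA of Cα coordinates, free-energy landscapes, well occupancy, PC scores.

Principal components are computed in Cartesian space over pooled, superposed
Cα coordinates.  A free-energy landscape over a 2D PC subspace is the
Boltzmann inversion of the observed density, F = -kT ln(rho/rho_max), so the
most occupied bin sits at F = 0.  Along PC1 the pooled density is often
bimodal for the GDP state — Switch 1 folded in (well I, the WT-dominant
side) versus extended (well II); the well boundary is the density minimum
between the two main KDE modes and each variant's occupancy ratio is its
fraction of frames on the well-II side.  Per-variant PC sampling is
standardized against WT: z = (mean_mut - mean_WT)/SD_WT per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from rasdyn.trajectory_io import TrajectoryEnsemble

#: Boltzmann constant in kcal/(mol K)
KB_KCAL = 0.0019872


def _as_frame_matrix(x) -> np.ndarray:
    """Pooled frames as a (n_frames, 3*n_ca) matrix."""
    if isinstance(x, TrajectoryEnsemble):
        ca = x.ca_coords()
        return ca.reshape(-1, ca.shape[2] * 3)
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    if x.ndim == 2:
        return x
    raise ValueError("expected a TrajectoryEnsemble, (n, d) matrix or (n, n_ca, 3) array")


@dataclass
class PCModel:
    """PCA basis over flattened Cα coordinates."""

    mean: np.ndarray  # (3*n_ca,)
    components: np.ndarray  # (k, 3*n_ca), orthonormal rows
    eigenvalues: np.ndarray  # (k,), variances along components (A^2)
    variance_fractions: np.ndarray  # (k,), relative to total coordinate variance
    total_variance: float
    n_frames: int
    scope: str = "pooled"

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(
    ensembles,
    n_components: int | None = None,
    stride: int = 1,
    scope: str = "pooled",
) -> PCModel:
    """Eigendecomposition of pooled Cα coordinate covariance.

    ``ensembles`` is one ensemble/array or a collection; all must be
    superposed to a common reference and share the Cα count.  The component
    sign is fixed so each component's largest-magnitude loading is positive,
    making scores reproducible across runs.  ``scope`` is a free-text tag
    recorded in the model (e.g. "GDP", "GTP", "pooled").
    """
    if isinstance(ensembles, (TrajectoryEnsemble, np.ndarray)):
        ensembles = [ensembles]
    blocks = [_as_frame_matrix(e)[::stride] for e in ensembles]
    dims = {b.shape[1] for b in blocks}
    if len(dims) != 1:
        raise ValueError(f"ensembles have differing Cα dimensionality: {sorted(dims)}")
    x = np.vstack(blocks)
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 frames")
    mean = x.mean(axis=0)
    centered = x - mean
    # thin SVD handles frames < dimensions
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (x.shape[0] - 1)
    total = float(eig.sum())
    if total <= 0:
        raise ValueError("zero total variance: all frames identical")
    k = eig.size if n_components is None else min(n_components, eig.size)
    comps = vt[:k].copy()
    for j in range(k):
        if comps[j, np.argmax(np.abs(comps[j]))] < 0:
            comps[j] = -comps[j]
    return PCModel(
        mean=mean,
        components=comps,
        eigenvalues=eig[:k],
        variance_fractions=eig[:k] / total,
        total_variance=total,
        n_frames=x.shape[0],
        scope=scope,
    )


def project(x, model: PCModel) -> np.ndarray:
    """Per-frame PC coordinates, ``components @ (frame - mean)``; order kept."""
    mat = _as_frame_matrix(x) if not (isinstance(x, np.ndarray) and x.ndim == 1) else x[None, :]
    if mat.shape[1] != model.mean.size:
        raise ValueError(f"dimension mismatch: frames have {mat.shape[1]}, model has {model.mean.size}")
    return (mat - model.mean) @ model.components.T


def reconstruct(projections: np.ndarray, model: PCModel) -> np.ndarray:
    """Coordinates rebuilt from PC coordinates (inverse of :func:`project`)."""
    projections = np.atleast_2d(np.asarray(projections, float))
    k = projections.shape[1]
    return model.mean + projections @ model.components[:k]


@dataclass
class FESurface:
    """Free-energy grid over a 2D PC subspace.

    ``free_energy`` is in kcal/mol with the most occupied bin at exactly 0;
    bins with no observations are NaN (undefined, not infinite barriers).
    """

    xedges: np.ndarray
    yedges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    kt: float
    pcs: tuple


def build_fel(
    projections: np.ndarray,
    pcs: tuple = (0, 1),
    n_bins: int = 50,
    temperature: float = 300.0,
    padding: float = 0.05,
) -> FESurface:
    """Boltzmann-inverted 2D histogram: F = -kT ln(rho/rho_max).

    The grid spans the data extent padded by ``padding`` on each side.
    Scaling all counts by a constant leaves F unchanged (only the density
    ratio enters).
    """
    projections = np.asarray(projections, dtype=float)
    a, b = pcs
    x, y = projections[:, a], projections[:, b]
    if x.size == 0:
        raise ValueError("no projections supplied")

    def _padded(v):
        lo, hi = v.min(), v.max()
        span = hi - lo
        pad = padding * span if span > 0 else max(abs(hi), 1.0) * padding
        return lo - pad, hi + pad

    counts, xe, ye = np.histogram2d(x, y, bins=n_bins, range=[_padded(x), _padded(y)])
    kt = KB_KCAL * temperature
    occupied = counts > 0
    if not occupied.any():
        raise ValueError("no occupied bins")
    fe = np.full_like(counts, np.nan)
    fe[occupied] = -kt * np.log(counts[occupied] / counts.max())
    return FESurface(xedges=xe, yedges=ye, counts=counts, free_energy=fe, kt=kt, pcs=tuple(pcs))


@dataclass
class WellBoundary:
    """Position of the density minimum separating the two PC1 wells."""

    position: float | None
    unimodal: bool
    density_grid: np.ndarray | None = None
    density: np.ndarray | None = None


def detect_wells(
    pc1_samples: np.ndarray, grid_size: int = 512, min_peak_fraction: float = 0.05
) -> WellBoundary:
    """Locate the two-well boundary along PC1 from the pooled density.

    A Gaussian KDE (Silverman bandwidth, deterministic) is evaluated on a
    grid; the boundary is the density minimum between the two highest local
    maxima.  Maxima below ``min_peak_fraction`` of the density peak (in
    height or prominence) are treated as sampling ripple, so a unimodal
    density returns ``position=None`` with the ``unimodal`` flag set instead
    of a spurious boundary.
    """
    pc1_samples = np.asarray(pc1_samples, dtype=float).ravel()
    if pc1_samples.size < 100:
        raise ValueError("well detection needs at least 100 samples for a stable density")
    kde = gaussian_kde(pc1_samples, bw_method="silverman")
    lo, hi = pc1_samples.min(), pc1_samples.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    floor = min_peak_fraction * dens.max()
    peaks, _ = find_peaks(dens, height=floor, prominence=floor)
    if peaks.size < 2:
        return WellBoundary(position=None, unimodal=True, density_grid=grid, density=dens)
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley = left + int(np.argmin(dens[left : right + 1]))
    return WellBoundary(position=float(grid[valley]), unimodal=False, density_grid=grid, density=dens)


@dataclass
class WellStats:
    """Per-replicate and pooled occupancy of the two PC1 wells."""

    boundary: float
    counts_i: np.ndarray  # per replicate
    counts_ii: np.ndarray
    ratio: float  # pooled n_II / (n_I + n_II)
    per_replicate_ratio: np.ndarray
    well_ii_side: str


def occupancy_ratio(
    projections,
    boundary: WellBoundary | float,
    well_ii_side: str = "negative",
) -> WellStats:
    """Fraction of frames on the well-II side of the PC1 boundary.

    ``projections`` is a (n_replicates, n_frames) array or list of per-
    replicate PC1 arrays.  ``well_ii_side`` says which side of the boundary
    is well II — by convention the side opposite the WT modal well (for the
    Switch-1-extended conformations).  Ratio 0 means well II is never
    sampled, 1 means well I is never sampled.
    """
    if isinstance(boundary, WellBoundary):
        if boundary.unimodal or boundary.position is None:
            raise ValueError(
                "well boundary is undefined (unimodal density); occupancy ratio is not applicable"
            )
        pos = boundary.position
    else:
        pos = float(boundary)
    if well_ii_side not in ("negative", "positive"):
        raise ValueError("well_ii_side must be 'negative' or 'positive'")
    reps = [np.asarray(r, dtype=float).ravel() for r in projections]
    counts_i, counts_ii, ratios = [], [], []
    for rep in reps:
        in_ii = rep < pos if well_ii_side == "negative" else rep > pos
        n_ii = int(in_ii.sum())
        counts_ii.append(n_ii)
        counts_i.append(rep.size - n_ii)
        ratios.append(n_ii / rep.size if rep.size else np.nan)
    total = sum(counts_i) + sum(counts_ii)
    return WellStats(
        boundary=pos,
        counts_i=np.array(counts_i),
        counts_ii=np.array(counts_ii),
        ratio=sum(counts_ii) / total,
        per_replicate_ratio=np.array(ratios),
        well_ii_side=well_ii_side,
    )


@dataclass
class PCStandardScore:
    """WT-standardized PC sampling scores for one variant/state."""

    variant_id: str
    nucleotide: str
    z: np.ndarray  # per-PC, typically the top 3


def pc_standard_score(
    variant_projections: np.ndarray,
    wt_projections: np.ndarray,
    n_pcs: int = 3,
    variant_id: str = "",
    nucleotide: str = "",
) -> PCStandardScore:
    """z_k = (mean_mut,k - mean_WT,k) / SD_WT,k for the top PCs.

    The WT spread is the SD of the pooled WT per-frame projections.  A
    variant sampling exactly like WT scores (0, 0, 0).
    """
    var = np.atleast_2d(np.asarray(variant_projections, float))[:, :n_pcs]
    wt = np.atleast_2d(np.asarray(wt_projections, float))[:, :n_pcs]
    sd = wt.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("WT projection SD is zero on some component")
    z = (var.mean(axis=0) - wt.mean(axis=0)) / sd
    return PCStandardScore(variant_id=variant_id, nucleotide=nucleotide, z=z)
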