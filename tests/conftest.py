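import numpy as np
import pandas as pd
import pytest

from rasdyn.synthetic_data import (
    EnsembleSpec,
    ModeDef,
    TwoWellDef,
    generate_ensemble,
    random_orthonormal_modes,
)
from rasdyn.trajectory_io import TrajectoryEnsemble


def ca_atom_table(n_residues: int, resnames=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resid": np.arange(1, n_residues + 1),
            "resname": ["ALA"] * n_residues if resnames is None else resnames,
            "name": ["CA"] * n_residues,
            "element": ["C"] * n_residues,
        }
    )


def make_ensemble(coords, variant_id="toy", nucleotide="GDP", atoms=None) -> TrajectoryEnsemble:
    coords = np.asarray(coords, dtype=float)
    if atoms is None:
        atoms = ca_atom_table(coords.shape[2])
    return TrajectoryEnsemble(variant_id=variant_id, nucleotide=nucleotide, coords=coords, atoms=atoms)


@pytest.fixture
def noise_ensemble():
    """Small noise-only ensemble with known isotropic fluctuation."""
    spec = EnsembleSpec(n_residues=25, n_replicates=2, n_frames=300, noise=0.4, seed=11)
    return generate_ensemble(spec)


@pytest.fixture
def twowell_ensemble():
    """Ensemble with a planted two-state Switch-like coordinate."""
    n_res = 30
    direction = random_orthonormal_modes(n_res, 1, seed=5, region=(10, 20))[0]
    spec = EnsembleSpec(
        n_residues=n_res,
        n_replicates=3,
        n_frames=500,
        twowell=TwoWellDef(direction=direction, center_i=2.0, center_ii=-3.0, occupancy_ii=0.3, dwell=20),
        noise=0.2,
        seed=7,
    )
    return generate_ensemble(spec)
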