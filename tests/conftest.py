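"""Shared fixtures: small synthetic structures and mixtures."""

import numpy as np
import pytest

from pammotifs.pamm import FeatureMatrix
from pammotifs.synth import (
    BackboneSpec,
    MixtureSpec,
    build_backbone,
    build_hb_toy,
    sample_mixture,
    write_pdb,
)

HELIX_PHI_PSI = (-57.0, -47.0)
SHEET_PHI_PSI = (-139.0, 135.0)

TOY_GEOMETRIES = [
    (2.9, 1.95, 1.0, "NHO"),
    (2.8, 1.9, 1.0, "NHN"),
    (2.7, 1.8, 0.98, "OHO"),
    (3.0, 2.1, 1.0, "OHN"),
    (3.3, 2.6, 1.1, "NHO"),
]


@pytest.fixture(scope="session")
def helix_structure():
    return build_backbone(BackboneSpec(phi_psi_sequence=[HELIX_PHI_PSI] * 10))


@pytest.fixture(scope="session")
def sheet_structure():
    return build_backbone(BackboneSpec(phi_psi_sequence=[SHEET_PHI_PSI] * 10))


@pytest.fixture(scope="session")
def hb_toy_structure():
    return build_hb_toy(TOY_GEOMETRIES)


@pytest.fixture
def helix_pdb(helix_structure, tmp_path):
    path = tmp_path / "helix.pdb"
    write_pdb(helix_structure, path)
    return path


@pytest.fixture(scope="session")
def two_blob_features():
    """Two well-separated isotropic Gaussians, weights 0.7/0.3."""
    spec = MixtureSpec(
        means=[np.array([0.0, 0.0]), np.array([10.0, 10.0])],
        covariances=[np.eye(2), np.eye(2)],
        weights=np.array([0.7, 0.3]),
        n_samples=20000,
        seed=421,
    )
    return sample_mixture(spec)


@pytest.fixture(scope="session")
def small_model(two_blob_features):
    from pammotifs.pamm import fit_pamm

    fm, _ = two_blob_features
    return fit_pamm(fm, n_grid=400, bandwidth_scale=0.5, qs_scale=1.0, seed=5)
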