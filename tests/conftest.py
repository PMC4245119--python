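import numpy as np
import pytest

import psnkit as pk


TWO_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  C   ALA A   1       2.000  -1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       3.200  -1.500   0.000  1.00  0.00           O
ATOM      6  N   ALA A   2       1.200  -2.400   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       1.700  -3.800   0.000  1.00  0.00           C
ATOM      8  CB  ALA A   2       3.200  -3.900   0.200  1.00  0.00           C
ATOM      9  C   ALA A   2       1.100  -4.600   1.200  1.00  0.00           C
ATOM     10  O   ALA A   2       0.200  -4.200   1.900  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def helix10():
    return pk.build_toy_structure(
        pk.ToyStructureSpec(n_residues=10, geometry="alpha_helix"))


@pytest.fixture(scope="session")
def two_domain50():
    return pk.build_toy_structure(
        pk.ToyStructureSpec(n_residues=50, geometry="two_domain", seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sample_isotropic(model, sigma2, n_frames, seed=0):
    """Ensemble with independent isotropic per-residue variance sigma2."""
    scale = np.full(model.n_residues, sigma2)
    cov = pk.make_planted_covariance(
        pk.PlantedCovarianceSpec(per_residue_scale=scale), model)
    return pk.sample_ensemble(model, cov, n_frames, seed=seed)
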