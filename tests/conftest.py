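import numpy as np
import pytest

import bafdyn as b
from bafdyn.synthetic import core_ranges


@pytest.fixture(scope="session")
def toy_dimer() -> b.StructureModel:
    return b.build_toy_dimer(89)


@pytest.fixture(scope="session")
def toy_core(toy_dimer):
    return core_ranges(toy_dimer)


@pytest.fixture(scope="session")
def restricted_traj(toy_dimer) -> b.TrajectoryEnsemble:
    """Small Gly16Arg-like ensemble (unimodal arm, bridge enforced)."""
    return b.sample_ensemble(toy_dimer, b.restricted_recipe(n_frames=400, seed=11))


@pytest.fixture(scope="session")
def open_traj(toy_dimer) -> b.TrajectoryEnsemble:
    """Small wild-type-like ensemble (bimodal arm, no bridge)."""
    return b.sample_ensemble(toy_dimer, b.open_recipe(n_frames=400, seed=12))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


TOY_PDB = """\
HELIX    1   1 ALA A    2  ALA A    3  1                                   2
ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C
ATOM      2  CA  ALA A   2      12.500  -7.250   3.000  1.00  0.00           C
ATOM      3  N   GLY A   3       0.000   1.500  -2.250  1.00  0.00           N
END
"""


@pytest.fixture()
def toy_pdb_file(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path
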