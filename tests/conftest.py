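import pytest

from coupledmoves import fixtures
from coupledmoves.energy import EnergyConfig, EnergyModel
from coupledmoves.rotamers import RotamerLibrary


def random_pose_change(pose, rotlib, rng):
    """Random side-chain, backrub or ligand move description (test helper)."""
    from coupledmoves.backrub import BackrubMove
    from coupledmoves.rotamers import get_rotamers
    from coupledmoves.sampler import BackrubChange, LigandChange, SidechainChange

    kind = rng.integers(3) if pose.ligand is not None else rng.integers(2)
    if kind == 0:
        key = pose.residues[int(rng.integers(1, len(pose.residues) - 1))].key
        rotset = get_rotamers(pose, key, ("A", "S", "L", "V", "F"), rotlib)
        rot = rotset.rotamers[int(rng.integers(len(rotset.rotamers)))]
        return SidechainChange(key, rot)
    if kind == 1:
        key = pose.residues[int(rng.integers(1, len(pose.residues) - 1))].key
        return BackrubChange(BackrubMove(key, float(rng.normal(0, 4.57))))
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(rng.normal(size=3) * 0.02).as_matrix()
    return LigandChange(R, rng.normal(0, 0.1, size=3), pose.ligand.centroid())


@pytest.fixture(scope="session")
def rotlib():
    return RotamerLibrary.packaged()


@pytest.fixture(scope="session")
def model(rotlib):
    return EnergyModel(EnergyConfig(), rotlib)


@pytest.fixture(scope="session")
def helix(rotlib):
    """Mixed-sequence ideal helix; tests must copy before mutating."""
    return fixtures.make_helix("AALSFALTA", rotlib=rotlib)


@pytest.fixture(scope="session")
def toy_complex(rotlib):
    """Default toy complex (hbond-probe, target L->S); copy before mutating."""
    return fixtures.make_toy_complex(fixtures.ToyComplexSpec(), rotlib)


@pytest.fixture(scope="session")
def spec_pair(rotlib):
    """(native_pose, nonnative_pose, task, notes) for the specificity toy."""
    return fixtures.specificity_pair(0, rotlib)
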