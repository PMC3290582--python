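import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.transform import Rotation

from ccpdock import fixtures, structures

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rigid_transform(rng):
    """A uniformly random rotation and a bounded random translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def apply_rigid(R, t, pos):
    return None if pos is None else np.asarray(pos) @ R.T + t


def transform_protein_sites(sites, R, t):
    return [
        structures.ProteinSite(
            residue_type=s.residue_type, chain_id=s.chain_id,
            residue_index=s.residue_index,
            position=apply_rigid(R, t, s.position),
            extent=s.extent, charge=s.charge,
            ca_position=apply_rigid(R, t, s.ca_position),
        )
        for s in sites
    ]


def transform_na_sites(sites, R, t):
    return [
        structures.NucleotideSites(
            base_type=n.base_type, chain_id=n.chain_id,
            residue_index=n.residue_index,
            major_position=apply_rigid(R, t, n.major_position),
            minor_position=apply_rigid(R, t, n.minor_position),
            p_position=apply_rigid(R, t, n.p_position),
            c2p_position=apply_rigid(R, t, n.c2p_position),
            c4_position=apply_rigid(R, t, n.c4_position),
        )
        for n in sites
    ]


@pytest.fixture(scope="session")
def duplex10():
    return fixtures.build_bdna("GATTACAGAT")


@pytest.fixture(scope="session")
def toy_layout():
    return [
        ("LYS", (12.0, 0.0, 5.0)),
        ("ASP", (0.0, 12.0, 10.0)),
        ("ALA", (-12.0, 0.0, 15.0)),
        ("THR", (0.0, -12.0, 20.0)),
        ("GLY", (12.0, 12.0, 25.0)),
    ]


@pytest.fixture(scope="session")
def toy_protein(toy_layout):
    return fixtures.build_toy_protein(toy_layout, rng_seed=0)


@pytest.fixture(scope="session")
def native_pose(toy_protein, duplex10):
    return structures.ComplexPose(
        protein_sites=toy_protein, na_sites=duplex10.sites, pose_id="native"
    )
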