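import numpy as np
import pytest

import ciliabase as cb

#: True axial zone boundaries (nm) of the default five-zone barrel model.
TRUE_BOUNDARIES = {"P->C": 205.0, "C->B": 435.0, "B->TZ": 465.0, "TZ->AX": 718.0}
ZONE_DIAMETERS = {"P": 215.0, "C": 197.0, "B": 190.0, "TZ": 169.0, "AX": 178.0}


@pytest.fixture(scope="session")
def clean_cilium() -> cb.ParticleSet:
    """Noise-free default barrel: exact geometry, exact labels."""
    return cb.gen_cilium(cb.CiliumModel(jitter_sigma=0.0, label_noise=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_cilium() -> cb.ParticleSet:
    """Default study conditions: 20% label noise, 1 nm positional jitter."""
    return cb.gen_cilium(cb.CiliumModel(jitter_sigma=1.0, label_noise=0.2, seed=42))


@pytest.fixture(scope="session")
def necklace_default():
    """7 rows x 54 particles at 17.5 nm pitch, 0.5 nm noise."""
    model = cb.NecklaceModel(noise_sigma=0.5, seed=7)
    params, pos, rows = cb.gen_necklace(model)
    return model, params, pos, rows


@pytest.fixture(scope="session")
def planted_crosslinks():
    """Three-chain toy structure with 100 true links and 50 decoys."""
    sm = cb.gen_structure(n_chains=3, n_res=120)
    model = cb.XlSimModel(n_true=100, n_decoy=50, seed=5)
    table_a, table_b, truth = cb.gen_crosslinks(model, sm)
    return sm, model, table_a, table_b, truth


def cylinder_points(radius, length, n, seed=0, sigma=0.0):
    """Uniform random points on (or near) a cylinder surface along z."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, length, n)
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th), z])
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
    return pts


def random_rigid_motion(seed):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-100.0, 100.0, 3)
    return R, t
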