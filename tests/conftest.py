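import numpy as np
import pytest

from refoldkit.synthetic_data import (
    SyntheticSpec,
    _rotation_about_axis,
    make_ideal_backbone,
    make_refolding_pair,
)


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_hinged_pair(seed: int, core: int = 80, tail: int = 20,
                     angle: float = 90.0, sigma: float = 0.5):
    """Study-condition pair: noisy core, tail hinged about a random axis."""
    spec = SyntheticSpec(
        core_length=core,
        tail_lengths=(0, tail),
        core_noise_sigma=sigma,
        hinge_angle=angle,
        seed=seed,
    )
    return make_refolding_pair(spec)


def make_divergent_tail_pair(seed: int, core: int = 80, tail: int = 20,
                             angle: float = 90.0, sigma: float = 0.0):
    """Explicit geometric construction: straight strand tail bent like a door
    hinge (axis perpendicular to the tail direction), so every tail residue
    visibly diverges from the target conformation."""
    layout = [("H", 14), ("C", 4), ("E", 8), ("C", 4)]
    full = []
    remaining = core
    i = 0
    while remaining > 0:
        state, length = layout[i % 4]
        take = min(length, remaining)
        full.append((state, take))
        remaining -= take
        i += 1
    full.append(("E", tail))  # straight tail: maximal, unambiguous divergence
    target = make_ideal_backbone(full, seed=seed)
    rng = np.random.default_rng(seed + 777)
    ca = target.ca_coords.copy()
    ca[:core] += rng.normal(0.0, sigma, size=(core, 3))
    pivot = ca[core - 1]
    tail_dir = ca[-1] - pivot
    tail_dir /= np.linalg.norm(tail_dir)
    ref = rng.normal(size=3)
    axis = np.cross(tail_dir, ref)
    axis /= np.linalg.norm(axis)
    R = _rotation_about_axis(axis, angle)
    ca[core:] = (ca[core:] - pivot) @ R.T + pivot
    return target, ca
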