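import numpy as np
import pytest

from hexchan.synthetic import SynthesisParams, build_hexamer, channel_definition


def small_params(**overrides) -> SynthesisParams:
    """A fast-to-build hexamer: few frames, few waters."""
    defaults = dict(
        n_frames=5,
        n_pocket_waters=6,
        n_bulk_waters=20,
        jitter_sigma=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return SynthesisParams(**defaults)


@pytest.fixture(scope="session")
def static_hexamer():
    """Zero-jitter hexamer shared by read-only tests."""
    params = small_params()
    traj, manifest = build_hexamer(params)
    return params, traj, manifest, channel_definition(params)


@pytest.fixture(scope="session")
def jittered_hexamer():
    params = small_params(jitter_sigma=0.25, n_frames=8, seed=7)
    traj, manifest = build_hexamer(params)
    return params, traj, manifest, channel_definition(params)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
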