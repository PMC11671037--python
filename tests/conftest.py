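import numpy as np
import pytest

from turnmap.peptide_builder import ResidueSpec, build_fragment, turn_window_template


@pytest.fixture(scope="session")
def type1_window():
    """8-residue window: extended tails around an ideal type I turn,
    Ser (g+, helical phi) at turn position 4."""
    specs = turn_window_template(
        -60, -30, -90, 0, sequence="GAADDSKL",
        chis={5: [60.0]}, phipsi_overrides={5: (-90.0, 130.0)},
    )
    return build_fragment(specs, source_id="TYPE1")


@pytest.fixture(scope="session")
def extended_octamer():
    specs = [ResidueSpec("A", -120, 130) for _ in range(8)]
    return build_fragment(specs, source_id="EXT8")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=20.0, size=3)
    return R, t
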