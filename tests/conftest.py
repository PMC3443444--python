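import dataclasses

import numpy as np
import pytest

from octgraft import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec.default()


@pytest.fixture(scope="session")
def clean_phantom(default_spec):
    """Noise-free, high-contrast phantom with its ground truth."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def speckled_phantom(default_spec):
    spec = dataclasses.replace(default_spec, speckle_sigma=0.15, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def biconvex_phantom():
    """Short, thick lens graft with sharp posterior cusps."""
    spec = PhantomSpec.default(corner_cols=(166.0, 346.0),
                               graft_central_thickness=20.0)
    return generate_phantom(spec)


def random_lens_spec(rng: np.random.Generator) -> PhantomSpec:
    """Random but valid lens-graft geometry (for oracle comparisons)."""
    half = rng.uniform(60, 150)
    mid = rng.uniform(200, 312)
    t = rng.uniform(4, 18)
    return PhantomSpec.default(
        corner_cols=(mid - half, mid + half),
        graft_central_thickness=float(t),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
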