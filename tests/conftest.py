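"""Shared fixtures: small fast phantoms and plans.

The "small" phantom keeps the default physical geometry (same organ
positions and sizes in mm) on a coarser 64 x 64 x 32 grid at
4 x 4 x 5 mm voxels, which makes brute-force voxel scans affordable.
"""

import numpy as np
import pytest
from hypothesis import settings

import sctsa as S

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

SMALL_KW = dict(shape=(64, 64, 32), spacing=(4.0, 4.0, 5.0))


@pytest.fixture(scope="session")
def small_spec() -> S.PhantomSpec:
    return S.PhantomSpec(**SMALL_KW, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return S.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_plan(small_phantom):
    ct, masks = small_phantom
    return S.default_plan(S.mask_centroid(masks.prostate, ct))


@pytest.fixture(scope="session")
def small_model(small_phantom, small_plan):
    ct, _ = small_phantom
    return S.IsocentreDoseModel(ct, small_plan)


@pytest.fixture(scope="session")
def small_cohort():
    return S.cohort(S.PhantomSpec(**SMALL_KW), n_patients=3, seed=5)


def water_box(n=41, spacing=2.0, hu=0.0):
    """A uniform block (default water) centred on the world origin."""
    shape = (n, n, n)
    origin = tuple(-(m - 1) * spacing / 2.0 for m in shape)
    vox = np.full(shape, hu, dtype=float)
    return S.CTVolume(voxels=vox, spacing=(spacing,) * 3, origin=origin)
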