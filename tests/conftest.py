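import numpy as np
import pytest
import trimesh

from aneufuse.types import SegMask, SurfaceMesh, VolumeImage


def make_icosphere(radius: float = 1.0, subdivisions: int = 3) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def make_box(extents=(1.0, 1.0, 1.0)) -> SurfaceMesh:
    tm = trimesh.creation.box(extents=extents)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    return make_box((1.0, 1.0, 1.0))


@pytest.fixture
def icosphere_r10() -> SurfaceMesh:
    return make_icosphere(radius=10.0, subdivisions=3)


@pytest.fixture
def small_volume_pair():
    """A 6x6x6 volume at 0.5 mm spacing with a centred 4x4x4 foreground
    block; already at target spacing so preprocessing leaves the grid alone."""
    rng = np.random.default_rng(11)
    data = rng.uniform(0, 50, size=(6, 6, 6))
    data[1:5, 1:5, 1:5] += 50
    vol = VolumeImage(data=data, spacing=[0.5] * 3, origin=[0.0] * 3)
    m = np.zeros((6, 6, 6), dtype=np.uint8)
    m[1:5, 1:5, 1:5] = 1
    mask = SegMask(data=m, spacing=[0.5] * 3, origin=[0.0] * 3)
    return vol, mask


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic phantom case shared across tests."""
    from aneufuse.phantom import PhantomParams, generate_case

    params = PhantomParams(seed=3)
    return params, generate_case(params, [3, 0])
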