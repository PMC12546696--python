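import numpy as np
import pytest

from octacov import phantom as ph
from octacov.volume_io import (
    AcquisitionSeries,
    LayerBoundaries,
    Modality,
    VolumeGrid,
)


@pytest.fixture(scope="session")
def motion_free_phantom():
    """One motion-free default phantom shared across tests (read-only)."""
    spec = ph.PhantomSpec(seed=11)
    series, truth = ph.generate_phantom_series(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def textured_phantom():
    """Larger transverse grid for feature-based registration tests."""
    spec = ph.PhantomSpec(seed=12, shape=(64, 128, 128), n_repeats=2)
    series, truth = ph.generate_phantom_series(spec)
    return spec, series, truth


def make_two_depth_series(n_repeats: int = 10):
    """Hand-built series where two vessels share every A-scan: one at
    z=10 alternating 100/102 across repeats, one at z=20 alternating
    102/100.  The slab MIP always picks 102 — from a different depth
    each repeat — so Protocol B sees a constant while each vessel truly
    fluctuates."""
    nz, nx, ny = 32, 16, 16
    spacing = (6.0, 12.0, 12.0)
    layers = LayerBoundaries(
        np.full((nx, ny), 5), np.full((nx, ny), 8), np.full((nx, ny), 30)
    )
    vessel = np.zeros((nx, ny), dtype=bool)
    vessel[4:12, 4:12] = True
    octas = []
    for k in range(n_repeats):
        v = np.zeros((nz, nx, ny))
        v[10][vessel] = 100.0 if k % 2 == 0 else 102.0
        v[20][vessel] = 102.0 if k % 2 == 0 else 100.0
        octas.append(VolumeGrid(v, spacing, Modality.OCTA))
    octs = [VolumeGrid(np.zeros((nz, nx, ny)), spacing, Modality.OCT)
            for _ in range(n_repeats)]
    series = AcquisitionSeries(octas, octs, session_id="two-depth")
    return series, layers, vessel


@pytest.fixture()
def two_depth_series():
    return make_two_depth_series()
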