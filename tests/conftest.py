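import numpy as np
import pytest

from stocta import (
    LayerSpec,
    MotionSpec,
    PhantomSpec,
    VesselSpec,
    FiberSpec,
    generate_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def tiny_phantom_spec(seed: int = 7, motion: bool = False, **overrides) -> PhantomSpec:
    """A small, fast phantom: one vessel per layer, one fiber, 64x48x3x64."""
    nx = nz = 64
    ny = 48
    defaults = dict(
        nx=nx, ny=ny, nt=3, nz=nz,
        layers=[
            LayerSpec(6, 18, 70.0, label="superficial"),
            LayerSpec(18, 30, 65.0, label="intermediate"),
            LayerSpec(30, 42, 60.0, label="deep"),
        ],
        vessels=[
            VesselSpec([(10.0, 0.0), (16.0, 63.0)], 4.0, 12.0, 130.0),
            VesselSpec([(0.0, 30.0), (63.0, 36.0)], 2.0, 24.0, 120.0),
            VesselSpec([(40.0, 0.0), (44.0, 63.0)], 1.5, 36.0, 110.0),
        ],
        fibers=[FiberSpec([(0.0, 10.0), (63.0, 16.0)], 3.0, 12.0, 110.0)],
        motion=MotionSpec(scan_rate=40 * 3 * nx) if motion else None,
        tissue_jitter=0.3,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Motion-free small phantom shared across tests (volume, masks)."""
    spec = tiny_phantom_spec()
    vol, vmask, fmask, _ = generate_phantom(spec)
    return spec, vol, vmask, fmask
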