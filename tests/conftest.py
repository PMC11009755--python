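import numpy as np
import pytest

from scopeloop import (
    AffineMap,
    BenchModel,
    FrameSpec,
    ScratchParams,
    VirtualBench,
    make_scratch_scene,
)

#: Small frames keep render/scan runtimes desk-scale; same 16:9-ish aspect
#: as the full-size sensor readout.
SMALL_CAMERA = FrameSpec(384, 216, "camera")
SMALL_PROJECTOR = FrameSpec(384, 216, "projector")


@pytest.fixture
def small_camera():
    return SMALL_CAMERA


@pytest.fixture
def identity_bench():
    """Noise-free bench with equal frames and an identity light path."""
    model = BenchModel(
        ground_truth_map=AffineMap.identity("projector", "camera"),
        camera=SMALL_CAMERA,
        projector=SMALL_PROJECTOR,
        background_level=0.0,
    )
    return VirtualBench(model)


@pytest.fixture
def sine_scene():
    """Scratch scene with a sinusoidal wound front (amplitude 20 px)."""
    params = ScratchParams(
        camera=SMALL_CAMERA,
        wound_width_um=200.0,
        sine_amplitude_px=20.0,
        sine_period_px=100.0,
        roughness_px=2.0,
    )
    return make_scratch_scene(params, seed=3)


def frame_grid(frame: FrameSpec, nx: int = 20, ny: int = 12) -> np.ndarray:
    """Regular grid of (x, y) points spanning a frame."""
    xs = np.linspace(0, frame.width - 1, nx)
    ys = np.linspace(0, frame.height - 1, ny)
    X, Y = np.meshgrid(xs, ys)
    return np.column_stack([X.ravel(), Y.ravel()])
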