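import numpy as np
import pytest

from eusquant import CalibratedImage, CalibrationSpec
from eusquant.phantom import Ellipse, LobuleSpec, PhantomSpec, RegionNoise, render_phantom


@pytest.fixture
def unit_calibration() -> CalibrationSpec:
    return CalibrationSpec(1.0)


@pytest.fixture
def study_calibration() -> CalibrationSpec:
    return CalibrationSpec()  # 12.2674 px/mm


@pytest.fixture
def small_image(unit_calibration) -> CalibratedImage:
    """4×4 grid from the region-growing worked example."""
    grid = np.array(
        [[10, 10, 50, 50], [10, 12, 50, 50], [60, 60, 60, 50], [10, 10, 10, 50]],
        dtype=np.uint8,
    )
    return CalibratedImage(gray=grid, calibration=unit_calibration)


@pytest.fixture(scope="session")
def contrast_phantom():
    """A high-contrast phantom (solid−cystic gap 30, per-region σ ≤ 6) whose
    cystic lobule is cleanly recoverable by the tracing tool."""
    spec = PhantomSpec(
        height=480,
        width=640,
        background=RegionNoise(68.3, 11.3),
        lesion=Ellipse((240.0, 320.0), (8.0, 11.0)),
        solid_noise=RegionNoise(40.0, 6.0),
        lobules=(LobuleSpec(Ellipse((240.0, 320.0), (4.0, 5.5)), RegionNoise(10.0, 6.0)),),
        seed=42,
    )
    return render_phantom(spec)
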