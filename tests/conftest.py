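import numpy as np
import pytest

from morphomig import MaskFrame, TrackConfig


@pytest.fixture
def unit_config() -> TrackConfig:
    """1 µm/px, 1 s/frame: pixel and physical coordinates coincide."""
    return TrackConfig(pixel_size_um=1.0, frame_interval_s=1.0)


@pytest.fixture
def calibrated_config() -> TrackConfig:
    """A realistic microscope calibration (0.65 µm/px, 20 s interval)."""
    return TrackConfig(pixel_size_um=0.65, frame_interval_s=20.0)


def frame_from_array(arr, index: int = 1, pixel_size: float = 1.0, dt: float = 1.0):
    """Wrap a raw array as a MaskFrame with simple calibration."""
    return MaskFrame(
        pixels=np.asarray(arr),
        frame_index=index,
        time_s=(index - 1) * dt,
        pixel_size_um=pixel_size,
    )
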