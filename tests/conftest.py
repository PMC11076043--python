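import sys
from pathlib import Path

import pytest

# make tests/_oracles.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))

from smtirf import AcquisitionParams  # noqa: E402


@pytest.fixture
def acq_52ms():
    """Standard acquisition: 52 ms frames, track-table geometry only."""
    return AcquisitionParams(frame_interval_s=0.052, field_area_um2=1000.0, n_frames=2000)


@pytest.fixture
def acq_imaging():
    """Small imaging geometry for rendering/detection tests."""
    return AcquisitionParams(
        frame_interval_s=0.052, pixel_size_um=0.16, image_shape=(64, 64), n_frames=20
    )
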