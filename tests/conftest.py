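import numpy as np
import pytest

import tailbeat as tb


@pytest.fixture(scope="session")
def bg_ctrl_trace():
    """Beat-and-glide control recording with ground truth (30 Hz, snr 5)."""
    spec = tb.SyntheticTraceSpec(mode="bg_ctrl", tailbeat_hz=30.0, snr=5.0,
                                 seed=7)
    return tb.generate_fictive_trace(spec)


@pytest.fixture(scope="session")
def swim_video():
    """Half a second of 30 Hz swimming at 500 fps, with ground truth."""
    frames, midlines, angles, positions = tb.generate_swim_video(
        wave_hz=30.0, n_frames=250, fps=500.0)
    return frames, midlines, angles, positions


@pytest.fixture
def sinusoid_epoch():
    """Clean 200-ms 30 Hz epoch at 10 kHz (unit amplitude, no noise)."""
    rate = 10_000.0
    t = np.arange(int(0.2 * rate)) / rate
    return tb.TimeSeriesTrace(np.sin(2 * np.pi * 30.0 * t), rate)
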