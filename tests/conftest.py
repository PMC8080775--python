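import numpy as np
import pytest

from combmap import Recording, TraceParams
from combmap.synthetic import make_planar_wave_stack, make_transient_template


@pytest.fixture
def tent_template():
    """Piecewise-linear AP: rise 10 frames, fall 10 frames, amplitude 1."""
    return make_transient_template("ap_tent", 10, 10, 1.0)


@pytest.fixture
def raw_params():
    """Trace params with smoothing and drift removal disabled: features on
    noise-free fixtures must then be exact."""
    return TraceParams(smoothing_window=0, drift_poly_degree=-1)


@pytest.fixture
def planar_stack():
    """Noise-free plane wave: 8x8 px, 1 px/frame along rows, BCL 120, 6 beats."""
    return make_planar_wave_stack(
        rows=8, cols=8, speed_px_per_frame=1.0, bcl_frames=120, n_beats=6
    )


@pytest.fixture
def flash_recording():
    """Spatially uniform tent-flash train (no propagation), BCL 120, 6 beats."""
    rec, gt = make_planar_wave_stack(
        rows=6, cols=6, speed_px_per_frame=np.inf, bcl_frames=120, n_beats=6
    )
    assert isinstance(rec, Recording)
    return rec, gt
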