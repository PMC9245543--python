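import numpy as np
import pytest

import vigilnet as v
from vigilnet.core_io import PipelineConfig, StateLabel


#: Compact 16-ROI label set (half posterior, half frontal) for fast tests.
SMALL_LABELS = tuple(
    [f"Occipital_Mid_{k}" for k in range(4)]
    + [f"Parietal_Sup_{k}" for k in range(4)]
    + [f"Frontal_Sup_{k}" for k in range(4)]
    + [f"Temporal_Mid_{k}" for k in range(4)]
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_recording():
    """A deterministic 16-ROI session: 5 EO + 5 A-EC/D-EC pairs."""
    rec, labels = v.standard_session(2, seed=7, roi_labels=SMALL_LABELS)
    return rec, labels


@pytest.fixture
def noise_epoch(rng):
    """One 16-channel epoch of plain white noise at the default rate."""
    rec = v.Recording(
        data=rng.standard_normal((16, 4096)),
        fs=312.5,
        roi_labels=list(SMALL_LABELS),
    )
    return v.segment_epochs(rec)[0]
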