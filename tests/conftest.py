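import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_detector

from catrace import SessionInfo, TraceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trace(values, sampling_rate=5.0, session=None, roi_id="roi000"):
    """Single-ROI TraceMatrix from a 1-D sequence."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return TraceMatrix(
        values=arr,
        sampling_rate=sampling_rate,
        roi_ids=tuple(f"{roi_id[:-1]}{i}" for i in range(arr.shape[0]))
        if arr.shape[0] > 1
        else (roi_id,),
        session=session,
    )


@pytest.fixture
def session_600s():
    return SessionInfo(animal_id="m1", day=1, phase="baseline", duration_s=600.0)
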