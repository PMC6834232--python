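from datetime import datetime

import numpy as np
import pytest

from oxiscreen import SpO2Trace


def make_trace(values, fs=1, valid=None, device="app"):
    """Build a trace from a plain value list for tests."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return SpO2Trace(
        device=device,
        fs=fs,
        start_time=datetime(2000, 1, 1, 23, 0, 0),
        values=values,
        valid_mask=np.asarray(valid, dtype=bool),
    )


def brute_force_dips(values, valid, fs, baseline, min_drop=3.0, min_duration=10.0):
    """Reference dip scan: walk every sample, collect maximal qualifying runs.

    Returns (start_index, stop_index) pairs. Deliberately naive and
    independent of the vectorised implementation.
    """
    runs = []
    i, n = 0, len(values)
    while i < n:
        if valid[i] and values[i] <= baseline - min_drop:
            j = i
            while j < n and valid[j] and values[j] <= baseline - min_drop:
                j += 1
            if (j - i) / fs >= min_duration:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def dip_oracle():
    return brute_force_dips
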