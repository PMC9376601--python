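import numpy as np
import pytest

import tremorscore as ts


@pytest.fixture(scope="session")
def spectral_config():
    return ts.SpectralConfig()


@pytest.fixture(scope="session")
def index_config():
    return ts.IndexConfig()


@pytest.fixture(scope="session")
def et_recording():
    """60-s six-channel recording with a strong 6 Hz tremor."""
    params = ts.SubjectParams(
        group="ET", tremor_freq=6.0, tremor_rel_amp=3.0, seed=42
    )
    return ts.simulate_recording(params, ts.FINGER_SENSOR)


@pytest.fixture(scope="session")
def control_recording():
    """60-s control recording: fractal background + weak 8-12 Hz component."""
    params = ts.SubjectParams(
        group="CTRL", tremor_freq=10.0, tremor_rel_amp=0.2, seed=43
    )
    return ts.simulate_recording(params, ts.FINGER_SENSOR)


@pytest.fixture(scope="session")
def short_et_recording():
    """20-s recording (cheap full-pipeline fixture)."""
    params = ts.SubjectParams(
        group="ET", tremor_freq=6.0, tremor_rel_amp=3.0, seed=44
    )
    return ts.simulate_recording(params, ts.PHONE_SENSOR, duration=20.0)


def brute_force_top_median(values, top_fraction=1.0 / 3.0):
    """Independent oracle: sort, keep ceil(fraction*n) largest, median."""
    import math

    ordered = sorted(values, reverse=True)
    k = math.ceil(top_fraction * len(ordered))
    kept = ordered[:k]
    mid = len(kept) // 2
    if len(kept) % 2:
        return kept[mid]
    return 0.5 * (kept[mid - 1] + kept[mid])


def brute_force_auc(pos, neg):
    """Independent oracle: pair counting with ties worth 1/2."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
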