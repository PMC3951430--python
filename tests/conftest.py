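import numpy as np
import pytest

from stnpipe import synthetic


@pytest.fixture(scope="session")
def small_expression():
    """Small seeded chip experiment with planted truth (shared, read-only)."""
    truth = synthetic.default_expression_truth(
        n_probesets=800, n_hfs_only=8, n_lesion_only=8, n_counter=6, seed=11
    )
    dataset, truth = synthetic.gen_expression_dataset(truth, n_probesets=800)
    return dataset, truth


@pytest.fixture(scope="session")
def bout_track():
    """Zero-jitter locomotion track with 20 scheduled bouts."""
    truth = synthetic.default_track_truth(n_bouts=20, seed=5)
    track, truth = synthetic.gen_locomotion_track(truth)
    return track, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
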