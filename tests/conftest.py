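import numpy as np
import pytest

import ecgseg as es

# small-but-trainable validator settings used across tests; the default
# full-size architecture is exercised by the acceptance suite
SMALL_NET = dict(channels=(8, 8, 16, 16), dense_widths=(64, 32))


@pytest.fixture(scope="session")
def clean_record():
    """20 noise-free beats at 360 Hz with a constant 0.8-s RR."""
    return es.generate_record(n_beats=20, fs=360, mean_rr=0.8, rr_jitter=0.0, seed=7)


@pytest.fixture(scope="session")
def train_records_small():
    """Four lightly noisy records slow enough to yield negative windows."""
    rng = np.random.default_rng(5)
    return [
        es.generate_record(
            12, fs=360, mean_rr=1.2, rr_jitter=0.05,
            noise=[es.NoiseSpec("highfreq", 0.03)],
            seed=int(rng.integers(0, 2**31)),
            record_id=f"rec{i}", subject_id=f"subj{i}")
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def small_segments(train_records_small):
    return es.build_segments(train_records_small, es.AugmentationConfig(),
                             model_len=300, augment=True)


@pytest.fixture(scope="session")
def small_validator(small_segments):
    """A reduced-width validator trained on the small synthetic set."""
    return es.train_validator(small_segments, epochs=6, random_state=0, **SMALL_NET)


@pytest.fixture(scope="session")
def end_to_end_report():
    """The scaled end-to-end experiment: the default-architecture CNN
    trained for 10 epochs on 20 augmented synthetic records, evaluated on
    10 held-out noisy records whose detections carry 10% injected false
    positives.  Shared across the suite because training takes minutes."""
    return es.run_experiment(es.ExperimentConfig(seed=1))
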