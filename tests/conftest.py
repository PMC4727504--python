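import numpy as np
import pytest

from neoseiz.classifier import TrainConfig, label_epochs, train_model
from neoseiz.features import N_FEATURES, extract_feature_matrix
from neoseiz.io import SeizureEvent, SeizureEventList, preprocess
from neoseiz.synthetic import SimConfig, simulate_record


def random_event_list(rng: np.random.Generator, duration: float = 3600.0,
                      max_events: int = 8) -> SeizureEventList:
    """Random valid annotation with millisecond-precision times."""
    n = int(rng.integers(0, max_events + 1))
    events = []
    for _ in range(n):
        onset = round(float(rng.uniform(0, duration - 15)), 3)
        length = float(rng.uniform(10, min(400.0, duration - onset)))
        events.append(SeizureEvent(onset, round(onset + length, 3)))
    return SeizureEventList(events, duration)


@pytest.fixture(scope="session")
def sim_short():
    """One short simulated seizure record (raw 256 Hz) plus ground truth."""
    cfg = SimConfig(duration_s=900.0, sleep_cycle_s=300.0)
    rec, truth = simulate_record(cfg, np.random.default_rng(11))
    return cfg, rec, truth


@pytest.fixture(scope="session")
def trained_pipeline():
    """A small trained detector: 4 training records, 2 held-out records.

    Scaled down for test runtime; the full-scale study conditions are
    exercised in the acceptance suite.
    """
    cfg = SimConfig(duration_s=900.0)
    ss = np.random.SeedSequence(1)
    children = ss.spawn(6)
    X, y, held_out = [], [], []
    for i, child in enumerate(children):
        rec, truth = simulate_record(cfg, np.random.default_rng(child))
        rec32 = preprocess(rec)
        fm = extract_feature_matrix(rec32)
        if i < 4:
            labels = label_epochs(fm.epoch_starts, truth.events)
            e, c, _ = fm.values.shape
            X.append(fm.values.reshape(e * c, N_FEATURES))
            y.append(np.repeat(labels, c))
        else:
            held_out.append((rec32, truth, fm))
    model = train_model(np.vstack(X), np.concatenate(y),
                        TrainConfig(seed=1, max_train_rows=3000))
    return model, held_out
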