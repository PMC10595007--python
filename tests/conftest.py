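import numpy as np
import pytest

import eegaffect as ea


@pytest.fixture(scope="session")
def planted_features():
    """Feature matrix from a small planted-asymmetry dataset (3 subjects)."""
    cfg = ea.SyntheticConfig(n_subjects=3, records_per_subject=64, asymmetry_effect=2.0, seed=1)
    epochs = []
    for rec in ea.simulate_dataset(cfg):
        rec = ea.preprocess_recording(rec)
        epochs.extend(ea.epoch_recording(rec, cfg.window_seconds, 0.0))
    return ea.extract_feature_matrix(epochs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epoch(samples, fs=128.0, label=0, subject="S00", channels=ea.DEFAULT_MONTAGE):
    return ea.Epoch(
        subject_id=subject,
        condition_label=label,
        window_index=0,
        samples=np.asarray(samples, dtype=float),
        sampling_rate=fs,
        channel_names=channels,
    )


@pytest.fixture()
def tone_epoch():
    """14-channel epoch: 10 Hz alpha tone on every channel plus faint noise."""
    fs, n = 128.0, 128
    t = np.arange(n) / fs
    g = np.random.default_rng(0)
    x = np.vstack([np.sin(2 * np.pi * 10 * t) + 0.01 * g.standard_normal(n)
                   for _ in range(14)])
    return make_epoch(x, fs=fs)
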