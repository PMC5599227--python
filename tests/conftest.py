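import numpy as np
import pytest

from nirsbci.core_io import ChannelLayout, HemodynamicRecord, default_layout, segment_trials
from nirsbci.denoise import denoise_record
from nirsbci.features import extract_feature_table
from nirsbci.simulate import SimulationConfig, simulate_session


@pytest.fixture
def small_layout() -> ChannelLayout:
    return default_layout(4)


@pytest.fixture
def toy_record(small_layout) -> HemodynamicRecord:
    rng = np.random.default_rng(42)
    return HemodynamicRecord(
        hbo=rng.standard_normal((120, 4)),
        hbr=rng.standard_normal((120, 4)),
        fs_hz=25.7,
        layout=small_layout,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Full default simulated session (200 trials), denoised and featurized.

    Session-scoped: several acceptance criteria and interpretation tests
    share this dataset.
    """
    cfg = SimulationConfig(seed=1)
    record, onsets, labels = simulate_session(cfg)
    filtered = denoise_record(record)
    trials = segment_trials(filtered, onsets, labels)
    table = extract_feature_table(trials)
    return {
        "config": cfg,
        "record": record,
        "filtered": filtered,
        "onsets": onsets,
        "labels": np.asarray(trials.labels),
        "trials": trials,
        "table": table,
    }


@pytest.fixture(scope="session")
def tiny_session():
    """One-experiment, 8-channel session: smallest record that still supports
    a 10-level decomposition (4 blocks x 257 = 1028 >= 1024 samples)."""
    cfg = SimulationConfig(seed=5, n_channels=8, n_experiments=1, n_sessions=1)
    record, onsets, labels = simulate_session(cfg)
    return cfg, record, onsets, labels
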