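"""Shared fixtures: small synthetic cohorts generated once per session."""

import warnings

import pandas as pd
import pytest

from posuse.pipeline import process_dataset
from posuse.synthetic import SimulationConfig, generate_dataset


def _run(dataset, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return process_dataset(
            dataset["gps"],
            dataset["counts"],
            dataset["cohort"],
            dataset["schools"],
            dataset["timetables"],
            dataset["annotations"],
            dataset["weather"],
            **kw,
        )


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free cohort (50 participants, 2 days): ground-truth oracle."""
    cfg = SimulationConfig(n_participants=50, n_days=2, seed=20).noise_free()
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_dataset):
    return _run(clean_dataset, keep_fused=True)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions: non-wear, short days, GPS dropout, jitter."""
    cfg = SimulationConfig(n_participants=50, n_days=2, seed=21)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_result(noisy_dataset):
    return _run(noisy_dataset, keep_fused=True)


@pytest.fixture
def truth_by_day(clean_dataset):
    return {
        (d["participant_id"], d["date"]): d for d in clean_dataset["truth_days"]
    }


def make_epoch_frame(counts, start="2015-10-05T09:00:00", pid="P1"):
    """15 s count stream helper for the accelerometer tests."""
    ts = pd.date_range(start, periods=len(counts), freq="15s")
    return pd.DataFrame({"participant_id": pid, "timestamp": ts, "counts": counts})
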