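"""Shared fixtures: small synthetic configurations and derived tables.

All evaluation-level fixtures use a 250 Hz sampling rate and a handful of
channels/epochs so the whole suite runs on one CPU in minutes; the generator
itself defaults to the full study dimensions (1000 Hz, 30 channels, 300
epochs per state).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from entrofatigue import CHANNELS_30, SynthConfig, generate_recording
from entrofatigue.entropy import extract_features
from entrofatigue.preprocess import apply_filters, epoch_recording, normalize_features, \
    stack_epochsets

SMOKE_FS = 250.0


@pytest.fixture(scope="session")
def smoke_cfg() -> SynthConfig:
    return SynthConfig(n_subjects=2, channel_names=CHANNELS_30[:3], fs=SMOKE_FS,
                       epochs_per_state=30, regularity_boost=2.0, seed=123)


@pytest.fixture(scope="session")
def smoke_recording(smoke_cfg):
    return generate_recording(smoke_cfg, 0, "normal")


def features_for(cfg: SynthConfig, subject: int, channel: str,
                 features: tuple[str, ...]) -> pd.DataFrame:
    """Filter -> epoch -> extract for both states of one subject/channel."""
    sets = []
    for state in ("normal", "fatigue"):
        rec = apply_filters(generate_recording(cfg, subject, state))
        sets.append(epoch_recording(rec)[channel])
    return extract_features(stack_epochsets(*sets), features)


@pytest.fixture(scope="session")
def smoke_features(smoke_cfg) -> pd.DataFrame:
    """Normalized SE/PE features of subject 0, all smoke channels."""
    tables = [features_for(smoke_cfg, 0, ch, ("SE", "PE"))
              for ch in smoke_cfg.channel_names]
    return normalize_features(pd.concat(tables, ignore_index=True))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def make_results(rows) -> pd.DataFrame:
    """Build a results table from (subject, channel, feature, classifier, acc, auc)."""
    df = pd.DataFrame(rows, columns=["subject", "channel", "feature",
                                     "classifier", "acc", "auc"])
    for col in ("tp", "fp", "tn", "fn"):
        df[col] = 0
    df["sn"] = df["acc"]
    df["sp"] = df["acc"]
    return df
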