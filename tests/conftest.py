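"""Shared fixtures: small synthetic studies and toy feature matrices.

The tiny study (3 subjects, 24 trials each) exercises the full
simulate -> preprocess -> features path cheaply; acceptance-scale
studies live in test_acceptance.py with their own session fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tonguemi import (FeatureMatrix, SimulationConfig, build_feature_matrix,
                      preprocess_study, simulate_study, standard_montage)
from tonguemi.io import FEATURE_META_COLUMNS, feature_columns


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def tiny_config():
    # 3 subjects x (2 trials/command/session x 2 cmds x 2 sessions x 3
    # patterns) = 3 x 24 = 72 trials
    return SimulationConfig(n_subjects=3, trials_per_command_per_session=2,
                            seed=7)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_study_features(tiny_study):
    epochs = preprocess_study(tiny_study)
    return build_feature_matrix(epochs)


def gaussian_feature_matrix(commands, n_subjects=6, trials_per_class=10,
                            separation=0.0, spread=1.0, seed=0,
                            n_channels=14) -> FeatureMatrix:
    """Toy ERD-feature matrix: one Gaussian blob per command.

    Class means are placed along distinct feature axes, ``separation``
    apart; ``separation=0`` gives an exchangeable null.
    """
    rng = np.random.default_rng(seed)
    montage = standard_montage()
    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        for ci, cmd in enumerate(commands):
            mean = np.zeros(n_channels)
            mean[ci % n_channels] = separation
            for t in range(trials_per_class):
                x = rng.normal(mean, spread)
                row = {"subject_id": sid, "session_id": "S1",
                       "pattern_id": "P1", "trial_index": t,
                       "command": cmd}
                row.update(zip(feature_columns(montage), x))
                rows.append(row)
    frame = pd.DataFrame(rows, columns=list(FEATURE_META_COLUMNS)
                         + feature_columns(montage))
    return FeatureMatrix(frame, montage)


@pytest.fixture
def toy_separable_fm():
    return gaussian_feature_matrix(("LL", "LR"), n_subjects=6,
                                   trials_per_class=10, separation=12.0,
                                   spread=0.5, seed=3)


@pytest.fixture
def toy_null_fm():
    return gaussian_feature_matrix(("LL", "LR"), n_subjects=8,
                                   trials_per_class=15, separation=0.0,
                                   seed=4)
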