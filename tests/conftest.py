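"""Shared fixtures.

The heavy session-scoped fixtures simulate complete desk-scale studies
(12 participants, 125 trials in 5 blocks, 8 channels) through the full
measurement chain (EEG synthesis -> spectra -> spectral parameterization ->
two-stage regression); they are shared between the replication tests so
each study is simulated exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from toteeg import SessionConfig
from toteeg.pipeline import make_study_config, scalar_study

N_STUDIES = 20
SPURIOUS_SEEDS = [1000 + k for k in range(N_STUDIES)]
GENUINE_SEEDS = [2000 + k for k in range(N_STUDIES)]


@pytest.fixture(scope="session")
def spurious_studies():
    """Spurious-regime studies analysed in the pre-stimulus window."""
    return [scalar_study(make_study_config("spurious", seed),
                         window=(-1.0, 0.0), outcomes=("alpha_pow", "alpha_cf"))
            for seed in SPURIOUS_SEEDS]


@pytest.fixture(scope="session")
def genuine_studies():
    """Genuine-regime studies analysed in the post-stimulus window."""
    return [scalar_study(make_study_config("genuine", seed),
                         window=(0.0, 1.0), outcomes=("alpha_pow",))
            for seed in GENUINE_SEEDS]


@pytest.fixture
def tiny_config():
    """Small, fast session configuration for unit tests."""
    return SessionConfig.spurious_regime(
        n_participants=2, trials_per_block=10, n_blocks=2, n_channels=4,
        epoch_window=(-1.0, 1.0), seed=42)
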