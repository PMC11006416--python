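"""Shared fixtures: all data is generated programmatically at test time.

The expensive session fixtures (a small training corpus, a fixture-trained
emulator, a small calibrated population) are deliberately scaled down from
the full desk-scale recipe so that the whole suite runs on one CPU within a
CI-style budget; the assertions they feed keep their full-strength
thresholds.
"""

from __future__ import annotations

import numpy as np
import pytest

from apemu.dataset import build_training_set, train_val_split
from apemu.simulator import ConductanceSet, PacingProtocol, simulate_ap


@pytest.fixture(scope="session")
def protocol():
    return PacingProtocol()


@pytest.fixture(scope="session")
def fast_protocol():
    """Reduced-beat protocol for tests that only need an approximate limit cycle."""
    return PacingProtocol(n_beats=40)


@pytest.fixture(scope="session")
def baseline_trace(protocol):
    return simulate_ap(ConductanceSet(), protocol)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small two-range training corpus with a 20% validation split."""
    ds = build_training_set(900, protocol=PacingProtocol(n_beats=200), seed=0)
    return train_val_split(ds, 0.2, seed=0)


@pytest.fixture(scope="session")
def trained(fixture_dataset):
    """Emulator trained at reduced scale on the fixture corpus.

    Small constant batches with a capped time-subset fraction buy many Adam
    steps per CPU-second; see the methods note.  Returns
    (weights, training_log, dataset).
    """
    from apemu.training import TrainingConfig, train

    cfg = TrainingConfig(epochs=480, batch_start=64, batch_end=64,
                         lr=3e-3, lr_decay=0.05,
                         time_frac_start=1.0 / 16.0, time_frac_end=1.0 / 8.0,
                         seed=0, val_every=60)
    weights, logbook = train(fixture_dataset, cfg)
    return weights, logbook, fixture_dataset


@pytest.fixture(scope="session")
def small_population():
    """Six calibrated synthetic cardiomyocytes (population-of-models fixture)."""
    from apemu.pharmacology import build_population

    return build_population(n=6, protocol=PacingProtocol(n_beats=200), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
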