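"""Shared fixtures: small synthetic fractions and fast model/training configs."""

import numpy as np
import pytest

from respredict import (
    SyntheticConfig,
    TCNConfig,
    LSTMConfig,
    TrainOptions,
    WindowSpec,
    simulate_fraction,
)

#: Desk-scale study conditions used by the slower end-to-end tests:
#: 60 s of training + 20 s of test at 25 Hz, a reduced-width TCN and a
#: short Adam budget. Kept in one place so every test runs the same setup.
FAST_DURATION_S = 80.0
FAST_T_S = 1500  # 60 s at 25 Hz

def fast_fraction(seed: int):
    return simulate_fraction(SyntheticConfig(duration_s=FAST_DURATION_S, seed=seed))


def fast_tcn(seed: int, **kw):
    base = dict(n_layers=4, filter_size=5, channels_per_layer=16)
    base.update(kw)
    return TCNConfig(seed=seed, **base)


def fast_lstm(seed: int, **kw):
    base = dict(n_layers=2, hidden_units=32, input_window=15)
    base.update(kw)
    return LSTMConfig(seed=seed, **base)


def fast_train_options(seed: int, **kw):
    # 600 Adam iterations at lr 0.002 brings the reduced-width TCN close to
    # its training-cost plateau on these fractions (the "trained model"
    # condition the end-to-end checks assume)
    base = dict(learning_rate=0.002, max_iterations=600)
    base.update(kw)
    return TrainOptions(seed=seed, **base)


def fast_window(ahead_ms: float = 400.0, t_delay: int = 15) -> WindowSpec:
    return WindowSpec.from_ms(t_delay, ahead_ms, FAST_T_S, 25.0)


@pytest.fixture
def fraction():
    """One deterministic synthetic fraction at the default study conditions."""
    return fast_fraction(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
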