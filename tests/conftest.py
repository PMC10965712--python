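"""Shared fixtures: tiny enumerable problems and recovery experiments."""

from __future__ import annotations

import pytest

from dipsmc.synthetic import recovery_problem, tiny_inverse_problem


def make_tiny_model(seed, snr=3.0, n_true=1, n_max=2, mode="fixed"):
    return tiny_inverse_problem(
        seed, snr=snr, n_true=n_true, n_max=n_max, moment_mode=mode
    )


def make_recovery_problem(seed, **kwargs):
    return recovery_problem(seed, **kwargs)


@pytest.fixture
def tiny_model():
    return make_tiny_model(seed=5)


@pytest.fixture
def tiny_model_hyper():
    return make_tiny_model(seed=5, mode="hyper")
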