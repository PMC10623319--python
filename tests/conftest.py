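"""Shared fixtures: small simulated studies and fitted models.

Everything is generated programmatically at test time; expensive fits are
session-scoped so several test modules can share them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from adsorbkin.datasets import Port, builtin_design
from adsorbkin.estimate import two_stage_fit
from adsorbkin.simulate import default_population, simulate_study


def rich_design(group="G2_CYA", n_intervention=50, n_control=0, step=0.25):
    """A Group-2-like design with dense paired sampling over the session."""
    times = tuple(np.round(np.arange(0.0, 6.0 + 1e-9, step), 6))
    des = builtin_design(group)
    return replace(
        des,
        n_intervention=n_intervention,
        n_control=n_control,
        sampling_times={Port.inlet: times, Port.outlet: times},
    )


@pytest.fixture(scope="session")
def cya_population():
    return default_population("CYA")


@pytest.fixture(scope="session")
def small_cya_dataset(cya_population):
    """5 intervention + 3 control subjects, protocol sampling times."""
    return simulate_study(builtin_design("G2_CYA"), cya_population, seed=202)


@pytest.fixture(scope="session")
def rich_cya_dataset(cya_population):
    """n=50 with 15-min paired sampling — the recovery workhorse."""
    return simulate_study(rich_design(), cya_population, seed=7)


@pytest.fixture(scope="session")
def rich_cya_two_stage(rich_cya_dataset, cya_population):
    """Two-stage fit of the rich dataset, shared across modules."""
    return two_stage_fit(rich_cya_dataset, cya_population)
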