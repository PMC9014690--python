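"""Shared fixtures: the cardiac-surgery reference setting.

All headline computations need only printed parameters: the Phase-I
beta-binomial(71, 0.59, 4.12) patient mix, the logistic risk model
(b0 = -3.6798, b1 = 0.0768), and the chart designs QA = 2 (upper,
h+ = 4.5) and QA = 1/2 (lower, h- = 4).
"""

import numpy as np
import pytest

from racusum import (
    BetaBinomialMix,
    BetaMix,
    DiscretizedBetaMix,
    DEFAULT_RISK_MODEL,
    w_atoms,
)


@pytest.fixture(scope="session")
def model():
    return DEFAULT_RISK_MODEL


@pytest.fixture(scope="session")
def phase1_mix():
    return BetaBinomialMix(71, 0.59, 4.12)


@pytest.fixture(scope="session")
def beta_mix():
    return BetaMix(0.61, 4.09, smax=71)


@pytest.fixture(scope="session")
def discrete_beta_mix():
    return DiscretizedBetaMix(0.61, 4.09, ncat=72)


@pytest.fixture(scope="session")
def phase1_atoms_up(phase1_mix, model):
    return w_atoms(phase1_mix, model, qa=2.0)


@pytest.fixture(scope="session")
def phase1_atoms_down(phase1_mix, model):
    return w_atoms(phase1_mix, model, qa=0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)
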