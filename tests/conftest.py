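"""Shared fixtures: converged reference patterns for every built-in model.

Session-scoped so the (expensive) stiff integrations run once per session.
Parameter sets: the Schnakenberg set is the non-dimensional image of the
dimensional reference set (Du,Dv,c1,c2,c3,c4) = (1,40,0.1,1,1,0.9); the
FitzHugh-Nagumo set is the image of (0.05,0.00028,10,1,1); the Brusselator
and Lengyel-Epstein sets are documented package examples inside the models'
Turing regions.
"""

import warnings

import numpy as np
import pytest

from turinverse.simulate import integrate_to_steady_state

SCHNAK_BETA = np.array([0.1, 1.0, 0.9, 40.0])
FHN_BETA = np.array([1.0, 0.1, 0.1, 0.0056])
BRUSS_BETA = np.array([2.0 ** 2 / 4.4 ** 3, 3.4 / 4.4, 0.1])
LE_BETA = np.array([10.0, 4.0, 0.04])

MODEL_CASES = {
    "schnakenberg_nd": (SCHNAK_BETA, 1.0),
    "fitzhugh_nagumo_nd": (FHN_BETA, 0.25),
    "brusselator_nd": (BRUSS_BETA, 0.6),
    "lengyel_epstein_a": (LE_BETA, 0.2),
}


def _simulate(name):
    beta, dx = MODEL_CASES[name]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return integrate_to_steady_state(name, beta, dx=dx, seed=1)


@pytest.fixture(scope="session")
def schnak_pattern():
    return _simulate("schnakenberg_nd")


@pytest.fixture(scope="session")
def fhn_pattern():
    return _simulate("fitzhugh_nagumo_nd")


@pytest.fixture(scope="session")
def bruss_pattern():
    return _simulate("brusselator_nd")


@pytest.fixture(scope="session")
def le_pattern():
    return _simulate("lengyel_epstein_a")


@pytest.fixture(scope="session")
def pattern_bank(schnak_pattern, fhn_pattern, bruss_pattern, le_pattern):
    return {
        "schnakenberg_nd": schnak_pattern,
        "fitzhugh_nagumo_nd": fhn_pattern,
        "brusselator_nd": bruss_pattern,
        "lengyel_epstein_a": le_pattern,
    }
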