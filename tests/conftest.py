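import logging

import numpy as np
import pytest

import pericausal as pc

# quiet the (expected) reference-window warnings for plain stationary runs
logging.getLogger("pericausal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def svar4_model():
    """The uni-directionally coupled SVAR(4) used by the perturbation
    scenario (stable, unit-variance innovations)."""
    return pc.perturbation_model()


@pytest.fixture(scope="session")
def stationary_ensemble(svar4_model):
    """Medium stationary simulation shared by estimation tests."""
    return pc.simulate_svar(svar4_model, n_trials=600, n_samples=40,
                            burn_in=300, seed=11)


def rand_stable_model(rng, p=2):
    """Random stable bivariate SVAR(p) by rejection on the companion
    spectral radius."""
    while True:
        coeffs = [rng.uniform(-0.6, 0.6, size=p) for _ in range(4)]
        model = pc.SVARModel.stationary(
            *coeffs,
            innov_var_1=rng.uniform(0.5, 2.0),
            innov_var_2=rng.uniform(0.5, 2.0))
        stable, radius = pc.stability_check(model)
        if stable and radius < 0.95:
            return model
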