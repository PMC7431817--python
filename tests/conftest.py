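"""Shared fixtures: reference truth and pre-computed expensive fits."""

import warnings

import pytest

from egfrbind import (
    BindingSimDesign,
    GlobalFitConfig,
    fit_global,
    reference_parameters,
    simulate_binding_experiment,
)
from egfrbind.parameters import REFERENCE_K1


@pytest.fixture(scope="session")
def ref_params():
    """Published parameter estimates, untreated condition (K1 = 104)."""
    return reference_parameters("untreated")


@pytest.fixture(scope="session")
def truth_values():
    """All eleven generating parameter values keyed by fit-parameter name."""
    t = {f"K1:{c}": v for c, v in REFERENCE_K1.items()}
    t.update(
        K2=2.9, K3=1.3, K4=36_900.0, K5=95.0, K6=0.45,
        K7=480.0, K8=0.1, K9=2.96,
    )
    return t


@pytest.fixture(scope="session")
def noiseless_design():
    """Noiseless 12-dataset (3 conditions x 4 gates) synthetic design."""
    return simulate_binding_experiment(BindingSimDesign(cv=0.0, seed=3))


@pytest.fixture(scope="session")
def noisy_design():
    """5%-CV, 3-replicate synthetic design (the study's noise conditions)."""
    return simulate_binding_experiment(BindingSimDesign(cv=0.05, seed=3))


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_design):
    """Cold multi-start global fit of the noiseless design (40 starts)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_global(noiseless_design, GlobalFitConfig(starts=40, seed=1))


@pytest.fixture(scope="session")
def noisy_fit(noisy_design):
    """Cold multi-start global fit of the noisy design."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_global(noisy_design, GlobalFitConfig(starts=12, seed=1))
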