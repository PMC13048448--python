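"""Shared fixtures: models and expensive solves reused across the suite.

Two parameter sets recur throughout: the baseline symmetric set (equal
demography in the sexes, moderate size matching) under which selection at
the joint singular strategy is stabilising, and a sex-asymmetric set (cheap
male growth, low male mortality, strong size matching) under which
selection on male growth turns disruptive.
"""

from __future__ import annotations

import numpy as np
import pytest

from ontosel import SexualNicheParams, build_model, find_singular_strategy
from ontosel.quadratic import hessian

#: baseline: symmetric demography, moderate size matching
BASELINE = SexualNicheParams(c=0.5, alpha=0.2, mu_e_f=0.1, mu_e_m=0.1,
                             beta_f=0.2, beta_m=0.2, kappa=1.0, K=1e4)
#: sex-asymmetric demography with strong size matching (disruptive on males)
ASYMMETRIC = SexualNicheParams(c=0.5, alpha=0.1, mu_e_f=0.1, mu_e_m=0.05,
                               beta_f=0.1, beta_m=0.01, kappa=2.0, K=1e4)


@pytest.fixture(scope="session")
def baseline_params():
    return BASELINE


@pytest.fixture(scope="session")
def asymmetric_params():
    return ASYMMETRIC


@pytest.fixture(scope="session")
def baseline_model():
    return build_model(BASELINE)


@pytest.fixture(scope="session")
def asymmetric_model():
    return build_model(ASYMMETRIC)


@pytest.fixture(scope="session")
def baseline_vstar(baseline_model):
    ss = find_singular_strategy(baseline_model, [0.5, 0.5])
    assert ss.converged
    return ss.v_star


@pytest.fixture(scope="session")
def asymmetric_vstar(asymmetric_model):
    ss = find_singular_strategy(asymmetric_model, [0.6, 0.6])
    assert ss.converged
    return ss.v_star


@pytest.fixture(scope="session")
def baseline_shared_vstar():
    model = build_model(BASELINE, shared_trait=True)
    ss = find_singular_strategy(model, [0.4, 0.4])
    assert ss.converged
    return float(ss.v_star[0])


@pytest.fixture(scope="session")
def asymmetric_shared_vstar():
    model = build_model(ASYMMETRIC, shared_trait=True)
    ss = find_singular_strategy(model, [0.3, 0.3])
    assert ss.converged
    return float(ss.v_star[0])


@pytest.fixture(scope="session")
def baseline_hessian(baseline_model, baseline_vstar):
    return hessian(baseline_model, baseline_vstar)


@pytest.fixture(scope="session")
def asymmetric_hessian(asymmetric_model, asymmetric_vstar):
    return hessian(asymmetric_model, asymmetric_vstar)


@pytest.fixture(scope="session")
def kappa0_singular():
    """Singular search without size matching: male trait pinned at zero."""
    model = build_model(BASELINE.replace(kappa=0.0))
    return find_singular_strategy(model, [0.5, 0.3], n_grid=401)


@pytest.fixture(scope="session")
def baseline_trajectory(baseline_model):
    from ontosel import solve_resident

    return solve_resident(baseline_model, np.array([0.5, 0.4]))
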