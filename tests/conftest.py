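import numpy as np
import pandas as pd
import pytest

from gutshift import simulate


@pytest.fixture(scope="session")
def planted_study():
    """Reference intervention scenario: planted HPLC/LPHC effects, OW hyper-response."""
    return simulate.simulate_study(simulate.demo_study_config(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """Small clean study (no detection-limit censoring) for structural tests."""
    cfg = simulate.StudyConfig(n_dogs=12, n_taxa=20, detection_limit=1e-12, seed=5)
    return simulate.simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def closed_lognormal(rng, d, n, corr_pairs=()):
    """Independent lognormal basis closed to compositions; optional planted basis
    correlations as (i, j, rho) triples."""
    z = rng.normal(size=(d, n))
    for i, j, rho in corr_pairs:
        z[j] = rho * z[i] + np.sqrt(1 - rho**2) * rng.normal(size=n)
    basis = np.exp(z)
    frac = basis / basis.sum(axis=0)
    return pd.DataFrame(frac, index=[f"t{i:02d}" for i in range(d)])
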