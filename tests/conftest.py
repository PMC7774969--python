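import numpy as np
import pytest

import prediasim as ps


@pytest.fixture(scope="session")
def params():
    return ps.default_parameters()


@pytest.fixture(scope="session")
def lifetable():
    return ps.fit_synthetic_lifetable(76.5)


@pytest.fixture(scope="session")
def flat_lifetable():
    """Constant low mortality until a terminal age; handy for controlled
    engine tests."""
    ages = np.arange(0, 111)
    qx = np.full(111, 0.01)
    qx[-1] = 1.0
    return ps.LifeTable(ages=ages, qx=qx)


@pytest.fixture(scope="session")
def base_runs(params, lifetable):
    """Base-case runs at n=10,000 for both horizons, one common seed.

    Session-scoped because several tests read different summaries off
    the same pair of runs.
    """
    seed = 20160630
    p30 = params.copy()
    p30.settings.horizon_mode = "thirty_year"
    run30 = ps.run_base_case(p30, lifetable, seed)
    plife = params.copy()
    plife.settings.horizon_mode = "lifetime"
    runlife = ps.run_base_case(plife, lifetable, seed)
    return {"thirty_year": run30, "lifetime": runlife}


def small_params(params, n=500, horizon="thirty_year"):
    p = params.copy()
    p.settings.cohort_size = n
    p.settings.horizon_mode = horizon
    return p
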