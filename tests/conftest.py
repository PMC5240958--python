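"""Shared fixtures: the 9-item instrument and simulated null cohorts.

Expensive objects (fitted cohorts) are session-scoped so the many tests
that only read them pay the simulation and estimation cost once.
"""

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

import raschpcm as rp
from raschpcm.residuals import standardized_residuals


@pytest.fixture(scope="session")
def fixture_items():
    return rp.make_cmtns_like_items()


def _fitted_cohort(items, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        responses, truth = rp.simulate_responses(config, items)
        params, meta = rp.fit_cml(responses)
        persons = rp.estimate_persons(responses, params)
        resid = standardized_residuals(responses, params, persons)
    return SimpleNamespace(
        responses=responses,
        truth=truth,
        params=params,
        meta=meta,
        persons=persons,
        resid=resid,
        items=items,
    )


@pytest.fixture(scope="session")
def null_cohort_1000(fixture_items):
    """n=1000 well-targeted cohort simulated from the model (no violations)."""
    cfg = rp.SimulationConfig(
        n_persons=1000, ability=("normal", 0.0, 1.0), seed=11
    )
    return _fitted_cohort(fixture_items, cfg)


@pytest.fixture(scope="session")
def mixture_cohort(fixture_items):
    """Cohort-sized (n=277) sample with the mild/moderate/severe mixture."""
    cfg = rp.SimulationConfig(n_persons=277, seed=29)
    return _fitted_cohort(fixture_items, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
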