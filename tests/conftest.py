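"""Shared fixtures.

The expensive session fixtures run the five standard scenarios (100
replicates each) and the three selection schemes once; several acceptance
checks read different statistics off the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from igevar.model_core import EffectSet, SimParams, scenario_params
from igevar.population import Cohort
from igevar.runner import run_scenario
from igevar.selection import SCHEMES, SelectionExperiment, run_selection_replicates

MASTER_SEED = 20180328  # master seed for the whole suite


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture
def small_params():
    """Cheap but non-degenerate configuration: 500 individuals, 250 pairs."""
    def factory(scenario: int = 3, **overrides) -> SimParams:
        base = dict(n_sires=50, n_dams_per_sire=5, n_offspring_per_dam=2, n_groups=250)
        base.update(overrides)
        return scenario_params(scenario, **base)
    return factory


@pytest.fixture
def toy_cohort():
    """Hand-built cohort from explicit weights and pair indices."""
    def factory(weights, pairs, b_values=None, sire_ids=None) -> Cohort:
        w = np.atleast_2d(np.asarray(weights, dtype=float))
        if w.shape[0] == 1:
            w = w.T
        n = w.shape[0]
        pairs = np.asarray(pairs, dtype=np.intp)
        zeros = np.zeros(n)
        return Cohort(
            generation=0,
            ids=np.arange(1, n + 1, dtype=np.int64),
            sire_ids=np.zeros(n, dtype=np.int64) if sire_ids is None
            else np.asarray(sire_ids, dtype=np.int64),
            dam_ids=np.zeros(n, dtype=np.int64),
            sex=np.zeros(n, dtype=int),
            effects=EffectSet(*(zeros.copy() for _ in range(6))),
            weights=w,
            pair_members=pairs,
            b_values=np.zeros(pairs.shape, dtype=float) if b_values is None
            else np.asarray(b_values, dtype=float),
        )
    return factory


@pytest.fixture(scope="session")
def scenario_results():
    """The five standard scenarios at full size, 100 replicates each."""
    return {s: run_scenario(s, n_replicates=100, seed=MASTER_SEED) for s in range(1, 6)}


@pytest.fixture(scope="session")
def selection_trajectories():
    """Mean 10-generation trajectories of the three schemes, 100 replicates."""
    return {
        scheme: run_selection_replicates(
            SelectionExperiment(scheme=scheme), n_replicates=100, seed=MASTER_SEED
        )
        for scheme in SCHEMES
    }
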