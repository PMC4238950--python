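"""Shared fixtures: synthetic study conditions reused across test modules.

Heavy computations (cohort fits, seed searches, null contrasts) are
session-scoped so each runs once.
"""

from __future__ import annotations

import numpy as np
import pytest

import esmnet as em
from esmnet.fitting import SearchConfig
from esmnet.model import ESMParams


@pytest.fixture(scope="session")
def geometric_conn():
    """10-node geometric-random connectome under default study conditions."""
    spec = em.SyntheticSpec(n_regions=10, rng_seed=2)
    return em.make_connectome(spec)


@pytest.fixture(scope="session")
def chain_fixture():
    """8-node chain with a sustained high-equilibrium propagation wave."""
    params = ESMParams(beta0=0.9, delta0=0.05, p_seed_init=0.9, velocity=0.004,
                       horizon_days=18250)
    spec = em.SyntheticSpec(n_regions=8, geometry="chain", rng_seed=11,
                            params=params)
    conn = em.make_connectome(spec)
    traj = em.simulate(conn, params, {0})
    return conn, traj


@pytest.fixture(scope="session")
def recovery_experiment():
    """20-subject parameter-recovery cohort and its trajectory-matching fits."""
    spec = em.SyntheticSpec(n_regions=10, rng_seed=7)
    conn = em.make_connectome(spec)
    patterns, truth = em.make_cohort(conn, spec)
    cfg = SearchConfig(params=spec.params)
    fits = em.fit_cohort(patterns, conn, sorted(spec.seeds), cfg)
    return {"spec": spec, "conn": conn, "patterns": patterns, "truth": truth,
            "fits": fits}


@pytest.fixture(scope="session")
def planted_seed_search():
    """Cohort planted at seed set {0, 6} on 12 nodes, searched both ways."""
    spec = em.SyntheticSpec(n_regions=12, rng_seed=13, cohort_size=6,
                            seeds=frozenset({0, 6}))
    conn = em.make_connectome(spec)
    patterns, _ = em.make_cohort(conn, spec)
    cfg = SearchConfig(grid_size=8, refine=False, params=spec.params)
    exhaustive = em.seed_search(patterns, conn, max_k=2, strategy="exhaustive",
                                cfg=cfg)
    greedy = em.seed_search(patterns, conn, max_k=2, strategy="greedy", cfg=cfg)
    return {"spec": spec, "exhaustive": exhaustive, "greedy": greedy}


@pytest.fixture(scope="session")
def null_contrast_result():
    """True-vs-randomized connectome contrast on a 15-node cohort."""
    spec = em.SyntheticSpec(n_regions=15, rng_seed=31, cohort_size=6)
    conn = em.make_connectome(spec)
    patterns, _ = em.make_cohort(conn, spec)
    cfg = SearchConfig(grid_size=6, refine=False, params=spec.params)
    true_score, null_scores, p = em.null_model_contrast(
        patterns, conn, sorted(spec.seeds), n_random=19, rng_seed=5,
        search_cfg=cfg,
    )
    return {"true": true_score, "nulls": null_scores, "p": p}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
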