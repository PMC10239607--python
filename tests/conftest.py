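"""Shared fixtures: synthetic landscapes, tracks and step sets.

Expensive artefacts (simulated tracks, fitted models) are session-scoped;
everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hmmssf import (
    Formula,
    Track,
    build_design,
    sample_controls,
    simulate_track,
)
from hmmssf.datasets import example_formula, example_landscape, example_model


@pytest.fixture(scope="session")
def land():
    return example_landscape(seed=11)


@pytest.fixture(scope="session")
def true_model():
    return example_model()


@pytest.fixture(scope="session")
def sim_track(true_model, land):
    track, states = simulate_track(
        true_model, land,
        track_length=1201, n_proposals=3000, burn_in=100,
        seed=33, start=(25.0, 25.0),
    )
    return track, states


@pytest.fixture(scope="session")
def step_sets(sim_track, land):
    track, _ = sim_track
    ss = sample_controls([track], n_controls=25, scheme="gamma_radial", seed=5)
    return build_design(ss, land, example_formula())


@pytest.fixture(scope="session")
def fitted(step_sets):
    from hmmssf import fit

    return fit(
        step_sets, 2, transition_covariates=("tod_cos", "tod_sin"),
        n_starts=3, seed=7,
    )


@pytest.fixture()
def straight_track():
    """Deterministic 6-point track heading east then north."""
    times = pd.date_range("2021-03-01", periods=6, freq="30min")
    xy = np.array([[0, 0], [1, 0], [2, 0], [3, 0], [3, 1], [3, 2]], dtype=float)
    return Track("a", times, xy, np.ones(6, dtype=bool))


def random_hmm_instance(rng, n_states, n_steps):
    """Random log-densities and transition matrices for oracle tests."""
    log_dens = rng.normal(0.0, 1.5, size=(n_steps, n_states))
    raw = rng.gamma(1.0, 1.0, size=(n_steps, n_states, n_states)) + 0.05
    gammas = raw / raw.sum(axis=2, keepdims=True)
    return log_dens, gammas


def enumerate_likelihood(log_dens, gammas, delta):
    """Brute-force likelihood: sum over all full state sequences."""
    import itertools

    T, K = log_dens.shape
    p = np.exp(log_dens)
    total = 0.0
    for seq in itertools.product(range(K), repeat=T):
        term = delta[seq[0]] * p[0, seq[0]]
        for t in range(1, T):
            term *= gammas[t, seq[t - 1], seq[t]] * p[t, seq[t]]
        total += term
    return total
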