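"""Shared fixtures.

Light fixtures (miniature worlds, canonical trajectories, hand-weighted
nets) come from ``motivnet.config.make_fixtures``.  The heavy session
fixtures at the bottom train the actual networks once and are shared by the
acceptance tests; they are lazy, so unit-test-only runs never pay for them.
"""

from __future__ import annotations

import numpy as np
import pytest

from motivnet.config import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(np.random.default_rng(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# heavy, shared training runs (acceptance scale)

@pytest.fixture(scope="session")
def transport_setup():
    """A 10-city world with a fully trained agent and its evaluation.

    Trained at the standard 1e5 episodes; shared by the transport and
    hierarchy acceptance tests.
    """
    from motivnet.transport import (
        default_transport_schedule,
        evaluate_transport,
        make_test_sets,
        sample_world,
        train_transport,
    )

    world = sample_world(10, np.random.default_rng(101))
    agent = train_transport(
        world, default_transport_schedule(100_000), np.random.default_rng(102)
    )
    tests = make_test_sets(world, 100, np.random.default_rng(103))
    flat = evaluate_transport(world, agent, tests, np.random.default_rng(104))
    return {"world": world, "agent": agent, "tests": tests, "flat": flat}


@pytest.fixture(scope="session")
def trained_rnn():
    """One value RNN trained at 2e5 batches (motivated)."""
    from motivnet.nets import TrainSchedule
    from motivnet.pavlovian import train_rnn

    params, losses = train_rnn(
        TrainSchedule(1e-2, 1e-4, 200_000, 0.9), np.random.default_rng(201)
    )
    return params, losses


@pytest.fixture(scope="session")
def rnn_population():
    """Five independently seeded RNNs at 6e4 batches, for population-level
    claims that must hold across training seeds."""
    from motivnet.nets import TrainSchedule
    from motivnet.pavlovian import train_rnn

    out = []
    for seed in range(5):
        params, _ = train_rnn(
            TrainSchedule(1e-2, 1e-4, 60_000, 0.9), np.random.default_rng(seed)
        )
        out.append(params)
    return out
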