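"""Shared fixtures: tiny hand-built units and one small simulated unit."""

from __future__ import annotations

import datetime

import numpy as np
import pytest

from tc_hierarchy.networks import WeeklyNetwork, WeekWindow
from tc_hierarchy.simulate import SimulationConfig, simulate_unit

WINDOW0 = WeekWindow(0, datetime.date(2020, 1, 6), datetime.date(2020, 1, 13))


def make_network(weights: np.ndarray, nodes: list[str] | None = None) -> WeeklyNetwork:
    """Wrap a weight matrix into a single-window network."""
    weights = np.asarray(weights, dtype=float)
    if nodes is None:
        nodes = [f"N{i}" for i in range(weights.shape[0])]
    return WeeklyNetwork(WINDOW0, nodes, weights)


def random_network(rng: np.random.Generator, max_nodes: int = 12) -> WeeklyNetwork:
    """Random weighted digraph: general, DAG, or two disconnected halves.

    Weights mix small integers and continuous values; used to exercise
    the centrality routines over the graph shapes weekly correction
    networks actually take.
    """
    n = int(rng.integers(1, max_nodes + 1))
    kind = int(rng.integers(0, 3))
    w = np.zeros((n, n))
    if n > 1:
        p = rng.uniform(0.1, 0.6)
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        if kind == 1:  # DAG
            mask = np.triu(mask, 1)
        if kind == 2 and n >= 4:  # disconnected halves
            h = n // 2
            mask[:h, h:] = False
            mask[h:, :h] = False
        weights = np.where(
            rng.random((n, n)) < 0.5,
            rng.integers(1, 4, (n, n)).astype(float),
            rng.uniform(0.5, 3.0, (n, n)),
        )
        w = mask * weights
    return make_network(w)


#: small unit for fast end-to-end tests (~60 residents, 29 weeks)
SMALL_SIM = SimulationConfig(
    n_beds=30, arrival_rate=0.35, span_days=200, seed=11
)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated unit shared across tests (roster, events, truth)."""
    return simulate_unit(SMALL_SIM)


@pytest.fixture(scope="session")
def small_sim_results(small_sim):
    """Fitted pipeline results on the small simulated unit."""
    from tc_hierarchy.model import TCHierarchy

    roster, events, _ = small_sim
    return TCHierarchy(events, roster).fit()
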