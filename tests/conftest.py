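import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from cohortnet.io import WeeklyNetwork, simplify


def net_from(week, edges, extra_nodes=()):
    return simplify(WeeklyNetwork.from_edges(week, edges, extra_nodes=extra_nodes))


@pytest.fixture
def toy_weeks():
    """Three tiny weeks with known turnover: W1={AB,BC}, W2={AB,CD}, W3={BC,CD,DE}."""
    return [
        net_from(1, [("A", "B"), ("B", "C")]),
        net_from(2, [("A", "B"), ("C", "D")]),
        net_from(3, [("B", "C"), ("C", "D"), ("D", "E")]),
    ]


def bidirected_clique(names):
    return [(a, b) for a in names for b in names if a != b]


@pytest.fixture
def two_cliques_net():
    """Two disconnected bidirected 4-cliques on 8 nodes."""
    edges = bidirected_clique(["a1", "a2", "a3", "a4"]) + bidirected_clique(["b1", "b2", "b3", "b4"])
    return net_from(1, edges)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort reused across tests (40 students, 3 weeks)."""
    from cohortnet.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_students=40, n_weeks=3, seed=7)
    attrs, networks = generate_cohort(cfg)
    return cfg, attrs, networks
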