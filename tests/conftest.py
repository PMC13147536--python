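"""Shared fixtures: hand-built and simulated ARGs.

Everything is generated programmatically; the hand-built ARGs pin down
the sub-edge semantics with enumerable answers, the msprime ones cover
realistic recombining genealogies.
"""

import numpy as np
import pytest

from arglmm import ArgData, SimParams, simulate_arg


@pytest.fixture(scope="session")
def two_haploid_arg():
    """Two haploid samples joined at a root at time t=3, L=100, one tree.

    B = diag(t*L, t*L): the only areas above each sample are the two
    root branches; there is no edge above the root to share.
    """
    return ArgData.from_tables(
        node_times=[0.0, 0.0, 3.0],
        node_sample_flags=[True, True, False],
        edges=[(0.0, 100.0, 2, 0), (0.0, 100.0, 2, 1)],
        sequence_length=100.0,
    )


@pytest.fixture(scope="session")
def nested_haploid_arg():
    """((a,b),c): cherry at t=1, root at t=2, L=50, one tree."""
    return ArgData.from_tables(
        node_times=[0.0, 0.0, 0.0, 1.0, 2.0],
        node_sample_flags=[True, True, True, False, False],
        edges=[
            (0.0, 50.0, 3, 0),
            (0.0, 50.0, 3, 1),
            (0.0, 50.0, 4, 2),
            (0.0, 50.0, 4, 3),
        ],
        sequence_length=50.0,
    )


@pytest.fixture(scope="session")
def two_tree_arg():
    """Two local trees; one edge persists across both but a recombination
    below it swaps which sample subtends it, so that edge must split
    into two sub-edges.

    Nodes: samples a=0, b=1, c=2; internal m=3 (t=1), root r=4 (t=2).
    Tree on [0,60): ((a,b)m, c)r; tree on [60,100): ((a,c)m, b)r.
    The edge m->a and r->m persist; below r->m the membership changes.
    """
    return ArgData.from_tables(
        node_times=[0.0, 0.0, 0.0, 1.0, 2.0],
        node_sample_flags=[True, True, True, False, False],
        edges=[
            (0.0, 100.0, 3, 0),  # m->a persists
            (0.0, 60.0, 3, 1),  # m->b, tree 1
            (60.0, 100.0, 3, 2),  # m->c, tree 2
            (0.0, 100.0, 4, 3),  # r->m persists, membership changes below
            (0.0, 60.0, 4, 2),  # r->c, tree 1
            (60.0, 100.0, 4, 1),  # r->b, tree 2
        ],
        sequence_length=100.0,
    )


@pytest.fixture(scope="session")
def small_diploid_arg():
    """15 diploids, ~50 kb recombining ARG (tens of local trees)."""
    arg = simulate_arg(
        SimParams(n_diploids=15, sequence_length=5e4, seed=11)
    )
    assert arg.ts.num_trees >= 10
    return arg


@pytest.fixture(scope="session")
def medium_diploid_arg():
    """100 diploids, 200 kb: the standard mid-size REML fixture."""
    return simulate_arg(SimParams(n_diploids=100, sequence_length=2e5, seed=7))


def random_args(n_args, max_samples=100, rng_seed=0):
    """A stream of (seed-varied) small recombining ARGs for property suites."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n_args):
        n = int(rng.integers(3, max_samples // 2 + 1))
        length = float(rng.choice([2e4, 5e4, 1e5]))
        out.append(
            simulate_arg(
                SimParams(n_diploids=n, sequence_length=length, seed=1000 + i)
            )
        )
    return out
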