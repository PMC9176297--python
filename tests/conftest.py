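import numpy as np
import pytest

from coalseq import tables as tbl


@pytest.fixture
def single_tree():
    """3-node, 2-edge single tree: samples 0,1 below root 2 at t=1."""
    t = tbl.TableCollection(sequence_length=10.0)
    t.add_node(tbl.NODE_IS_SAMPLE, 0.0, 0)
    t.add_node(tbl.NODE_IS_SAMPLE, 0.0, 0)
    t.add_node(0, 1.0, 0)
    t.add_edge(0, 10, 2, 0)
    t.add_edge(0, 10, 2, 1)
    return t


@pytest.fixture
def two_tree():
    """Two marginal trees sharing one spanning edge.

    Samples 0,1,2; node 3 (t=1) is the parent of 1 everywhere and of 0 on
    [0,5) only; node 4 (t=2) roots everything, picking up 0 directly on
    [5,10).
    """
    t = tbl.TableCollection(sequence_length=10.0)
    for _ in range(3):
        t.add_node(tbl.NODE_IS_SAMPLE, 0.0, 0)
    t.add_node(0, 1.0, 0)
    t.add_node(0, 2.0, 0)
    t.add_edge(0, 5, 3, 0)
    t.add_edge(0, 10, 3, 1)
    t.add_edge(5, 10, 4, 0)
    t.add_edge(0, 10, 4, 3)
    t.add_edge(0, 10, 4, 2)
    return tbl.sort_tables(t)


def brute_force_parent(t, position):
    """Per-position tree reconstruction straight from the edge table."""
    parent = [tbl.NULL] * len(t.nodes)
    for e in t.edges:
        if e.left <= position < e.right:
            parent[e.child] = e.parent
    return parent


@pytest.fixture
def oracle_parent():
    return brute_force_parent


def random_ancestry(seed, n=3, L=100, rho_rate=1e-3, N=50, **kw):
    import coalseq as cq

    return cq.sim_ancestry(
        samples=[(0, n)], ploidy=2, population_size=N, sequence_length=L,
        recombination=rho_rate, seed=seed, **kw,
    )


@pytest.fixture
def make_ancestry():
    return random_ancestry
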