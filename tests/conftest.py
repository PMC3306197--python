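"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's dynamic-programming paths:
tree length is minimized by enumerating every internal-state assignment,
and the star-tree maximum by scanning every integer center.
"""

from __future__ import annotations

import numpy as np
import pytest

from foldphylo.trees import PhyloTree


def brute_force_steps(tree: PhyloTree, char: dict[str, int],
                      n_states: int = 24) -> int:
    """Minimum total |i-j| edge cost over all internal-state assignments,
    by exhaustive enumeration (vectorized over assignments)."""
    internals = [n for n in tree.nodes() if n not in tree.labels]
    leaf_state = {n: char[tree.labels[n]] for n in tree.leaves()}
    if not internals:
        ((u, v),) = tree.edges()
        return abs(leaf_state[u] - leaf_state[v])
    grids = np.meshgrid(*([np.arange(n_states)] * len(internals)),
                        indexing="ij")
    assign = np.stack([g.ravel() for g in grids])
    idx = {n: i for i, n in enumerate(internals)}
    total = np.zeros(assign.shape[1], dtype=np.int64)
    for u, v in tree.edges():
        su = assign[idx[u]] if u in idx else leaf_state[u]
        sv = assign[idx[v]] if v in idx else leaf_state[v]
        total += np.abs(su - sv)
    return int(total.min())


def brute_force_star_max(values, n_states: int = 24) -> int:
    """Star-tree length minimized over every integer center."""
    values = np.asarray(values)
    return min(int(np.abs(values - z).sum()) for z in range(n_states))


def splits_compatible(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    return (a <= b or b <= a or not (a & b)
            or a | b == universe)


@pytest.fixture(scope="session")
def quartet():
    """((A,B),(C,D)) as an unrooted quartet."""
    return PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture(scope="session")
def pectinate4():
    """Rooted pectinate 4-leaf tree (((L4,L3),L2),L1)."""
    return PhyloTree.from_newick("(((L4,L3),L2),L1);", rooted=True)


@pytest.fixture(scope="session")
def default_world():
    from foldphylo.simulate import generate_world
    return generate_world(seed=1)


@pytest.fixture(scope="session")
def small_world():
    """A lighter world for pipeline-level tests."""
    from foldphylo.simulate import WorldParams, generate_world
    return generate_world(WorldParams(n_ff=30, n_per_superkingdom=4), seed=11)
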