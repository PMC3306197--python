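"""Ordered-multistate (Wagner) parsimony on 24-state abundance characters.

Characters are linearly ordered: a change between states i and j costs
|i - j|.  Tree length is computed by linear-cost Sankoff dynamic
programming; the min-plus step for the |i - j| metric reduces to two
cumulative-minimum passes, so each edge costs O(n_characters * 24) numpy
work.  Directed cost vectors (an up pass and a down pass over the tree)
score every stepwise-addition or SPR candidate of a tree in O(n) total
instead of O(n^2) full re-evaluations.

Rooting is outgroup-free (Lundberg): a hypothetical ancestor with every
character at the ancestral extreme (23 for fold-family taxa, 0 for proteome
taxa) is attached in turn to every edge of the most parsimonious unrooted
tree, and the root is placed on the edge minimizing total length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .census import EncodedMatrix, N_STATES
from .trees import PhyloTree, TreeError

__all__ = [
    "SearchParams", "TreeStats", "CharacterDiagnostics",
    "wagner_length", "matrix_length", "char_diagnostics", "tree_stats",
    "is_informative", "exhaustive_search", "heuristic_search",
    "enumerate_topologies", "random_topology", "lundberg_root",
    "bootstrap_support", "attach_support", "majority_consensus",
    "tree_from_clades", "robinson_foulds", "g1_signal",
    "n_unrooted_topologies",
]

_BIG = np.int64(1) << 40
_ARANGE = np.arange(N_STATES, dtype=np.int64)


@dataclass
class SearchParams:
    """Heuristic search and bootstrap settings."""

    replicates: int = 10
    swap: str = "SPR"          # NNI | SPR | TBR
    seed: int = 0
    bootstrap_reps: int = 100


# -- state-cost machinery --------------------------------------------------

def _minplus(c: np.ndarray) -> np.ndarray:
    """d[.., j] = min_i c[.., i] + |i - j| under the linear state order."""
    lo = np.minimum.accumulate(c - _ARANGE, axis=-1) + _ARANGE
    hi = np.flip(np.minimum.accumulate(np.flip(c + _ARANGE, -1), axis=-1), -1) - _ARANGE
    return np.minimum(lo, hi)


def _leaf_cost(state_row: np.ndarray) -> np.ndarray:
    k = state_row.shape[0]
    c = np.full((k, N_STATES), _BIG, dtype=np.int64)
    c[np.arange(k), state_row] = 0
    return c


def _states_dict(e: EncodedMatrix) -> dict[str, np.ndarray]:
    return {t: e.states[i] for i, t in enumerate(e.taxa)}


def _check_leaves(tree: PhyloTree, states: Mapping[str, np.ndarray]) -> None:
    for lab in tree.labels.values():
        if lab not in states:
            raise TreeError(f"leaf {lab!r} has no character states")


def _per_character_lengths(tree: PhyloTree,
                           states: Mapping[str, np.ndarray]) -> np.ndarray:
    """Minimum total |i-j| cost per character over internal assignments."""
    _check_leaves(tree, states)
    nodes = tree.nodes()
    if len(nodes) == 1:
        (only,) = nodes
        k = len(states[tree.labels[only]])
        return np.zeros(k, dtype=np.int64)
    start = next((n for n in nodes if n not in tree.labels), nodes[0])
    cost: dict[int, np.ndarray] = {}
    root_cost = None
    for node, par in tree.postorder(start):
        c = _leaf_cost(states[tree.labels[node]]) if node in tree.labels else None
        for kid in tree.neighbors(node):
            if kid != par:
                term = _minplus(cost.pop(kid))
                c = term if c is None else c + term
        if par is None:
            root_cost = c
        else:
            cost[node] = c
    return root_cost.min(axis=1)


def wagner_length(tree: PhyloTree, char: Mapping[str, int]) -> int:
    """Ordered-parsimony length of one character on a tree.

    Identical for every rooting of the same unrooted topology.
    """
    states = {lab: np.array([s]) for lab, s in char.items()}
    return int(_per_character_lengths(tree, states)[0])


def matrix_length(tree: PhyloTree, e: EncodedMatrix,
                  weights: Optional[np.ndarray] = None) -> int:
    """Total tree length: sum of per-character Wagner lengths (optionally
    weighted, as in bootstrap resampling)."""
    if set(tree.labels.values()) != set(e.taxa):
        raise TreeError("tree leaves do not match matrix taxa")
    lens = _per_character_lengths(tree, _states_dict(e))
    if weights is None:
        return int(lens.sum())
    return int(np.dot(lens, weights))


# -- per-character diagnostics --------------------------------------------

@dataclass
class CharacterDiagnostics:
    s: int               # observed steps on the tree
    m: int               # minimum conceivable steps (state range)
    g: int               # maximum steps (star tree, best integer center)
    ci: float            # m/s, defined as 1.0 when s == 0
    ri: Optional[float]  # (g-s)/(g-m); None (undefined) when g == m


def _char_m(values: np.ndarray) -> int:
    return int(values.max() - values.min())


def _char_g(values: np.ndarray) -> int:
    """Star-tree length: min over integer center z of sum |x - z|; the
    optimum sits at an integer median."""
    med = int(np.median(values))
    return min(int(np.abs(values - z).sum()) for z in (med - 1, med, med + 1))


def char_diagnostics(tree: PhyloTree, char: Mapping[str, int]) -> CharacterDiagnostics:
    labs = [tree.labels[n] for n in tree.leaves()]
    values = np.array([char[lab] for lab in labs])
    s = wagner_length(tree, char)
    m = _char_m(values)
    g = _char_g(values)
    return CharacterDiagnostics(
        s, m, g, m / s if s > 0 else 1.0,
        (g - s) / (g - m) if g > m else None)


@dataclass
class TreeStats:
    """Ensemble homoplasy statistics of a tree against a matrix."""

    length: int
    ci: float
    ri: float
    per_character: list

    def as_dict(self) -> dict:
        return {"length": self.length, "ci": self.ci, "ri": self.ri}


def tree_stats(tree: PhyloTree, e: EncodedMatrix) -> TreeStats:
    """Tree length plus ensemble CI = sum(m)/sum(s) and
    RI = (sum(g)-sum(s))/(sum(g)-sum(m)); the RI sums run over characters
    with g > m (the others carry no retention information)."""
    lens = _per_character_lengths(tree, _states_dict(e))
    per = []
    for j in range(e.n_characters):
        values = e.states[:, j]
        s = int(lens[j])
        m = _char_m(values)
        g = _char_g(values)
        per.append(CharacterDiagnostics(
            s, m, g, m / s if s > 0 else 1.0,
            (g - s) / (g - m) if g > m else None))
    total_s = sum(d.s for d in per)
    total_m = sum(d.m for d in per)
    ci = total_m / total_s if total_s > 0 else 1.0
    varying = [d for d in per if d.g > d.m]
    sg = sum(d.g for d in varying)
    ss = sum(d.s for d in varying)
    sm = sum(d.m for d in varying)
    ri = (sg - ss) / (sg - sm) if sg > sm else 1.0
    return TreeStats(int(lens.sum()), ci, ri, per)


# -- topology enumeration and sampling ------------------------------------

def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labeled leaves."""
    out = 1
    for k in range(4, n + 1):
        out *= 2 * k - 5
    return out


def enumerate_topologies(labels: Sequence[str]) -> Iterator[PhyloTree]:
    """All unrooted binary topologies on the labels, by sequential edge
    insertion in deterministic (sorted-label) order."""
    labels = sorted(labels)
    if len(labels) == 0:
        return
    if len(labels) == 1:
        t = PhyloTree()
        t.new_node(labels[0])
        yield t
        return
    if len(labels) == 2:
        t = PhyloTree()
        t.add_edge(t.new_node(labels[0]), t.new_node(labels[1]))
        yield t
        return

    def grow(tree: PhyloTree, idx: int) -> Iterator[PhyloTree]:
        if idx == len(labels):
            yield tree
            return
        for u, v in tree.edges():
            t2 = tree.copy()
            t2.attach_leaf_on_edge(u, v, labels[idx])
            yield from grow(t2, idx + 1)

    yield from grow(PhyloTree.star(labels[:3]), 3)


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform random unrooted binary topology via sequential addition with
    uniform edge choice."""
    labels = list(labels)
    if len(labels) < 4:
        return next(enumerate_topologies(labels))
    t = PhyloTree.star(labels[:3])
    for lab in labels[3:]:
        edges = t.edges()
        u, v = edges[rng.integers(len(edges))]
        t.attach_leaf_on_edge(u, v, lab)
    return t


# -- informativeness -------------------------------------------------------

def is_informative(char: Mapping[str, int]) -> bool:
    """True iff the character's Wagner length is not constant across
    topologies: exact (topology enumeration) for <= 8 taxa; for larger
    inputs the surrogate rule (informative iff >= 2 distinct states each
    occur >= 2 times, or >= 3 distinct states occur)."""
    labels = sorted(char)
    if len(labels) < 4:
        return False
    if len(labels) <= 8:
        seen: set[int] = set()
        for t in enumerate_topologies(labels):
            seen.add(wagner_length(t, char))
            if len(seen) > 1:
                return True
        return False
    counts: dict[int, int] = {}
    for v in char.values():
        counts[v] = counts.get(v, 0) + 1
    if len(counts) >= 3:
        return True
    return sum(1 for c in counts.values() if c >= 2) >= 2


# -- directed cost vectors (shared by addition, SPR and Lundberg) ----------

def _directed_vectors(tree: PhyloTree, states: Mapping[str, np.ndarray],
                      ) -> dict[tuple[int, int], np.ndarray]:
    """Min-plus-transformed cost vectors for all directed edges.

    M[(u, v)] is the min-plus transform of the cost vector, at u, of the
    component on u's side when edge (u, v) is removed.  Attaching a new
    node on edge (u, v) together with an extra component E (already
    transformed) costs min_s M[(u,v)][., s] + M[(v,u)][., s] + E[., s]
    per character.
    """
    nodes = tree.nodes()
    start = next((n for n in nodes if n not in tree.labels), nodes[0])
    order = tree.postorder(start)
    M: dict[tuple[int, int], np.ndarray] = {}

    def own_cost(node: int) -> Optional[np.ndarray]:
        if node in tree.labels:
            return _leaf_cost(states[tree.labels[node]])
        return None

    for node, par in order:  # up: child -> parent
        if par is None:
            continue
        c = own_cost(node)
        for nb in tree.neighbors(node):
            if nb != par:
                c = M[(nb, node)] if c is None else c + M[(nb, node)]
        M[(node, par)] = _minplus(c)
    for node, par in reversed(order):  # down: parent -> child (preorder)
        kids = [nb for nb in tree.neighbors(node) if nb != par]
        if not kids:
            continue
        base = own_cost(node)
        if par is not None:
            base = M[(par, node)] if base is None else base + M[(par, node)]
        ksum = None
        for kid in kids:
            ksum = M[(kid, node)] if ksum is None else ksum + M[(kid, node)]
        for kid in kids:
            c = ksum - M[(kid, node)] if len(kids) > 1 else None
            if base is not None:
                c = base if c is None else c + base
            M[(node, kid)] = _minplus(c)
    return M


def _attachment_scores(tree: PhyloTree, states: Mapping[str, np.ndarray],
                       extra: np.ndarray, weights: Optional[np.ndarray],
                       ) -> list[tuple[int, tuple[int, int]]]:
    """(length, edge) for attaching a component with transformed cost vector
    ``extra`` on every edge of ``tree``, in deterministic edge order."""
    M = _directed_vectors(tree, states)
    out = []
    for (u, v) in tree.edges():
        tot = M[(u, v)] + M[(v, u)] + extra
        lens = tot.min(axis=1)
        L = int(lens.sum()) if weights is None else int(np.dot(lens, weights))
        out.append((L, (u, v)))
    return out


def _subtree_vector(tree: PhyloTree, root: int, par: int,
                    states: Mapping[str, np.ndarray]) -> np.ndarray:
    """Raw cost vector of the subtree at ``root`` looking away from ``par``."""
    order = []
    stack = [(root, par)]
    while stack:
        node, p = stack.pop()
        order.append((node, p))
        for nb in tree.neighbors(node):
            if nb != p:
                stack.append((nb, node))
    order.reverse()
    cost: dict[int, np.ndarray] = {}
    for node, p in order:
        c = _leaf_cost(states[tree.labels[node]]) if node in tree.labels else None
        for nb in tree.neighbors(node):
            if nb != p:
                term = _minplus(cost.pop(nb))
                c = term if c is None else c + term
        cost[node] = c
    return cost[root]


def _component_nodes(tree: PhyloTree, start: int, banned: int) -> list[int]:
    out, stack = [], [(start, banned)]
    while stack:
        node, par = stack.pop()
        out.append(node)
        for nb in tree.neighbors(node):
            if nb != par:
                stack.append((nb, node))
    return out


def _restricted_tree(tree: PhyloTree, keep: set[int]) -> PhyloTree:
    """Subgraph on ``keep`` (assumed connected), preserving node ids."""
    t = PhyloTree()
    t._adj = {n: [nb for nb in tree._adj[n] if nb in keep] for n in keep}
    t.labels = {n: lab for n, lab in tree.labels.items() if n in keep}
    t._next_id = tree._next_id
    return t


# -- searches --------------------------------------------------------------

def exhaustive_search(e: EncodedMatrix,
                      weights: Optional[np.ndarray] = None) -> list[PhyloTree]:
    """All most parsimonious unrooted topologies, by full enumeration.

    Refuses more than 9 taxa (the count grows as (2n-5)!!).
    """
    n = e.n_taxa
    if n > 9:
        raise TreeError(
            f"exhaustive search over {n} taxa would visit "
            f"{n_unrooted_topologies(n)} topologies; use heuristic_search")
    states = _states_dict(e)
    best_len: Optional[int] = None
    best: list[PhyloTree] = []
    for t in enumerate_topologies(e.taxa):
        lens = _per_character_lengths(t, states)
        L = int(lens.sum()) if weights is None else int(np.dot(lens, weights))
        if best_len is None or L < best_len:
            best_len, best = L, [t]
        elif L == best_len:
            best.append(t)
    return best


def _stepwise_addition(order: Sequence[str], states: Mapping[str, np.ndarray],
                       weights: Optional[np.ndarray]) -> PhyloTree:
    tree = PhyloTree.star(order[:3])
    for lab in order[3:]:
        extra = _minplus(_leaf_cost(states[lab]))
        scores = _attachment_scores(tree, states, extra, weights)
        _, (u, v) = min(scores, key=lambda x: x[0])
        tree.attach_leaf_on_edge(u, v, lab)
    return tree


def _best_spr_move(tree: PhyloTree, states: Mapping[str, np.ndarray],
                   weights: Optional[np.ndarray], current: int,
                   ) -> Optional[tuple[int, tuple]]:
    """Best strictly improving SPR move, or None.

    A move prunes the subtree on the v side of directed edge (u, v) and
    reattaches it on an edge of the remaining tree.
    """
    best: Optional[tuple[int, tuple]] = None
    for u, v in [d for uv in tree.edges() for d in (uv, uv[::-1])]:
        sub = set(_component_nodes(tree, v, u))
        rest_leaves = sum(1 for n in tree.labels if n not in sub)
        if rest_leaves < 3:
            continue
        extra = _minplus(_subtree_vector(tree, v, u, states))
        rest = _restricted_tree(tree, set(tree.nodes()) - sub)
        if rest.degree(u) == 2 and u not in rest.labels:
            rest.suppress_node(u)
        for L, edge in _attachment_scores(rest, states, extra, weights):
            if L < current and (best is None or L < best[0]):
                best = (L, (u, v, edge))
    return best


def _apply_spr(tree: PhyloTree, move: tuple) -> PhyloTree:
    u, v, (x, y) = move
    t = tree.copy()
    t.remove_edge(u, v)
    if t.degree(u) == 2 and u not in t.labels:
        t.suppress_node(u)
    w = t.split_edge(x, y)
    t.add_edge(w, v)
    return t


def _nni_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    for u, v in tree.edges():
        if u in tree.labels or v in tree.labels:
            continue
        a = next(n for n in tree.neighbors(u) if n != v)
        for c in (n for n in tree.neighbors(v) if n != u):
            t = tree.copy()
            t.remove_edge(u, a)
            t.remove_edge(v, c)
            t.add_edge(u, c)
            t.add_edge(v, a)
            yield t


def _tbr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    for u, v in tree.edges():
        if u in tree.labels or v in tree.labels:
            continue
        side_v = set(_component_nodes(tree, v, u))
        side_u = set(tree.nodes()) - side_v
        tu = _restricted_tree(tree, side_u)
        tv = _restricted_tree(tree, side_v)
        for part, anchor in ((tu, u), (tv, v)):
            if part.degree(anchor) == 2 and anchor not in part.labels:
                part.suppress_node(anchor)
        pts_u = tu.edges() or [next(iter(tu.nodes()))]
        pts_v = tv.edges() or [next(iter(tv.nodes()))]
        for eu in pts_u:
            for ev in pts_v:
                yield _reconnect(tu, tv, eu, ev)


def _reconnect(tu: PhyloTree, tv: PhyloTree, eu, ev) -> PhyloTree:
    t = PhyloTree()
    t._adj = {n: list(nbs) for n, nbs in tu._adj.items()}
    t._adj.update({n: list(nbs) for n, nbs in tv._adj.items()})
    t.labels = {**tu.labels, **tv.labels}
    t._next_id = max(t._adj) + 1
    pu = t.split_edge(*eu) if isinstance(eu, tuple) else eu
    pv = t.split_edge(*ev) if isinstance(ev, tuple) else ev
    t.add_edge(pu, pv)
    return t


def _hill_climb(tree: PhyloTree, e: EncodedMatrix,
                states: Mapping[str, np.ndarray],
                weights: Optional[np.ndarray], swap: str,
                ) -> tuple[PhyloTree, int]:
    L = matrix_length(tree, e, weights)
    if swap == "SPR":
        while True:
            move = _best_spr_move(tree, states, weights, L)
            if move is None:
                return tree, L
            L = move[0]
            tree = _apply_spr(tree, move[1])
    gen = {"NNI": _nni_neighbors, "TBR": _tbr_neighbors}[swap]
    improved = True
    while improved:
        improved = False
        for t2 in gen(tree):
            L2 = matrix_length(t2, e, weights)
            if L2 < L:
                tree, L = t2, L2
                improved = True
                break
    return tree, L


def heuristic_search(e: EncodedMatrix, n_replicates: int = 10, seed: int = 0,
                     swap: str = "SPR",
                     weights: Optional[np.ndarray] = None) -> list[PhyloTree]:
    """Random-addition-sequence heuristic search with branch swapping.

    Each replicate builds a tree by stepwise addition in a random taxon
    order (every new leaf placed on the length-minimizing edge) and then
    hill-climbs with the chosen rearrangement until no move improves the
    length.  Returns the distinct best trees found across replicates,
    deterministically for a given seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if e.n_taxa < 4:
        return exhaustive_search(e, weights)
    if swap not in ("NNI", "SPR", "TBR"):
        raise ValueError(f"unknown swap {swap!r}")
    rng = np.random.default_rng(seed)
    states = _states_dict(e)
    taxa = sorted(e.taxa)
    best_len: Optional[int] = None
    best: dict[frozenset, PhyloTree] = {}
    for _ in range(n_replicates):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        tree = _stepwise_addition(order, states, weights)
        tree, L = _hill_climb(tree, e, states, weights, swap)
        if best_len is None or L < best_len:
            best_len = L
            best = {frozenset(tree.bipartitions()): tree}
        elif L == best_len:
            best.setdefault(frozenset(tree.bipartitions()), tree)
    key = lambda s: sorted(sorted(side) for side in s)
    return [best[k] for k in sorted(best, key=key)]


# -- Lundberg rooting ------------------------------------------------------

def lundberg_root(tree: PhyloTree, e: EncodedMatrix) -> PhyloTree:
    """Root an unrooted MP tree with a hypothetical all-ancestral-state
    ancestor attached on the length-minimizing edge.

    The attachment point becomes the root (the hypothetical leaf itself is
    not kept).  Ties are broken by deterministic edge order; the tie count
    is recorded in ``metadata['lundberg_ties']``.
    """
    if tree.rooted:
        raise TreeError("lundberg_root expects an unrooted tree")
    if set(tree.labels.values()) != set(e.taxa):
        raise TreeError("tree does not cover the matrix taxa")
    states = _states_dict(e)
    anc = np.full(e.n_characters, e.ancestral_state, dtype=np.int64)
    extra = _minplus(_leaf_cost(anc))
    scores = _attachment_scores(tree, states, extra, None)
    best_len = min(L for L, _ in scores)
    ties = [edge for L, edge in scores if L == best_len]
    rooted = tree.root_on_edge(*ties[0])
    rooted.metadata["lundberg_length"] = best_len
    rooted.metadata["lundberg_ties"] = len(ties)
    return rooted


# -- bootstrap, consensus, splits -----------------------------------------

def bootstrap_support(e: EncodedMatrix, n_reps: int = 100, seed: int = 0,
                      search: Optional[SearchParams] = None,
                      ) -> dict[frozenset, float]:
    """Character bootstrap: resample columns with replacement, re-search,
    and report for each split the percentage of replicates whose strict
    consensus of best trees contains it (so two complementary splits can
    never both exceed 50%)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if e.n_taxa < 4:
        raise TreeError("bootstrap needs at least 4 taxa")
    search = search or SearchParams(replicates=2)
    rng = np.random.default_rng(seed)
    tallies: dict[frozenset, int] = {}
    k = e.n_characters
    for _ in range(n_reps):
        weights = rng.multinomial(k, np.full(k, 1.0 / k))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        trees = heuristic_search(e, n_replicates=search.replicates,
                                 seed=rep_seed, swap=search.swap,
                                 weights=weights)
        for sp in set.intersection(*(t.bipartitions() for t in trees)):
            tallies[sp] = tallies.get(sp, 0) + 1
    return {sp: 100.0 * c / n_reps for sp, c in tallies.items()}


def attach_support(tree: PhyloTree, support: Mapping[frozenset, float]) -> PhyloTree:
    """Attach split supports to the matching internal nodes of a (possibly
    rooted) tree by bipartition identity."""
    t = tree.copy()
    all_labels = frozenset(t.labels.values())
    anchor = min(all_labels)
    for u, v in t.edges():
        side_v = t._side_labels(u, v)
        if anchor in side_v:
            key, node = all_labels - side_v, u
        else:
            key, node = side_v, v
        if key in support and node not in t.labels:
            t.support[node] = support[key]
    return t


def majority_consensus(trees: Sequence[PhyloTree], cutoff: float = 0.5) -> PhyloTree:
    """Majority-rule consensus: exactly the splits occurring in more than
    ``cutoff`` of the input trees (rooted inputs consense clades, unrooted
    inputs bipartitions).  Node supports carry the split frequencies; the
    result may be multifurcating."""
    if not trees:
        raise TreeError("no trees to consense")
    leafsets = {frozenset(t.labels.values()) for t in trees}
    if len(leafsets) != 1:
        raise TreeError("consensus requires a shared leaf set")
    labels = sorted(leafsets.pop())
    rooted = all(t.rooted for t in trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        groups = set(t.clades().values()) if rooted else t.bipartitions()
        for gr in groups:
            if 1 < len(gr) < len(labels):
                counts[gr] = counts.get(gr, 0) + 1
    n = len(trees)
    kept = {gr: c / n for gr, c in counts.items() if c / n > cutoff}
    return tree_from_clades(labels, kept, rooted=rooted)


def tree_from_clades(labels: Sequence[str],
                     clades: Mapping[frozenset, float],
                     rooted: bool) -> PhyloTree:
    """Build a (possibly multifurcating) tree from pairwise compatible
    label sets; each set's value becomes the node's support * 100."""
    t = PhyloTree()
    universe = frozenset(labels)
    top = t.new_node()
    node_of: dict[frozenset, int] = {universe: top}
    owner: dict[str, int] = {lab: top for lab in labels}
    for cl in sorted(clades, key=lambda c: (-len(c), sorted(c))):
        parent_set = min((s for s in node_of if cl < s), key=len)
        node = t.new_node()
        t.add_edge(node_of[parent_set], node)
        t.support[node] = 100.0 * clades[cl]
        node_of[cl] = node
        for lab in cl:
            owner[lab] = node
    for lab in labels:
        t.add_edge(owner[lab], t.new_node(lab))
    if rooted:
        t.rooted = True
        t.root = top
    return t


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson-Foulds) distance on unrooted splits."""
    if set(t1.labels.values()) != set(t2.labels.values()):
        raise TreeError("trees must share a leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())


# -- phylogenetic signal ---------------------------------------------------

def g1_signal(e: EncodedMatrix, n_random_trees: int = 10000,
              seed: int = 0) -> float:
    """Skewness g1 of the tree-length distribution over uniform random
    topologies; strongly negative values indicate phylogenetic structure.
    NaN when the lengths have zero variance."""
    if e.n_taxa < 4:
        raise TreeError("g1 needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    states = _states_dict(e)
    lengths = np.empty(n_random_trees, dtype=np.int64)
    for i in range(n_random_trees):
        t = random_topology(e.taxa, rng)
        lengths[i] = int(_per_character_lengths(t, states).sum())
    if lengths.std() == 0:
        return float("nan")
    return float(stats.skew(lengths, bias=False))
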