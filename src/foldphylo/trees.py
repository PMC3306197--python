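"""Labeled phylogenetic trees.

A :class:`PhyloTree` is a mutable adjacency-list tree with string labels on
leaves, an optional root (the only node allowed to have degree 2), and
optional per-internal-node support values in [0, 100].  It is the object
shared by the parsimony machinery, the timeline code and the simulator.
Newick text is parsed through dendropy; serialization is done in-place so
support values ride along as internal-node labels.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Optional

import dendropy

__all__ = ["PhyloTree", "TreeError"]


class TreeError(ValueError):
    """Raised for structurally invalid tree operations."""


class PhyloTree:
    def __init__(self) -> None:
        self._adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self.rooted: bool = False
        self.root: Optional[int] = None
        self.support: dict[int, float] = {}
        self.metadata: dict = {}
        self._next_id: int = 0

    # -- construction ------------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self._adj[u].append(v)
        self._adj[v].append(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].remove(v)
        self._adj[v].remove(u)

    def remove_node(self, u: int) -> None:
        if self._adj[u]:
            raise TreeError("cannot remove a connected node")
        del self._adj[u]
        self.labels.pop(u, None)
        self.support.pop(u, None)
        if self.root == u:
            self.root = None

    @classmethod
    def star(cls, labels: Iterable[str]) -> "PhyloTree":
        """Unrooted star tree: one hub connected to every labeled leaf."""
        t = cls()
        hub = t.new_node()
        for lab in labels:
            t.add_edge(hub, t.new_node(lab))
        return t

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], rooted: bool = False,
                   root=None) -> "PhyloTree":
        """Build from (u, v) pairs of hashable node names; string names of
        degree one become leaf labels."""
        t = cls()
        ids: dict = {}
        deg: dict = {}
        pairs = list(edges)
        for u, v in pairs:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        for u, v in pairs:
            for x in (u, v):
                if x not in ids:
                    lab = x if isinstance(x, str) and deg[x] == 1 else None
                    ids[x] = t.new_node(lab)
            t.add_edge(ids[u], ids[v])
        if rooted:
            t.rooted = True
            t.root = ids[root]
        return t

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {u: list(vs) for u, vs in self._adj.items()}
        t.labels = dict(self.labels)
        t.rooted = self.rooted
        t.root = self.root
        t.support = dict(self.support)
        t.metadata = dict(self.metadata)
        t._next_id = self._next_id
        return t

    # -- inspection --------------------------------------------------------

    def nodes(self) -> list[int]:
        return list(self._adj)

    def neighbors(self, u: int) -> list[int]:
        return self._adj[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def leaves(self) -> list[int]:
        return [n for n in self._adj if n in self.labels]

    def leaf_labels(self) -> list[str]:
        return sorted(self.labels.values())

    def node_of(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label:
                return n
        raise TreeError(f"no leaf labeled {label!r}")

    def n_leaves(self) -> int:
        return len(self.labels)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges in deterministic (construction) order."""
        out = []
        for u in self._adj:
            for v in self._adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def postorder(self, start: Optional[int] = None) -> list[tuple[int, Optional[int]]]:
        """(node, parent) pairs with every node after its children."""
        if start is None:
            start = self.root if self.rooted else next(iter(self._adj))
        pre = []
        stack: list[tuple[int, Optional[int]]] = [(start, None)]
        while stack:
            node, par = stack.pop()
            pre.append((node, par))
            for nb in self._adj[node]:
                if nb != par:
                    stack.append((nb, node))
        pre.reverse()
        return pre

    # -- surgery -----------------------------------------------------------

    def split_edge(self, u: int, v: int) -> int:
        """Subdivide edge (u, v) with a new degree-2 node; return it."""
        self.remove_edge(u, v)
        w = self.new_node()
        self.add_edge(u, w)
        self.add_edge(w, v)
        return w

    def attach_leaf_on_edge(self, u: int, v: int, label: str) -> tuple[int, int]:
        w = self.split_edge(u, v)
        leaf = self.new_node(label)
        self.add_edge(w, leaf)
        return leaf, w

    def suppress_node(self, u: int) -> None:
        """Remove a degree-2 unlabeled node, joining its two neighbors."""
        if self.degree(u) != 2 or u in self.labels:
            raise TreeError("can only suppress an unlabeled degree-2 node")
        a, b = self._adj[u]
        self.remove_edge(u, a)
        self.remove_edge(u, b)
        self.remove_node(u)
        self.add_edge(a, b)

    def remove_leaf(self, leaf: int) -> None:
        """Detach a leaf and clean up the degree-2 node it leaves behind."""
        (nb,) = self._adj[leaf]
        self.remove_edge(leaf, nb)
        self.remove_node(leaf)
        if nb in self._adj and self.degree(nb) == 2 and nb not in self.labels \
                and nb != self.root:
            self.suppress_node(nb)

    def root_on_edge(self, u: int, v: int) -> "PhyloTree":
        """Return a rooted copy with a new root subdividing edge (u, v)."""
        t = self.copy()
        r = t.split_edge(u, v)
        t.rooted = True
        t.root = r
        return t

    def unroot(self) -> "PhyloTree":
        t = self.copy()
        if t.rooted and t.root is not None and t.degree(t.root) == 2:
            t.suppress_node(t.root)
        t.rooted = False
        t.root = None
        return t

    # -- splits ------------------------------------------------------------

    def _side_labels(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels in the component of v when edge (u, v) is cut."""
        seen = set()
        stack = [(v, u)]
        labs = []
        while stack:
            node, par = stack.pop()
            seen.add(node)
            if node in self.labels:
                labs.append(self.labels[node])
            for nb in self._adj[node]:
                if nb != par:
                    stack.append((nb, node))
        return frozenset(labs)

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits in unrooted sense, each given as the side that
        does not contain the lexicographically smallest leaf label."""
        all_labels = frozenset(self.labels.values())
        if not all_labels:
            return set()
        anchor = min(all_labels)
        out = set()
        for u, v in self.edges():
            side = self._side_labels(u, v)
            if anchor in side:
                side = all_labels - side
            if 1 < len(side) < len(all_labels) - 1:
                out.add(side)
        return out

    def clades(self) -> dict[int, frozenset[str]]:
        """For a rooted tree: node -> leaf labels below it."""
        if not self.rooted:
            raise TreeError("clades are defined for rooted trees only")
        below: dict[int, frozenset[str]] = {}
        for node, par in self.postorder(self.root):
            if node in self.labels:
                below[node] = frozenset([self.labels[node]])
            else:
                kids = [nb for nb in self._adj[node] if nb != par]
                acc: frozenset[str] = frozenset()
                for k in kids:
                    acc |= below[k]
                below[node] = acc
        return below

    # -- newick ------------------------------------------------------------

    def to_newick(self, with_support: bool = False) -> str:
        if self.rooted:
            start = self.root
        else:
            start = next((n for n in self._adj if n not in self.labels),
                         next(iter(self._adj)))

        def fmt(node: int, par: Optional[int]) -> str:
            kids = [nb for nb in self._adj[node] if nb != par]
            if not kids:
                return self.labels[node]
            inner = ",".join(fmt(k, node) for k in kids)
            tag = ""
            if with_support and node in self.support:
                tag = format(self.support[node], "g")
            return f"({inner}){tag}"

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * len(self._adj) + 100))
        try:
            return fmt(start, None) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
        t = cls()

        def walk(dnode) -> int:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
                return t.new_node(str(name))
            me = t.new_node()
            if dnode.label is not None:
                try:
                    t.support[me] = float(dnode.label)
                except ValueError:
                    pass
            for ch in dnode.child_nodes():
                t.add_edge(me, walk(ch))
            return me

        top = walk(dt.seed_node)
        if rooted:
            t.rooted = True
            t.root = top
        elif t.degree(top) == 2 and top not in t.labels:
            t.suppress_node(top)
        return t

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves()} leaves>"
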