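"""Synthetic fold-family censuses with known ground truth.

The generator emulates the evolutionary process the census analysis
assumes: an organismal tree in which the archaeal clade diverges first and
Bacteria/Eukarya are sister clades; fold families born at uniform times on
a 0-1 scale and immediately shared by every lineage alive; lineage-wise
loss with elevated rates for early-born families on archaeal branches
(reductive evolution) and for late-born families on microbial branches
(emulating eukaryal innovation); and per-proteome abundance that grows by
a preferential-attachment ("rich get richer") duplication process, so that
expected abundance increases with family age.  Growth rates differ between
superkingdoms (A < B < E) and evolve brownianly along the tree, giving
proteome columns both a size signal for rooting and clade-structured
covariance for topology recovery.

Every draw flows from one numpy Generator seeded by the caller, so a world
is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .census import (AbundanceMatrix, CensusTable, FFIdentifier,
                     ProteomeRecord, parse_ccs)
from .functions import MAJOR_CATEGORIES, FunctionMap
from .proteome import basal_group
from .timeline import TimelineEntry
from .trees import PhyloTree
from .parsimony import robinson_foulds

__all__ = ["WorldParams", "SyntheticWorld", "generate_world",
           "world_to_inputs", "evaluate_recovery", "RecoveryMetrics"]

_MINOR_BY_MAJOR = {
    "Metabolism": ["nucleotide m/tr", "redox", "transferases"],
    "General": ["small molecule binding", "protein interaction"],
    "Intra-cellular processes": ["ion m/tr", "proteases"],
    "Information": ["translation", "transcription"],
    "Regulation": ["signal transduction", "DNA binding"],
    "Extra-cellular processes": ["cell adhesion", "immune response"],
    "Other": ["viral proteins"],
}
# majors ordered by when the scheme seeds them along the timeline:
# metabolic and general-purpose domains first, informational next,
# extracellular/other machinery last.
_MAJOR_ERA = ("Metabolism", "General", "Intra-cellular processes",
              "Information", "Regulation", "Extra-cellular processes", "Other")


@dataclass(frozen=True)
class WorldParams:
    """Study conditions of the synthetic protein world.

    Rates are per time slice (duplication) or per branch (loss); the
    timeline spans [0, 1] in ``n_slices`` slices.
    """

    n_ff: int = 60
    n_per_superkingdom: int = 6
    duplication_rate: float = 0.06
    sk_growth: tuple = (("A", 0.6), ("B", 1.0), ("E", 1.4))
    rate_sigma: float = 0.3
    loss_base: float = 0.03
    loss_archaea_early: float = 0.45
    loss_microbial_late: float = 0.35
    early_cutoff: float = 0.25
    late_cutoff: float = 0.66
    noise: float = 0.25
    n_slices: int = 50
    t_split_A: float = 0.10
    t_split_BE: float = 0.30

    def validate(self) -> None:
        if self.n_ff < 10:
            raise ValueError("n_ff must be >= 10")
        if self.n_per_superkingdom < 3:
            raise ValueError("need >= 3 proteomes per superkingdom")
        for r in (self.duplication_rate, self.loss_base, self.noise):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if not 0 < self.t_split_A < self.t_split_BE < 1:
            raise ValueError("superkingdom split times must be ordered in (0,1)")


@dataclass
class SyntheticWorld:
    params: WorldParams
    seed: int
    organismal_tree: PhyloTree          # rooted, leaves A1.., B1.., E1..
    node_times: dict                    # node id -> divergence time
    birth_times: dict                   # ccs string -> birth time in [0, 1]
    presence: pd.DataFrame              # bool, index ccs, columns proteomes
    abundance: AbundanceMatrix          # only FFs surviving somewhere
    leaf_rates: dict                    # proteome -> per-slice duplication rate
    loss_events: list                   # (ccs, superkingdom context, edge id)
    extinct_ffs: list                   # ccs strings lost everywhere
    function_map: FunctionMap

    def birth_rank(self) -> dict:
        """ccs -> rank of birth time (0 = oldest) over surviving FFs."""
        ccs = [str(ff) for ff in self.abundance.row_labels]
        order = sorted(ccs, key=lambda c: self.birth_times[c])
        return {c: i for i, c in enumerate(order)}


def _grow_clade(tree: PhyloTree, root_node: int, t0: float, labels: list,
                times: dict, rng: np.random.Generator) -> None:
    """Forward birth process inside one superkingdom clade: lineages split
    at sorted uniform times; leaves get the given labels."""
    k = len(labels)
    lineages = [root_node]
    if k > 1:
        split_times = np.sort(rng.uniform(t0 + 0.02, 0.95, size=k - 1))
        for st in split_times:
            idx = int(rng.integers(len(lineages)))
            parent = lineages.pop(idx)
            times[parent] = float(st)
            a, b = tree.new_node(), tree.new_node()
            tree.add_edge(parent, a)
            tree.add_edge(parent, b)
            lineages.extend([a, b])
    shuffled = [labels[i] for i in rng.permutation(k)]
    for node, lab in zip(lineages, shuffled):
        tree.labels[node] = lab
        times[node] = 1.0


def _edge_list(tree: PhyloTree, times: dict) -> list:
    """(parent, child, t0, t1) for every edge of the rooted tree."""
    out = []
    for node, par in tree.postorder(tree.root):
        if par is not None:
            out.append((par, node, times[par], times[node]))
    out.sort(key=lambda e: (e[2], e[3], e[1]))
    return out


def _leaf_superkingdom(label: str) -> str:
    return label[0]


def _edge_superkingdom(tree: PhyloTree, parent: int, child: int) -> str:
    """Superkingdom context of an edge: A/B/E when all descendant leaves
    share one, else the joint label (e.g. 'BE' for the stem of B+E)."""
    labs = set()
    stack = [(child, parent)]
    while stack:
        n, par = stack.pop()
        if n in tree.labels:
            labs.add(_leaf_superkingdom(tree.labels[n]))
        for nb in tree.neighbors(n):
            if nb != par:
                stack.append((nb, n))
    return "".join(sorted(labs))


def _make_ccs(i: int) -> FFIdentifier:
    """Deterministic synthetic ccs; consecutive pairs share a superfamily."""
    sf_index = i // 2
    cls = "abcdefg"[sf_index % 7]
    return FFIdentifier(cls, sf_index + 1, 1, i % 2 + 1)


def generate_world(params: Optional[WorldParams] = None,
                   seed: int = 0) -> SyntheticWorld:
    """Simulate a census with known organismal history, birth order, losses
    and duplication history.  Deterministic given (params, seed)."""
    params = params or WorldParams()
    params.validate()
    rng = np.random.default_rng(seed)
    npsk = params.n_per_superkingdom
    labels = {sk: [f"{sk}{i+1:02d}" for i in range(npsk)] for sk in "ABE"}

    # the root is the first dichotomy: the archaeal stem diverges from the
    # ancestor of Bacteria + Eukarya
    tree = PhyloTree()
    times: dict = {}
    root = tree.new_node()
    times[root] = params.t_split_A
    tree.rooted = True
    tree.root = root
    a_root, be = tree.new_node(), tree.new_node()
    tree.add_edge(root, a_root)
    tree.add_edge(root, be)
    times[be] = params.t_split_BE
    b_root, e_root = tree.new_node(), tree.new_node()
    tree.add_edge(be, b_root)
    tree.add_edge(be, e_root)
    _grow_clade(tree, a_root, params.t_split_A, labels["A"], times, rng)
    _grow_clade(tree, b_root, params.t_split_BE, labels["B"], times, rng)
    _grow_clade(tree, e_root, params.t_split_BE, labels["E"], times, rng)

    ffs = [_make_ccs(i) for i in range(params.n_ff)]
    births = {str(ff): float(b)
              for ff, b in zip(ffs, rng.uniform(0, 1, params.n_ff))}

    # fold families are born into the whole communal world: present in every
    # proteome, then carved by lineage-wise loss
    proteomes = sorted(labels["A"] + labels["B"] + labels["E"])
    presence = pd.DataFrame(True, index=[str(ff) for ff in ffs],
                            columns=proteomes)
    edges = _edge_list(tree, times)
    sk_of_edge = {child: _edge_superkingdom(tree, par, child)
                  for par, child, _, _ in edges}
    below: dict[int, list] = {}
    for node, par in tree.postorder(tree.root):
        if node in tree.labels:
            below[node] = [tree.labels[node]]
        else:
            below[node] = [lab for nb in tree.neighbors(node) if nb != par
                           for lab in below[nb]]
    loss_events = []
    for par, child, t0, t1 in edges:
        ctx = sk_of_edge[child]
        for ff in ffs:
            key = str(ff)
            tb = births[key]
            if tb >= t1:
                continue  # family younger than the edge
            p = params.loss_base
            if "A" in ctx and "B" not in ctx and tb < params.early_cutoff:
                p = params.loss_archaea_early
            elif ctx in ("A", "B", "AB") and tb > params.late_cutoff:
                p = params.loss_microbial_late
            if rng.random() < p:
                presence.loc[key, below[child]] = False
                loss_events.append((key, ctx, child))

    # brownian evolution of the per-slice duplication rate along the tree
    sk_growth = dict(params.sk_growth)
    log_rates: dict[int, float] = {root: 0.0}
    for node, par in reversed(tree.postorder(tree.root)):
        if par is None:
            continue
        dt = max(times[node] - times[par], 1e-6)
        log_rates[node] = (log_rates[par]
                           + rng.normal(0.0, params.rate_sigma * np.sqrt(dt)))
    leaf_rates = {}
    for n, lab in tree.labels.items():
        base = params.duplication_rate * sk_growth[_leaf_superkingdom(lab)]
        leaf_rates[lab] = float(min(base * np.exp(log_rates[n]), 0.5))

    # preferential-attachment growth: each extant copy duplicates with the
    # proteome's per-slice rate
    n_ff, n_p = params.n_ff, len(proteomes)
    rates = np.array([leaf_rates[p] for p in proteomes])
    birth_slice = np.array([
        min(int(np.ceil(births[str(ff)] * params.n_slices)), params.n_slices - 1)
        for ff in ffs])
    pres = presence.to_numpy()
    copies = np.zeros((n_ff, n_p), dtype=np.int64)
    for t in range(params.n_slices):
        copies[(birth_slice == t)[:, None] & pres] = 1
        active = copies > 0
        dups = rng.binomial(copies, np.broadcast_to(rates, (n_ff, n_p)))
        copies += np.where(active, dups, 0)
    if params.noise > 0:
        factor = np.exp(rng.normal(0.0, params.noise, size=copies.shape))
        copies = np.round(copies * factor).astype(np.int64)
        copies[pres & (copies < 1)] = 1
    copies[~pres] = 0

    alive = copies.sum(axis=1) > 0
    extinct = [str(ff) for ff, a in zip(ffs, alive) if not a]
    kept_idx = sorted((i for i in range(n_ff) if alive[i]),
                      key=lambda i: ffs[i])
    kept = [ffs[i] for i in kept_idx]
    abundance = AbundanceMatrix(copies[kept_idx], kept, proteomes)

    fmap = _make_function_map(ffs, births)
    return SyntheticWorld(params=params, seed=seed, organismal_tree=tree,
                          node_times=times, birth_times=births,
                          presence=presence, abundance=abundance,
                          leaf_rates=leaf_rates, loss_events=loss_events,
                          extinct_ffs=extinct, function_map=fmap)


def _make_function_map(ffs: list, births: dict) -> FunctionMap:
    """Assign each superfamily a category by the era of its earliest member:
    metabolic/general machinery first, informational later, extracellular
    and 'Other' last — the seeding order the census chronology expects."""
    sf_birth: dict[str, float] = {}
    for ff in ffs:
        sf = ff.superfamily_ccs
        b = births[str(ff)]
        sf_birth[sf] = min(b, sf_birth.get(sf, 1.0))
    order = sorted(sf_birth, key=lambda sf: sf_birth[sf])
    mapping = {}
    n = len(order)
    for i, sf in enumerate(order):
        era = min(int(i / n * len(_MAJOR_ERA)), len(_MAJOR_ERA) - 1)
        major = _MAJOR_ERA[era]
        minors = _MINOR_BY_MAJOR[major]
        mapping[sf] = (major, minors[i % len(minors)])
    return FunctionMap(mapping)


def world_to_inputs(w: SyntheticWorld, n_parasites: int = 0,
                    zeroed_fraction: float = 0.7, seed: int = 0,
                    ) -> tuple[CensusTable, dict]:
    """Emit the census table and proteome metadata for a world.

    All proteomes are free-living; with ``n_parasites`` > 0 the last
    proteomes of each superkingdom (round robin) are converted to obligate
    parasites whose censuses lose ``zeroed_fraction`` of their fold
    families — emulating genome reduction.
    """
    m = w.abundance
    values = m.values.copy()
    lifestyles = {p: "free_living" for p in m.col_labels}
    if n_parasites > 0:
        rng = np.random.default_rng(seed)
        by_sk: dict[str, list] = {"A": [], "B": [], "E": []}
        for p in m.col_labels:
            by_sk[_leaf_superkingdom(p)].append(p)
        chosen = []
        i = 0
        while len(chosen) < min(n_parasites, len(m.col_labels)):
            sk = "ABE"[i % 3]
            pool = [p for p in by_sk[sk] if p not in chosen]
            if pool:
                chosen.append(pool[-1])
            i += 1
        for p in chosen:
            j = m.col_index(p)
            rows = np.flatnonzero(values[:, j] > 0)
            nzero = int(round(zeroed_fraction * len(rows)))
            kill = rng.choice(rows, size=nzero, replace=False)
            values[kill, j] = 0
            lifestyles[p] = "obligate_parasite"
    records = []
    for i, ff in enumerate(m.row_labels):
        for j, p in enumerate(m.col_labels):
            if values[i, j] > 0:
                records.append({"proteome_id": p, "ff": ff,
                                "count": int(values[i, j])})
    census = CensusTable(pd.DataFrame(records,
                                      columns=["proteome_id", "ff", "count"]))
    meta = {p: ProteomeRecord(p, _leaf_superkingdom(p), lifestyles[p])
            for p in m.col_labels}
    return census, meta


@dataclass
class RecoveryMetrics:
    spearman_nd_birth: float
    rf_distance: int
    max_rf: int
    basal_superkingdom: str
    basal_is_archaea: bool


def evaluate_recovery(w: SyntheticWorld, entries: list,
                      pt: PhyloTree) -> RecoveryMetrics:
    """Score the pipeline against the world's ground truth: rank agreement
    of nd with true birth order, Robinson-Foulds distance of the proteome
    tree to the organismal tree, and recovery of the basal superkingdom."""
    truth_rank = w.birth_rank()
    nd, rank = [], []
    for e in entries:
        key = str(e.ff)
        if key not in truth_rank:
            raise ValueError(f"entry {key} not in the world's census")
        nd.append(e.nd)
        rank.append(truth_rank[key])
    rho = float(_stats.spearmanr(nd, rank).statistic)
    org = w.organismal_tree.unroot()
    rf = robinson_foulds(pt.unroot(), org)
    n = len(org.leaf_labels())
    meta = {p: ProteomeRecord(p, _leaf_superkingdom(p), "free_living")
            for p in pt.labels.values()}
    rep = basal_group(pt, meta)
    return RecoveryMetrics(
        spearman_nd_birth=rho,
        rf_distance=rf,
        max_rf=2 * (n - 3),
        basal_superkingdom=rep.superkingdom,
        basal_is_archaea=rep.superkingdom == "A",
    )
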