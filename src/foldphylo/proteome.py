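"""Trees of proteomes, globally and per evolutionary phase.

Proteome trees use the transposed census matrix with reversed polarization:
low genomic abundance (state 0) is the ancestral condition because proteome
repertoires grow by repeated domain accumulation.  Each phase-specific tree
is built from the fold families assigned to that phase by the global
timeline, re-encoded against the subset's own g_max (a ``renormalize``
switch keeps the global codes instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .census import AbundanceMatrix, CensusError, EncodedMatrix, ProteomeRecord, encode_matrix
from .parsimony import (SearchParams, attach_support, bootstrap_support,
                        heuristic_search, lundberg_root, majority_consensus)
from .timeline import TimelineEntry
from .trees import PhyloTree, TreeError

__all__ = ["transpose", "phase_subset", "proteome_tree", "basal_group",
           "BasalReport"]


def transpose(m: AbundanceMatrix) -> AbundanceMatrix:
    """Swap rows and columns (and their kinds); g_max is unchanged and
    double transposition is the identity."""
    return AbundanceMatrix(m.values.T.copy(), list(m.col_labels),
                           list(m.row_labels), row_kind=m.col_kind,
                           col_kind=m.row_kind)


def phase_subset(m: AbundanceMatrix, entries: Sequence[TimelineEntry],
                 phase: str) -> AbundanceMatrix:
    """Restrict rows to the fold families of one phase; columns unchanged."""
    if m.row_kind != "ff":
        raise CensusError("phase_subset expects fold families on rows")
    wanted = {str(e.ff) for e in entries if e.phase == phase}
    if not wanted:
        raise CensusError(f"no fold families in phase {phase!r}")
    idx = [i for i, ff in enumerate(m.row_labels) if str(ff) in wanted]
    missing = wanted - {str(m.row_labels[i]) for i in idx}
    if missing:
        raise CensusError(f"timeline entries missing from matrix: "
                          f"{sorted(missing)[:3]}...")
    return AbundanceMatrix(m.values[idx].copy(),
                           [m.row_labels[i] for i in idx],
                           list(m.col_labels), m.row_kind, m.col_kind)


def proteome_tree(m: AbundanceMatrix,
                  search: Optional[SearchParams] = None,
                  encoded: Optional[EncodedMatrix] = None) -> PhyloTree:
    """Rooted tree of proteomes from the census matrix.

    Encodes with proteomes as taxa (ancestral state 0), runs the heuristic
    search, takes the majority-rule consensus when several equally
    parsimonious trees are found, roots with the all-zero Lundberg
    ancestor, and attaches bootstrap supports.
    """
    search = search or SearchParams()
    e = encoded if encoded is not None else encode_matrix(m, taxa_axis="proteome")
    if e.n_taxa < 4:
        raise TreeError("proteome_tree needs at least 4 proteomes")
    if e.ancestral_state != 0:
        raise TreeError("proteome taxa must be polarized with ancestral state 0")
    trees = heuristic_search(e, n_replicates=search.replicates,
                             seed=search.seed, swap=search.swap)
    tree = trees[0] if len(trees) == 1 else majority_consensus(trees)
    rooted = lundberg_root(tree, e)
    rooted.metadata["n_mp_trees"] = len(trees)
    if search.bootstrap_reps > 0:
        support = bootstrap_support(e, n_reps=search.bootstrap_reps,
                                    seed=search.seed,
                                    search=SearchParams(replicates=1,
                                                        swap=search.swap))
        rooted = attach_support(rooted, support)
    return rooted


@dataclass
class BasalReport:
    superkingdom: str          # composition-majority superkingdom at the base
    basal_taxon: Optional[str]  # leaf adjacent to the root, if any
    composition: dict          # superkingdom counts in the smaller root partition
    monophyly: dict            # superkingdom -> mono|para|polyphyletic
    tie: bool                  # True when both root partitions have equal size


def basal_group(tree: PhyloTree,
                meta: Mapping[str, ProteomeRecord]) -> BasalReport:
    """Identify the basal lineage of a rooted proteome tree.

    The basal group is the root partition with fewer leaves; its
    superkingdom composition names the basal superkingdom.  Monophyly of
    each superkingdom is classified cladistically: monophyletic when some
    clade equals its leaf set; otherwise paraphyletic when a most
    parsimonious reconstruction of the group's presence (absent at the
    root, gains and losses costing one step each) needs only a single
    origin, and polyphyletic when every such reconstruction needs several
    independent origins.
    """
    if not tree.rooted:
        raise TreeError("basal_group requires a rooted tree")
    kids = tree.neighbors(tree.root)
    clades = tree.clades()
    sides = sorted((clades[k] for k in kids), key=lambda s: (len(s), sorted(s)))
    small = sides[0]
    tie = len(sides) > 1 and len(sides[0]) == len(sides[1])
    comp: dict[str, int] = {}
    for lab in small:
        sk = meta[lab].superkingdom
        comp[sk] = comp.get(sk, 0) + 1
    basal_sk = max(sorted(comp), key=lambda sk: comp[sk])
    basal_taxon = None
    for k in kids:
        if k in tree.labels:
            basal_taxon = tree.labels[k]
            break
    mono: dict[str, str] = {}
    clade_sets = set(clades.values())
    by_sk: dict[str, set] = {}
    for lab in tree.labels.values():
        by_sk.setdefault(meta[lab].superkingdom, set()).add(lab)
    for sk, labs in sorted(by_sk.items()):
        fs = frozenset(labs)
        if fs in clade_sets:
            mono[sk] = "monophyletic"
        elif len(labs) == 1:
            mono[sk] = "monophyletic"
        else:
            mono[sk] = _origin_class(tree, clades, fs)
    return BasalReport(basal_sk, basal_taxon, comp, mono, tie)


def _origin_class(tree: PhyloTree, clades: Mapping[int, frozenset],
                  labs: frozenset) -> str:
    """Paraphyletic vs polyphyletic for a non-clade leaf set.

    Single-origin cost = 1 gain at the MRCA plus one loss per maximal clade
    of non-members nested inside the MRCA clade.  When that equals the
    unconstrained parsimony length of the binary presence character (root
    forced absent), a single-origin reconstruction is most parsimonious and
    the group is paraphyletic; when parsimony strictly prefers several
    independent gains, it is polyphyletic.
    """
    from .parsimony import wagner_length

    mrca = min((n for n, c in clades.items() if labs <= c),
               key=lambda n: len(clades[n]))
    # maximal nested clades that avoid the group entirely
    k = 0
    stack = [mrca]
    while stack:
        node = stack.pop()
        kids = [nb for nb in tree.neighbors(node) if clades[nb] < clades[node]]
        for kid in kids:
            if clades[kid] & labs:
                stack.append(kid)
            else:
                k += 1
    single_origin = 1 + k
    probe = tree.copy()
    out = probe.new_node("__outgroup__")
    probe.add_edge(probe.root, out)
    char = {lab: 1 if lab in labs else 0 for lab in tree.labels.values()}
    char["__outgroup__"] = 0
    L = wagner_length(probe, char)
    return "paraphyletic" if single_origin == L else "polyphyletic"
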