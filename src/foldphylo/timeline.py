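"""Timelines of fold-family appearance.

The rooted tree of fold families is highly unbalanced, so the relative age
of a fold family is read off the tree as a node distance nd: the number of
internal nodes between the root and the leaf, normalized by the deepest
leaf.  nd = 0 is the most ancestral taxon, nd = 1 the most recent.  The
distribution index f is the fraction of proteomes (optionally within one
superkingdom) that harbor the fold family.  The nd axis is partitioned into
five evolutionary phases: a primordial protein world, archaeal reductive
evolution, development of the three superkingdoms, organismal
diversification, and eukaryal diversification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .census import AbundanceMatrix, FFIdentifier, ProteomeRecord, SUPERKINGDOMS
from .trees import PhyloTree, TreeError

__all__ = [
    "PhaseDefinition", "PAPER_PHASES", "TimelineEntry",
    "node_distance", "fraction_index", "taxonomic_group", "assign_phases",
    "build_timeline", "timeline_frame", "cumulative_distribution", "use_reuse",
]


@dataclass(frozen=True)
class PhaseDefinition:
    """Contiguous, non-overlapping nd intervals covering [0, 1].

    Interval i is (high_{i-1}, high_i]; the first starts at 0 inclusive.
    """

    names: tuple[str, ...]
    uppers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.uppers) or not self.names:
            raise ValueError("phase names and bounds must align")
        if list(self.uppers) != sorted(self.uppers) or self.uppers[-1] != 1.0:
            raise ValueError("phase bounds must increase and end at 1.0")

    def phase_of(self, nd: float) -> str:
        if not 0.0 <= nd <= 1.0:
            raise ValueError(f"nd {nd} outside [0, 1]")
        for name, hi in zip(self.names, self.uppers):
            if nd <= hi:
                return name
        return self.names[-1]


#: The five phases of the protein world with their printed nd boundaries.
PAPER_PHASES = PhaseDefinition(
    names=("I", "II", "III", "IV", "V"),
    uppers=(0.150, 0.256, 0.550, 0.661, 1.0),
)


@dataclass(frozen=True)
class TimelineEntry:
    """Per-fold-family timeline record."""

    ff: FFIdentifier
    nd: float
    f_global: float
    f_A: float
    f_B: float
    f_E: float
    group: str     # Venn cell of superkingdom presence: A,B,E,AB,AE,BE,ABE
    phase: str
    major_category: Optional[str] = None
    minor_category: Optional[str] = None


def node_distance(tree: PhyloTree) -> dict[str, float]:
    """Relative age of every leaf: internal nodes strictly between root and
    leaf (both excluded), normalized by the deepest leaf.

    On polytomies every internal node on the path counts once.
    """
    if not tree.rooted:
        raise TreeError("node_distance requires a rooted tree")
    if tree.n_leaves() < 2:
        raise TreeError("node_distance needs at least 2 leaves")
    depth: dict[str, int] = {}
    stack = [(tree.root, None, 0)]  # (node, parent, edges from root)
    while stack:
        node, par, d = stack.pop()
        if node in tree.labels:
            depth[tree.labels[node]] = d - 1  # internal nodes between
        for nb in tree.neighbors(node):
            if nb != par:
                stack.append((nb, node, d + 1))
    dmax = max(depth.values())
    if dmax == 0:
        raise TreeError("degenerate tree: every leaf is adjacent to the root")
    return {lab: d / dmax for lab, d in depth.items()}


def fraction_index(m: AbundanceMatrix, ff,
                   proteome_subset: Optional[Iterable] = None) -> float:
    """Fraction of proteomes in the subset with a nonzero count of ff."""
    i = m.row_index(ff)
    if proteome_subset is None:
        cols = np.arange(len(m.col_labels))
    else:
        subset = list(proteome_subset)
        if not subset:
            raise ValueError("empty proteome subset")
        cols = np.array([m.col_index(p) for p in subset])
    return float((m.values[i, cols] > 0).mean())


def taxonomic_group(m: AbundanceMatrix,
                    meta: Mapping[str, ProteomeRecord], ff) -> str:
    """Venn cell of superkingdom presence, concatenated in A, B, E order."""
    i = m.row_index(ff)
    present = set()
    for j, p in enumerate(m.col_labels):
        if m.values[i, j] > 0:
            present.add(meta[p].superkingdom)
    group = "".join(sk for sk in SUPERKINGDOMS if sk in present)
    if not group:
        raise ValueError(f"fold family {ff} absent from every proteome "
                         "(should have been filtered)")
    return group


def assign_phases(nd_map: Mapping[str, float],
                  phases: PhaseDefinition = PAPER_PHASES) -> dict[str, str]:
    return {leaf: phases.phase_of(nd) for leaf, nd in nd_map.items()}


def build_timeline(m: AbundanceMatrix, meta: Mapping[str, ProteomeRecord],
                   rooted_tree: PhyloTree,
                   phases: PhaseDefinition = PAPER_PHASES,
                   ) -> list[TimelineEntry]:
    """Assemble per-fold-family timeline entries from the rooted FF tree and
    the abundance matrix it was built from."""
    nd = node_distance(rooted_tree)
    by_sk: dict[str, list] = {sk: [] for sk in SUPERKINGDOMS}
    for p in m.col_labels:
        by_sk[meta[p].superkingdom].append(p)
    entries = []
    for ff in m.row_labels:
        key = str(ff)
        if key not in nd:
            raise ValueError(f"fold family {key} missing from the tree")
        fs = {}
        for sk in SUPERKINGDOMS:
            fs[sk] = (fraction_index(m, ff, by_sk[sk])
                      if by_sk[sk] else float("nan"))
        entries.append(TimelineEntry(
            ff=ff,
            nd=nd[key],
            f_global=fraction_index(m, ff),
            f_A=fs["A"], f_B=fs["B"], f_E=fs["E"],
            group=taxonomic_group(m, meta, ff),
            phase=phases.phase_of(nd[key]),
        ))
    return entries


def timeline_frame(entries: Sequence[TimelineEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "ff": str(e.ff), "nd": e.nd, "f_global": e.f_global,
        "f_A": e.f_A, "f_B": e.f_B, "f_E": e.f_E,
        "group": e.group, "phase": e.phase,
        "major_category": e.major_category, "minor_category": e.minor_category,
    } for e in entries])


def cumulative_distribution(entries: Sequence[TimelineEntry],
                            by: Optional[str] = None) -> pd.DataFrame:
    """Cumulative count of fold families along nd, overall or per group.

    Returns a tidy frame (group, nd, cumulative); within each group the
    cumulative column is a nondecreasing step function ending at the group
    size.
    """
    if not entries:
        raise ValueError("no timeline entries")
    df = timeline_frame(entries)
    if by is None:
        df["_g"] = "all"
    elif by in df.columns:
        df["_g"] = df[by]
    else:
        raise ValueError(f"unknown grouping key {by!r}")
    out = []
    for g, sub in df.groupby("_g", sort=True):
        nds = np.sort(sub["nd"].to_numpy())
        for i, x in enumerate(nds, start=1):
            out.append({"group": g, "nd": float(x), "cumulative": i})
    return pd.DataFrame(out)


def use_reuse(m: AbundanceMatrix,
              meta: Mapping[str, ProteomeRecord]) -> pd.DataFrame:
    """FF use (distinct families) vs reuse (total abundance) per proteome."""
    rows = []
    for j, p in enumerate(m.col_labels):
        col = m.values[:, j]
        rows.append({
            "proteome_id": p,
            "n_distinct_ffs": int((col > 0).sum()),
            "total_abundance": int(col.sum()),
            "superkingdom": meta[p].superkingdom,
        })
    return pd.DataFrame(rows)
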