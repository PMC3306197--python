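"""Coarse-grained molecular-function annotation of fold families.

Each fold family inherits the functional category of its parent fold
superfamily: a user-supplied map from superfamily ccs prefixes to one of 7
major and 49 minor categories.  Fold families whose superfamily is not in
the map are flagged unannotated, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .timeline import TimelineEntry

__all__ = ["MAJOR_CATEGORIES", "FunctionMap", "load_function_map",
           "annotate", "first_appearance", "FunctionMapError"]

#: The seven major categories of the coarse-grained scheme.
MAJOR_CATEGORIES = (
    "General", "Information", "Metabolism", "Intra-cellular processes",
    "Extra-cellular processes", "Regulation", "Other",
)


class FunctionMapError(ValueError):
    pass


@dataclass
class FunctionMap:
    """superfamily ccs -> (major category, minor category); every minor
    category belongs to exactly one major category."""

    mapping: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        minor_to_major: dict[str, str] = {}
        for sf, (major, minor) in self.mapping.items():
            if major not in MAJOR_CATEGORIES:
                raise FunctionMapError(
                    f"unknown major category {major!r} for {sf}")
            if minor_to_major.setdefault(minor, major) != major:
                raise FunctionMapError(
                    f"minor category {minor!r} mapped to two major categories")

    def lookup(self, sf_ccs: str) -> Optional[tuple[str, str]]:
        return self.mapping.get(sf_ccs)


def load_function_map(path: Union[str, Path]) -> FunctionMap:
    """Read a function-map TSV with columns sf_ccs, major_category,
    minor_category."""
    mapping: dict[str, tuple[str, str]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FunctionMapError(f"{path}: empty function map")
    header = lines[0].rstrip("\n").split("\t")
    need = ["sf_ccs", "major_category", "minor_category"]
    if header[:3] != need:
        raise FunctionMapError(f"{path}: header must be {need}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FunctionMapError(
                f"{path}:{lineno}: expected 3 tab-separated fields")
        sf, major, minor = (p.strip() for p in parts)
        if sf in mapping:
            raise FunctionMapError(f"{path}:{lineno}: duplicate entry for {sf}")
        mapping[sf] = (major, minor)
    return FunctionMap(mapping)


def annotate(entries: Sequence[TimelineEntry],
             fmap: FunctionMap) -> list[TimelineEntry]:
    """Return new entries carrying (major, minor) categories inherited from
    the parent superfamily; unmapped entries keep None.  Never alters nd,
    f, group or phase."""
    out = []
    for e in entries:
        hit = fmap.lookup(e.ff.superfamily_ccs)
        if hit is None:
            out.append(e)
        else:
            out.append(replace(e, major_category=hit[0], minor_category=hit[1]))
    return out


def first_appearance(entries: Sequence[TimelineEntry],
                     level: str = "major") -> pd.Series:
    """Minimum nd per functional category (categories absent from the data
    are omitted); index sorted by first appearance then name."""
    if level not in ("major", "minor"):
        raise ValueError("level must be 'major' or 'minor'")
    attr = f"{level}_category"
    firsts: dict[str, float] = {}
    annotated = 0
    for e in entries:
        cat = getattr(e, attr)
        if cat is None:
            continue
        annotated += 1
        if cat not in firsts or e.nd < firsts[cat]:
            firsts[cat] = e.nd
    if annotated == 0:
        raise ValueError("no annotated entries")
    s = pd.Series(firsts, name="first_nd")
    return s.sort_values(kind="stable")
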