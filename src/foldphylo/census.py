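"""Census input, filtering, and construction of the encoded character matrix.

The raw data is a genomic census: how many times each SCOP fold family (FF)
is assigned to each proteome.  Abundances g are normalized to 24 ordered
character states with

    g_norm = Round[ ln(g + 1) / ln(g_max + 1) * 23 ]

where g_max is the maximum abundance of the whole matrix under analysis and
Round is round-half-up.  States are written with the alphanumeric symbols
'0'-'9' then 'A'-'N' so matrices interoperate with classic parsimony
programs.  High abundance (state 23, symbol 'N') is the ancestral state when
fold families are the taxa; low abundance (state 0) is ancestral when
proteomes are the taxa.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FFIdentifier", "CensusTable", "ProteomeRecord", "AbundanceMatrix",
    "EncodedMatrix", "SYMBOLS", "N_STATES", "LIFESTYLES",
    "parse_ccs", "load_census", "load_metadata", "build_abundance_matrix",
    "encode_abundance", "encode_matrix", "export_nexus", "read_nexus",
    "CensusError",
]

SYMBOLS = "0123456789ABCDEFGHIJKLMN"
N_STATES = 24
LIFESTYLES = ("free_living", "facultative_parasite", "obligate_parasite")
SUPERKINGDOMS = ("A", "B", "E")

_CCS_RE = re.compile(r"^([a-z])\.(\d+)\.(\d+)\.(\d+)$")


class CensusError(ValueError):
    """Malformed or inconsistent census input."""


@dataclass(frozen=True, order=True)
class FFIdentifier:
    """SCOP concise classification string, e.g. c.67.1.4 (class c, fold 67,
    superfamily 1, family 4)."""

    class_letter: str
    fold: int
    superfamily: int
    family: int

    def __str__(self) -> str:
        return f"{self.class_letter}.{self.fold}.{self.superfamily}.{self.family}"

    @property
    def superfamily_ccs(self) -> str:
        """ccs prefix of the parent fold superfamily (drop the family field)."""
        return f"{self.class_letter}.{self.fold}.{self.superfamily}"


def parse_ccs(text: str) -> FFIdentifier:
    """Parse a concise classification string like ``c.67.1.4``."""
    m = _CCS_RE.match(text.strip())
    if not m:
        raise CensusError(f"malformed ccs string: {text!r}")
    cls, fold, sf, fam = m.groups()
    for name, val in (("fold", fold), ("superfamily", sf), ("family", fam)):
        if int(val) <= 0:
            raise CensusError(f"malformed ccs string {text!r}: {name} must be positive")
    return FFIdentifier(cls, int(fold), int(sf), int(fam))


@dataclass
class CensusTable:
    """Aggregated (proteome, FF) -> count records; pairs are unique."""

    counts: pd.DataFrame  # columns: proteome_id (str), ff (FFIdentifier), count (int)

    def __post_init__(self) -> None:
        dup = self.counts.duplicated(subset=["proteome_id", "ff"])
        if dup.any():
            raise CensusError("duplicate (proteome, ff) pairs after aggregation")
        if (self.counts["count"] < 0).any():
            raise CensusError("negative counts in census")

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def proteomes(self) -> list[str]:
        return sorted(self.counts["proteome_id"].unique())

    def ffs(self) -> list[FFIdentifier]:
        return sorted(set(self.counts["ff"]))


@dataclass(frozen=True)
class ProteomeRecord:
    proteome_id: str
    superkingdom: str  # A | B | E
    lifestyle: str     # free_living | facultative_parasite | obligate_parasite

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise CensusError(f"unknown superkingdom {self.superkingdom!r}")
        if self.lifestyle not in LIFESTYLES:
            raise CensusError(f"unknown lifestyle {self.lifestyle!r}")


def load_census(path: Union[str, Path],
                e_value_cutoff: float = 1e-4) -> CensusTable:
    """Read a census TSV, auto-detecting count-level vs hit-level input.

    Count-level files have columns ``proteome_id, ff, count`` (duplicates are
    summed).  Hit-level files have one row per HMM hit with columns
    ``proteome_id, ff, e_value``; hits with e_value <= cutoff are counted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"proteome_id": str})
    cols = set(df.columns)
    if not {"proteome_id", "ff"} <= cols:
        raise CensusError(
            f"census file {path} must have 'proteome_id' and 'ff' columns; "
            f"found {sorted(cols)}")
    df["ff"] = df["ff"].map(parse_ccs)
    if "count" in cols:
        if df["count"].isna().any() or (df["count"] < 0).any():
            raise CensusError("census counts must be nonnegative integers")
        agg = (df.groupby(["proteome_id", "ff"], sort=True)["count"]
                 .sum().astype(int).reset_index())
    elif "e_value" in cols:
        if (df["e_value"] <= 0).any():
            raise CensusError("e_values must be positive")
        kept = df[df["e_value"] <= e_value_cutoff]
        agg = (kept.groupby(["proteome_id", "ff"], sort=True)
                   .size().rename("count").reset_index())
    else:
        raise CensusError(
            f"census file {path} needs either a 'count' or an 'e_value' column")
    return CensusTable(agg)


def load_metadata(path: Union[str, Path]) -> dict[str, ProteomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"proteome_id", "superkingdom", "lifestyle"}
    if not need <= set(df.columns):
        raise CensusError(f"metadata file {path} must have columns {sorted(need)}")
    out: dict[str, ProteomeRecord] = {}
    for row in df.itertuples(index=False):
        if row.proteome_id in out:
            raise CensusError(f"duplicate metadata for proteome {row.proteome_id}")
        out[row.proteome_id] = ProteomeRecord(row.proteome_id, row.superkingdom,
                                              row.lifestyle)
    return out


@dataclass
class AbundanceMatrix:
    """Nonnegative integer abundance matrix, rows x columns with labels.

    By convention rows are fold families and columns are proteomes; after
    :func:`foldphylo.proteome.transpose` the kinds swap, tracked by
    ``row_kind``/``col_kind``.
    """

    values: np.ndarray
    row_labels: list
    col_labels: list
    row_kind: str = "ff"
    col_kind: str = "proteome"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise CensusError("abundance matrix must be two-dimensional")
        if (self.values < 0).any():
            raise CensusError("abundances must be nonnegative")
        if len(self.row_labels) != self.values.shape[0] \
                or len(self.col_labels) != self.values.shape[1]:
            raise CensusError("label lengths do not match matrix shape")
        if len(set(map(str, self.row_labels))) != len(self.row_labels) \
                or len(set(map(str, self.col_labels))) != len(self.col_labels):
            raise CensusError("duplicate row or column labels")

    @property
    def g_max(self) -> int:
        """Global maximum abundance of the matrix (recomputed on demand, so
        it always reflects the matrix actually analyzed)."""
        return int(self.values.max()) if self.values.size else 0

    def row_index(self, label) -> int:
        try:
            return self.row_labels.index(label)
        except ValueError:
            raise CensusError(f"no row labeled {label!r}") from None

    def col_index(self, label) -> int:
        try:
            return self.col_labels.index(label)
        except ValueError:
            raise CensusError(f"no column labeled {label!r}") from None


def build_abundance_matrix(census: CensusTable,
                           meta: Mapping[str, ProteomeRecord],
                           lifestyles: Optional[Iterable[str]] = None,
                           ) -> AbundanceMatrix:
    """Assemble the FF x proteome abundance matrix from an aggregated census.

    Columns are restricted to proteomes whose lifestyle is in ``lifestyles``
    (None keeps all); rows with zero total abundance in the retained columns
    are dropped.  Labels are sorted so the matrix is deterministic.
    """
    for p in census.counts["proteome_id"].unique():
        if p not in meta:
            raise CensusError(f"proteome {p!r} has no metadata record")
    if lifestyles is None:
        keep = set(census.counts["proteome_id"])
    else:
        wanted = set(lifestyles)
        unknown = wanted - set(LIFESTYLES)
        if unknown:
            raise CensusError(f"unknown lifestyles: {sorted(unknown)}")
        keep = {p for p in census.counts["proteome_id"].unique()
                if meta[p].lifestyle in wanted}
    sub = census.counts[census.counts["proteome_id"].isin(keep)]
    cols = sorted(keep)
    rows = sorted({ff for ff in sub.loc[sub["count"] > 0, "ff"]})
    if not rows or not cols:
        raise CensusError("no data left after lifestyle filtering")
    values = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ridx = {ff: i for i, ff in enumerate(rows)}
    cidx = {p: j for j, p in enumerate(cols)}
    for row in sub.itertuples(index=False):
        values[ridx[row.ff], cidx[row.proteome_id]] = row.count
    return AbundanceMatrix(values, rows, cols)


def encode_abundance(g: int, g_max: int) -> int:
    """Normalize one abundance to a 0-23 state: Round[ln(g+1)/ln(g_max+1)*23]
    with round-half-up."""
    if g_max <= 0:
        raise CensusError("g_max must be positive (all-zero matrix carries no signal)")
    if g < 0 or g > g_max:
        raise CensusError(f"abundance {g} outside [0, g_max={g_max}]")
    x = math.log(g + 1) / math.log(g_max + 1) * 23.0
    return int(math.floor(x + 0.5))


@dataclass
class EncodedMatrix:
    """24-state encoded character matrix: rows are taxa, columns characters."""

    states: np.ndarray          # (n_taxa, n_chars) ints in 0..23
    taxa: list[str]
    characters: list[str]
    ancestral_state: int        # 23 when taxa are FFs, 0 when proteomes

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.min(initial=0) < 0 or self.states.max(initial=0) >= N_STATES:
            raise CensusError("encoded states must lie in [0, 23]")
        if self.ancestral_state not in (0, N_STATES - 1):
            raise CensusError("ancestral_state must be 0 or 23")
        if len(self.taxa) != self.states.shape[0] \
                or len(self.characters) != self.states.shape[1]:
            raise CensusError("taxon/character labels do not match state matrix")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def column(self, j: int) -> dict[str, int]:
        """One character as a leaf-label -> state mapping."""
        return {t: int(s) for t, s in zip(self.taxa, self.states[:, j])}

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, EncodedMatrix)
                and self.taxa == other.taxa
                and self.characters == other.characters
                and self.ancestral_state == other.ancestral_state
                and np.array_equal(self.states, other.states))


def encode_matrix(m: AbundanceMatrix, taxa_axis: str = "ff") -> EncodedMatrix:
    """Encode an abundance matrix with the matrix-global g_max.

    ``taxa_axis`` names the kind ('ff' or 'proteome') that plays the role of
    taxa; the other axis provides the characters.  Polarization follows the
    taxa kind: FF taxa get ancestral state 23 (high abundance ancestral),
    proteome taxa get 0 (small proteomes ancestral).
    """
    if taxa_axis not in ("ff", "proteome"):
        raise CensusError("taxa_axis must be 'ff' or 'proteome'")
    gmax = m.g_max
    if gmax < 1:
        raise CensusError("cannot encode an all-zero matrix")
    lut = np.array([encode_abundance(g, gmax) for g in range(gmax + 1)])
    states = lut[m.values]
    if taxa_axis == m.row_kind:
        taxa = [str(x) for x in m.row_labels]
        chars = [str(x) for x in m.col_labels]
    elif taxa_axis == m.col_kind:
        states = states.T
        taxa = [str(x) for x in m.col_labels]
        chars = [str(x) for x in m.row_labels]
    else:
        raise CensusError(f"matrix has no {taxa_axis!r} axis "
                          f"(kinds: {m.row_kind}, {m.col_kind})")
    ancestral = N_STATES - 1 if taxa_axis == "ff" else 0
    return EncodedMatrix(states, taxa, chars, ancestral)


# -- NEXUS interchange -----------------------------------------------------

def export_nexus(e: EncodedMatrix, path: Union[str, Path]) -> None:
    """Write a NEXUS DATA block (24-symbol ordered characters) plus an
    ASSUMPTIONS block; the ancestral state is recorded in a comment."""
    lines = ["#NEXUS", ""]
    lines.append(f"[ancestral_state={e.ancestral_state}]")
    lines.append("BEGIN DATA;")
    lines.append(f"    DIMENSIONS NTAX={e.n_taxa} NCHAR={e.n_characters};")
    lines.append(f'    FORMAT SYMBOLS="{SYMBOLS}";')
    lines.append("    CHARLABELS " + " ".join(e.characters) + ";")
    lines.append("    MATRIX")
    width = max(len(t) for t in e.taxa) + 2
    for t, row in zip(e.taxa, e.states):
        seq = "".join(SYMBOLS[s] for s in row)
        lines.append(f"    {t:<{width}}{seq}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN ASSUMPTIONS;")
    lines.append("    OPTIONS DEFTYPE=ORD;")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_nexus(path: Union[str, Path]) -> EncodedMatrix:
    """Re-parse a matrix written by :func:`export_nexus`."""
    text = Path(path).read_text(encoding="utf-8")
    m = re.search(r"\[ancestral_state=(\d+)\]", text)
    if not m:
        raise CensusError(f"{path}: missing ancestral_state comment")
    ancestral = int(m.group(1))
    dim = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+);", text)
    if not dim:
        raise CensusError(f"{path}: missing DIMENSIONS line")
    ntax, nchar = int(dim.group(1)), int(dim.group(2))
    mat = re.search(r"MATRIX\s*\n(.*?)\n\s*;", text, re.S)
    if not mat:
        raise CensusError(f"{path}: missing MATRIX block")
    taxa, rows = [], []
    for line in mat.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        name, seq = line.split(None, 1)
        seq = seq.strip()
        if len(seq) != nchar:
            raise CensusError(f"{path}: row {name} has {len(seq)} states, "
                              f"expected {nchar}")
        taxa.append(name)
        try:
            rows.append([SYMBOLS.index(c) for c in seq])
        except ValueError as exc:
            raise CensusError(f"{path}: bad symbol in row {name}") from exc
    if len(taxa) != ntax:
        raise CensusError(f"{path}: expected {ntax} taxa, found {len(taxa)}")
    cl = re.search(r"CHARLABELS\s+(.*?);", text, re.S)
    if cl:
        chars = cl.group(1).split()
        if len(chars) != nchar:
            raise CensusError(f"{path}: {len(chars)} character labels for "
                              f"{nchar} characters")
    else:
        chars = [f"char{j + 1}" for j in range(nchar)]
    return EncodedMatrix(np.array(rows), taxa, chars, ancestral)
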