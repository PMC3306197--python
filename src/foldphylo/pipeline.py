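"""End-to-end pipeline: census -> matrices -> trees -> timeline -> report.

Every run writes its artifacts (NEXUS matrix, Newick trees, timeline TSV,
per-tree statistics JSON, plots) into one output directory together with a
manifest recording input hashes, seeds and package version, so that a rerun
with the same configuration is reproducible artifact for artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .census import (build_abundance_matrix, encode_matrix, export_nexus,
                     load_census, load_metadata)
from .functions import annotate, first_appearance, load_function_map
from .parsimony import (SearchParams, g1_signal, heuristic_search,
                        lundberg_root, majority_consensus, tree_stats)
from .proteome import basal_group, phase_subset, proteome_tree, transpose
from .timeline import (PAPER_PHASES, PhaseDefinition, build_timeline,
                       cumulative_distribution, timeline_frame, use_reuse)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    census: str
    metadata: str
    outdir: str
    function_map: Optional[str] = None
    lifestyles: list = field(default_factory=lambda: ["free_living"])
    e_value_cutoff: float = 1e-4
    seed: int = 0
    replicates: int = 2
    swap: str = "SPR"
    bootstrap_reps: int = 25
    g1_trees: int = 2000
    phase_trees: bool = True
    renormalize_phases: bool = True
    plots: bool = True
    phase_names: Optional[list] = None
    phase_uppers: Optional[list] = None

    def phases(self) -> PhaseDefinition:
        if self.phase_names is None:
            return PAPER_PHASES
        return PhaseDefinition(tuple(self.phase_names),
                               tuple(self.phase_uppers))


def load_config(path: Union[str, Path]) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return PipelineConfig(**data)


def _sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _tree_report(tree, enc, seed: int, g1_trees: int) -> dict:
    stats = tree_stats(tree.unroot() if tree.rooted else tree, enc)
    rep = stats.as_dict()
    if enc.n_taxa >= 4 and g1_trees > 0:
        rep["g1"] = g1_signal(enc, n_random_trees=g1_trees, seed=seed)
    rep["lundberg_ties"] = tree.metadata.get("lundberg_ties")
    rep["n_mp_trees"] = tree.metadata.get("n_mp_trees")
    return rep


def _build_ff_tree(enc, cfg: PipelineConfig):
    trees = heuristic_search(enc, n_replicates=cfg.replicates,
                             seed=cfg.seed, swap=cfg.swap)
    tree = trees[0] if len(trees) == 1 else majority_consensus(trees)
    rooted = lundberg_root(tree, enc)
    rooted.metadata["n_mp_trees"] = len(trees)
    return rooted


def run_pipeline(config: Union[PipelineConfig, str, Path, dict]) -> dict:
    """Execute build-matrix -> tree-ff -> timeline -> functions ->
    phase-trees -> report; returns the report dict (also written as JSON).
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig(**config)
    else:
        cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("census", "metadata", "function_map"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"missing input: {name} = {p}")

    census = load_census(cfg.census, e_value_cutoff=cfg.e_value_cutoff)
    meta = load_metadata(cfg.metadata)
    matrix = build_abundance_matrix(census, meta,
                                    lifestyles=cfg.lifestyles or None)
    report: dict = {
        "n_ffs": len(matrix.row_labels),
        "n_proteomes": len(matrix.col_labels),
        "g_max": matrix.g_max,
    }

    # tree of fold families (taxa = FFs, ancestral state 23)
    enc_ff = encode_matrix(matrix, taxa_axis="ff")
    export_nexus(enc_ff, outdir / "matrix_ff.nex")
    ff_tree = _build_ff_tree(enc_ff, cfg)
    (outdir / "tree_ff.nwk").write_text(ff_tree.to_newick(with_support=True)
                                        + "\n", encoding="utf-8")
    report["ff_tree"] = _tree_report(ff_tree, enc_ff, cfg.seed, cfg.g1_trees)

    # timeline
    phases = cfg.phases()
    entries = build_timeline(matrix, meta, ff_tree, phases=phases)
    if cfg.function_map:
        entries = annotate(entries, load_function_map(cfg.function_map))
        for level in ("major", "minor"):
            fa = first_appearance(entries, level=level)
            fa.to_csv(outdir / f"first_appearance_{level}.tsv", sep="\t",
                      header=["first_nd"], index_label="category")
        report["n_annotated"] = sum(
            1 for e in entries if e.major_category is not None)
        report["n_unannotated"] = sum(
            1 for e in entries if e.major_category is None)
    tl = timeline_frame(entries)
    tl.to_csv(outdir / "timeline.tsv", sep="\t", index=False)
    report["phase_counts"] = tl["phase"].value_counts().to_dict()
    report["group_counts"] = tl["group"].value_counts().to_dict()
    cumulative_distribution(entries, by="group").to_csv(
        outdir / "cumulative_by_group.tsv", sep="\t", index=False)
    ur = use_reuse(matrix, meta)
    ur.to_csv(outdir / "use_reuse.tsv", sep="\t", index=False)

    # global tree of proteomes (taxa = proteomes, ancestral state 0)
    params = SearchParams(replicates=cfg.replicates, swap=cfg.swap,
                          seed=cfg.seed, bootstrap_reps=cfg.bootstrap_reps)
    tm = transpose(matrix)
    pt = proteome_tree(tm, search=params)
    (outdir / "tree_proteome.nwk").write_text(
        pt.to_newick(with_support=True) + "\n", encoding="utf-8")
    enc_p = encode_matrix(tm, taxa_axis="proteome")
    report["proteome_tree"] = _tree_report(pt, enc_p, cfg.seed, cfg.g1_trees)
    basal = basal_group(pt, meta)
    report["proteome_tree"]["basal_superkingdom"] = basal.superkingdom
    report["proteome_tree"]["basal_taxon"] = basal.basal_taxon
    report["proteome_tree"]["monophyly"] = basal.monophyly

    # phase-specific proteome trees
    if cfg.phase_trees:
        report["phase_trees"] = {}
        for phase in phases.names:
            if not (tl["phase"] == phase).any():
                continue
            sub = phase_subset(matrix, entries, phase)
            sub_t = transpose(sub)
            if cfg.renormalize_phases:
                enc_sub = encode_matrix(sub_t, taxa_axis="proteome")
            else:
                # keep the global codes: slice the phase's characters out of
                # the globally encoded proteome matrix
                cols = [enc_p.characters.index(str(ff))
                        for ff in sub_t.col_labels]
                from .census import EncodedMatrix
                enc_sub = EncodedMatrix(enc_p.states[:, cols],
                                        list(enc_p.taxa),
                                        [enc_p.characters[c] for c in cols],
                                        enc_p.ancestral_state)
            ptp = proteome_tree(sub_t, search=params, encoded=enc_sub)
            (outdir / f"tree_proteome_phase_{phase}.nwk").write_text(
                ptp.to_newick(with_support=True) + "\n", encoding="utf-8")
            prep = _tree_report(ptp, enc_sub, cfg.seed, cfg.g1_trees)
            b = basal_group(ptp, meta)
            prep["basal_superkingdom"] = b.superkingdom
            prep["basal_taxon"] = b.basal_taxon
            prep["n_ffs"] = len(sub.row_labels)
            report["phase_trees"][phase] = prep

    if cfg.plots:
        _write_plots(tl, ur, outdir)

    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=str) + "\n",
                                        encoding="utf-8")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "inputs": {name: _sha256(getattr(cfg, name))
                   for name in ("census", "metadata", "function_map")
                   if getattr(cfg, name)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2)
                                          + "\n", encoding="utf-8")
    return report


def _write_plots(tl, ur, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "red", "B": "blue", "E": "gray"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in tl.groupby("group"):
        ax.scatter(sub["nd"], sub["f_global"], s=12, label=group, alpha=0.7)
    ax.set_xlabel("nd (relative age)")
    ax.set_ylabel("f (fraction of proteomes)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "timeline_nd_vs_f.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in tl.groupby("group"):
        nds = np.sort(sub["nd"].to_numpy())
        ax.step(nds, np.arange(1, len(nds) + 1), where="post", label=group)
    ax.set_xlabel("nd")
    ax.set_ylabel("cumulative FFs")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "cumulative_by_group.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for sk, sub in ur.groupby("superkingdom"):
        ax.scatter(sub["n_distinct_ffs"], sub["total_abundance"],
                   c=colors.get(sk, "black"), label=sk, s=18)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("FF use (distinct families)")
    ax.set_ylabel("FF reuse (total abundance)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "use_reuse.png", dpi=120)
    plt.close(fig)
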