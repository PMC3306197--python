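# foldphylo

Phylogenomic analysis of protein fold-family abundance censuses.

Deep evolutionary history is hard to read from molecular sequences —
mutational saturation, rate heterogeneity, and site non-independence blur
the base of the tree of life.  Protein domain *structures* are far more
conserved: the number of times each SCOP fold family (FF) appears in a
proteome (its genomic abundance) is a slowly evolving, multistate
character.  `foldphylo` turns a census of FF abundances across proteomes
into:

* **rooted trees of fold families** (taxa = FFs, characters = proteomes)
  and a **timeline of domain appearance** — each family's relative age
  *nd* read off the unbalanced tree, its distribution index *f*, its
  superkingdom Venn group (A/B/E/AB/AE/BE/ABE), and its evolutionary
  phase;
* **rooted trees of proteomes** (taxa = proteomes, characters = FFs),
  globally and per phase, with bootstrap supports and identification of
  the basal superkingdom;
* **functional chronologies**: each family inherits the coarse-grained
  category (7 major / 49 minor) of its parent fold superfamily, and the
  first appearance of each category is placed on the timeline.

It is written for molecular evolution researchers who want a tested,
reproducible, pure-Python implementation of this census methodology that
runs at desk scale on their own assignment tables.

## The method in brief

Abundances are normalized to 24 linearly ordered character states
(symbols `0-9`, `A-N`):

    g_norm = Round[ ln(g + 1) / ln(g_max + 1) x 23 ]

Trees are built by Wagner (ordered) maximum parsimony — a change between
states *i* and *j* costs |i − j| — with random-addition-sequence
heuristic search and SPR branch swapping, and rooted without outgroups by
the Lundberg method: a hypothetical ancestor with every character at the
ancestral extreme is attached on the length-minimizing edge.  Polarization
is asymmetric: high abundance (state 23) is ancestral for trees of
families ("ancient domains had more time to accumulate"), low abundance
(state 0) for trees of proteomes ("repertoires grow from a small
primordial ancestor").  Homoplasy is summarized by ensemble and
per-character consistency and retention indices, phylogenetic signal by
the skewness (*g1*) of random-tree lengths, and confidence by character
bootstrap and 50% majority-rule consensus.  Details and all numerical
conventions are in [docs/methods.md](docs/methods.md).

Because no public accession ships the original census, the package
includes a first-class synthetic-data module: seeded worlds with an
archaeal-first organismal history, communal birth of families, lineage
loss (elevated early in Archaea), and preferential-attachment duplication,
retaining ground truth for every quantity the pipeline estimates.

## Worked example

```python
from foldphylo import (WorldParams, generate_world, world_to_inputs,
                       build_abundance_matrix, encode_matrix,
                       heuristic_search, lundberg_root, build_timeline,
                       tree_stats)
from foldphylo.proteome import transpose, proteome_tree, basal_group
from foldphylo.parsimony import SearchParams

world = generate_world(WorldParams(n_ff=30, n_per_superkingdom=4), seed=11)
census, meta = world_to_inputs(world)
matrix = build_abundance_matrix(census, meta, lifestyles=["free_living"])

enc = encode_matrix(matrix, taxa_axis="ff")        # ancestral state 23
tree = heuristic_search(enc, n_replicates=2, seed=11)[0]
rooted = lundberg_root(tree, enc)
stats = tree_stats(tree, enc)
entries = build_timeline(matrix, meta, rooted)

pt = proteome_tree(transpose(matrix),              # ancestral state 0
                   search=SearchParams(replicates=2, seed=11,
                                       bootstrap_reps=0))
rep = basal_group(pt, meta)
```

printed quantities from this exact run:

```
census: 30 fold families x 12 proteomes, g_max=69
FF tree: length=675, CI=0.279, RI=0.534
oldest family: f.13.1.1 (nd=0.00, group=ABE, phase I, f=0.92)
proteome tree rooted in superkingdom A (basal taxon A03)
```

The FF tree's length is the total number of ordered-character steps; the
low ensemble CI is expected for abundance characters (many states, many
taxa).  The oldest family (nd = 0) is shared by all three superkingdoms
(group ABE, phase I — the primordial, communal protein world) and present
in 92% of proteomes.  The proteome tree, built from the transposed matrix
with reversed polarization, roots on an archaeal lineage — recovering the
simulated archaeal-first history.

## Command line

```
foldphylo simulate --n-ff 60 --per-sk 6 --seed 1 --outdir sim/
foldphylo run --config config.yaml        # full pipeline, all artifacts
foldphylo build-matrix --census sim/census.tsv --metadata sim/metadata.tsv \
    --taxa proteome --out m.nex
foldphylo tree --nexus m.nex --replicates 5 --out tree.nwk
foldphylo signal --nexus m.nex --n-trees 10000
```

`run` executes build-matrix → FF tree → timeline → functions →
proteome/phase trees → report, writing NEXUS/Newick/TSV/JSON artifacts,
plots, and a manifest (input hashes, seed, version) into the configured
output directory; a rerun with the same config reproduces the artifacts
byte for byte.

Input formats: census TSV (`proteome_id, ff, count` or per-hit
`proteome_id, ff, e_value`, filtered at 1e-4), metadata TSV
(`proteome_id, superkingdom, lifestyle`), function map TSV
(`sf_ccs, major_category, minor_category`).

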