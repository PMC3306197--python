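# Methods

## The model

`foldphylo` reconstructs the evolutionary history of protein domains from a
*genomic census*: the number of times each SCOP fold family (FF) is
assigned to each proteome.  The working premise is that domain structures
spread and accumulate as genes duplicate and diversify, so families that
are more abundant across the protein world are, on average, more ancient —
a "rich get richer" accumulation process.  Genomic abundance therefore
carries deep phylogenetic signal that sequence-level characters have lost
to saturation.

Abundances g are normalized to 24 ordered character states,

    g_norm = Round[ ln(g + 1) / ln(g_max + 1) * 23 ],

with g_max the maximum abundance of the matrix under analysis and Round a
round-half-up (so `encode(10, 100) = 12`, symbol `C` in the `0-9A-N`
alphabet).  Character evolution is Wagner (ordered) parsimony: a change
between states i and j costs |i - j|.

Polarization is asymmetric by design and encodes two different biological
statements:

* **Trees of FFs** (taxa = fold families, characters = proteomes): state
  23 is ancestral.  Ancient families had more time to accumulate; there is
  no cap on a family's copy number across the protein world.
* **Trees of proteomes** (taxa = proteomes, characters = FFs): state 0 is
  ancestral.  Proteome repertoires grow from a small primordial ancestor,
  under an energetic cap that canalizes growth.

Both trees are rooted without outgroups by the Lundberg procedure: a
hypothetical ancestor with every character at the ancestral extreme is
attached to each edge of the most parsimonious unrooted tree in turn, and
the root is placed on the edge minimizing total length.  Ties are broken
by deterministic edge order and counted in the tree's metadata.

Relative ages are node distances: for each leaf, the number of internal
nodes strictly between root and leaf, normalized by the deepest leaf, so
nd = 0 is the most ancestral taxon and nd = 1 the most recent.  nd = 0 for
the earliest leaf is guaranteed whenever the root sits on a terminal edge,
which is where Lundberg rooting with an extreme ancestor lands on strongly
polarized data.  The nd axis is partitioned into five phases at the
boundaries 0.150, 0.256, 0.550, 0.661 (primordial world, archaeal
reductive evolution, superkingdom development, organismal diversification,
eukaryal diversification); the boundaries are configuration, and
data-driven phase detection is deliberately not attempted.

## Algorithms and numerical choices

* **Tree length.** Linear-cost Sankoff dynamic programming.  The min-plus
  step for the |i - j| metric factors into two cumulative-minimum sweeps,
  so one edge costs O(characters x 24) vectorized work; the DP is exact on
  multifurcating trees (consensus trees included).
* **Search.** Random-addition-sequence stepwise insertion followed by
  best-improvement SPR hill climbing (NNI and TBR are available).  All
  candidate placements of one pruned subtree are scored from directed
  up/down cost vectors in O(n) per prune rather than O(n) full
  re-evaluations, which is what makes desk-scale matrices (tens of taxa)
  interactive.  Equal-length trees found across replicates are kept as a
  set; downstream consumers take the 50% majority-rule consensus when the
  set has more than one member.
* **Determinism.** Every stochastic component (addition order, bootstrap
  resampling, random topologies, the simulator) draws from one seeded
  numpy Generator; ties break by lexicographic taxon/edge order.  Rerunning
  a configuration reproduces artifacts exactly.
* **Diagnostics.** Per character: observed steps s, ordered minimum
  m = max - min, star maximum g = min over integer centers z of
  sum |x - z| (z at a median), ci = m/s (1 when s = 0), ri = (g-s)/(g-m)
  (undefined when g = m, reported as such and excluded from ensemble RI
  sums).  Ensemble CI = sum(m)/sum(s), RI over characters with g > m.
* **Signal.** g1 is the bias-corrected sample skewness of tree lengths
  over uniform random topologies (sequential addition with uniform edge
  choice); it is exactly 2.0 on the pattern [0,0,0,1] and strongly
  negative on structured matrices.  Zero-variance length distributions
  yield NaN.
* **Bootstrap.** Characters are resampled to the original count as
  multinomial weights; a replicate counts a split iff the split is in the
  strict consensus of the replicate's best trees.  This makes "two
  complementary splits never both above 50%" a theorem rather than an
  observation.
* **Informativeness.** Exact by topology enumeration up to 8 taxa.  Above
  that, a character is called informative iff at least two states occur
  twice, or at least three distinct states occur; the rule is exact for
  the degenerate patterns that dominate census data and is checked against
  enumeration in the tests.
* **Monophyly calls.** A superkingdom is monophyletic when some clade
  equals its leaf set; otherwise a most parsimonious reconstruction of its
  presence (root forced absent) decides between one origin plus losses
  (paraphyletic) and several origins (polyphyletic).
* **Phase-specific proteome trees** re-encode each subset against the
  subset's own g_max (a switch keeps the global codes instead); phase
  labels always come from the global timeline.

## The synthetic worlds

The generator emulates the process the census model assumes, with ground
truth retained for every quantity the pipeline estimates:

* A rooted organismal tree over three superkingdom clades; Archaea
  diverges first (root at t = 0.10), Bacteria and Eukarya split at
  t = 0.30, within-clade divergences at sorted uniform times.
* FF birth times uniform on [0, 1]; a family is born into the communal
  world (present in all contemporary lineages) and is thereafter carved by
  per-branch loss.  Loss rates: background 0.03/branch; 0.45 on archaeal
  branches for families born before t = 0.25 (reductive evolution — this
  is what creates Bacteria+Eukarya-only families); 0.35 on microbial
  branches for families born after t = 0.66 (so late innovation is
  effectively eukaryal).
* Abundance grows by preferential attachment: each copy duplicates per
  time slice (50 slices) with a per-proteome rate = 0.06 x superkingdom
  multiplier (A 0.6, B 1.0, E 1.4, matching the archaeal-bacterial-
  eukaryal progression of proteome sizes) x a lognormal factor evolving
  brownianly along the tree (sigma 0.3 per unit time).  The superkingdom
  multipliers give the proteome tree its rooting signal; the Brownian
  component gives within-clade covariance; exponential growth in age gives
  the heavy-tailed ("rich get richer") abundance distribution and the
  age-abundance gradient the FF tree reads.
* Reported counts get multiplicative lognormal noise (sigma 0.25),
  floored at one copy for surviving families.

What the worlds do **not** emulate: horizontal transfer, domain
recruitment between families, correlated loss across families, real SCOP
class composition, and the paper-scale census (2,397 FFs x 420 proteomes).
Passing tests therefore show the pipeline recovers the histories this
process generates at desk scale; they do not certify behavior on the
full SUPERFAMILY census.

## Problem sizes and stability

Analyses in the tests and the acceptance script run at 60 families x 18
proteomes (6 per superkingdom), with 2 random-addition replicates for the
60-taxon searches and 10 for the small oracle-comparison instances; these
sizes keep a full run in minutes while leaving every qualitative result
(archaeal rooting, negative g1, heavy-tailed abundances, phase structure)
intact.  With only 18 characters the nd ranking of a single most
parsimonious tree retains noticeable seed-to-seed variance even though the
underlying abundance-age gradient is stable; the acceptance script
therefore averages its timeline-recovery and rooting metrics over five
independent worlds.  Early archaeal loss also genuinely delays the
apparent age of the oldest families (they surface at the start of the
reductive phase rather than at nd = 0) — the same effect the census model
describes for Bacteria+Eukarya-only families.

## Known limitations

* Heuristic search is not guaranteed to retain *all* co-optimal trees, so
  consensus trees may be over-resolved relative to an exhaustive collection;
  the oracle tests bound this at small sizes.
* nd is undefined on a star tree (no internal structure below the root);
  such degenerate consensus trees raise an error rather than fabricate
  ages.
* The Lundberg ancestor uses the ancestral extreme state, as the
  polarization prescribes; rooting with intermediate ancestors is not
  provided.
* Exhaustive search is refused above 9 taxa ((2n-5)!! growth).
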