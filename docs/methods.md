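# Methods

This note documents the models, estimators and numerical choices behind
`complexevo`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the procedure was
genuinely open.

## Network construction and weighting

Interactions are an undirected simple graph over protein identifiers.
Self-interactions are dropped on ingest (clustering adds its own
self-loops, and complexes are sets of distinct proteins); duplicate
edges across resources carry no multiplicity — a union of interaction
*sets*, not a count of evidence. TAP-MS bait–prey records expand under
the spoke model (bait–prey edges only) or the matrix model (all pairs
over bait ∪ preys); each purification expands independently and the
edge-set union merges duplicates.

Edge weights are `1 + GOSS(u, v)`. GOSS is Resnik similarity: the
information content of the most-informative common ancestor, maximised
over pairs of the proteins' *direct* biological-process terms, while
term frequencies for IC use *propagated* sets (direct terms plus all
`is_a` ancestors) — the Lord et al. convention. IC uses the natural
logarithm; only relative magnitudes matter for clustering. The reference
corpus for frequencies is the ingested annotation file itself. Only
`is_a` edges are traversed by default (`part_of` behind a switch). An
unannotated endpoint gives GOSS 0, so weighting degrades gracefully to
the unweighted (all-ones) network. Evidence-code filtering always drops
ND; IEA is dropped unless explicitly included (coverage in bacteria is
often too low without it).

## Markov clustering

The adjacency matrix (with self-loops set per node to its maximum
incident edge weight, a standard stabilisation) is column-normalised and
iterated: expansion (matrix power 2), inflation (entrywise power *I*,
column renormalisation), pruning of entries below 1e-5, until the
maximum entry change falls below 1e-6 or 100 iterations pass
(non-convergence interprets the current matrix with a logged warning).
These tolerances were chosen to converge comfortably on desk-scale
graphs (up to ~10⁴ nodes / 10⁵ edges on one CPU; matrices are
`scipy.sparse`). Clusters are attractor systems: rows with surviving
diagonal mass; attractor rows sharing support are merged; a node
attracted to several systems goes to the one with the larger total
attraction mass, ties broken toward the cluster containing the
lexicographically smallest member — required because predicted
complexes must be disjoint. Flow cannot cross connected components, so
components are never merged. Clusters of size one are removed before
any downstream analysis.

## Benchmark scores

Sensitivity, PPV and accuracy follow the Brohée & van Helden scheme.
Gold complexes of size one are excluded; clusters sharing no member with
any gold complex are excluded. The PPV column weight `T_j` is the column
marginal `Σ_i T_ij`, which makes each column a proper distribution when
gold complexes overlap; the literal variant (`T_j` = distinct
gold-annotated proteins in the cluster) is available via
`literal_tj=True` — the two differ only on overlapping gold standards.
The random baseline shuffles the pooled cluster members over the fixed
cluster-size skeleton; the SD reported is the population SD over
replicates.

## Permutation machinery

Every evolutionary statistic shares one null model: a uniform random
permutation of the pooled membership multiset re-sliced into the
original complex sizes. This preserves the complex-size distribution and
the protein multiset exactly. Within one analysis run a single stream of
shuffled datasets serves all per-superfamily tests (dataset-level
randomisation), so statistics computed on the same replicates are
comparable. Proteins without domain annotation occupy shuffle slots but
can never form homologous pairs, mirroring partial annotation coverage
in real proteomes.

Empirical p-values default to `(1 + #{null ≥ observed}) / (1 + n_rand)`:
the add-one form cannot return zero and counting ties against the
hypothesis is conservative. The literal "proportion of trials in which
the observed count was exceeded" (strict `>`, no pseudocount) is
available via `strict=True`. Defaults: 10 000 shuffles, superfamilies
tested only with ≥ 5 members (statistical power), BH-FDR at α = 0.01
across superfamilies. The correlated-pair screen applies a raw p ≤ 0.01
cutoff over the candidate pairs observed in ≥ 2 real complexes — no FDR,
matching the screen's design — with an optional BH switch. A complex
witnesses a correlated pair (A, B) only through *distinct* proteins, but
a witness protein may itself carry both domains provided a distinct
partner exists.

Functional-coherence nulls sample equal-size sets from the annotated
proteome (the annotated universe is the natural comparison set; sampling
from the full proteome would conflate annotation coverage with
coherence).

## Phylogenetic ages

Orthologues are bidirectional best hits at E ≤ 0.01. A tied best hit
satisfies the condition by default (`strict_unique` requires
uniqueness). Age groups are configuration data: a clade-presence-pattern
→ label table (vocabularies for an E. coli-like and a yeast-like focal
species ship with the package), ordered youngest → oldest, with a
precedence list mapping patterns that lack an exact rule to the nearest
defined label (logged). Presence of a clade means *any* species of the
clade holds an orthologue; requiring all species would be stricter and
is noted as the alternative. The chi-square test of homogeneity uses no
continuity correction; groups with expected counts below 5 are pooled
into the neighbouring older group (logged) — disable with
`pool_small=False`.

## Synthetic worlds

The generator produces the statistical structure the analysis assumes,
not realistic interactomes: planted complexes wired densely within
(default p_within = 0.9) and sparsely between (p_between = 0.01), sizes
from a truncated geometric on [2, 30] (right-skewed, echoing observed
complex-size distributions); TAP records with false-negative prey
drop-out and false-positive preys; domain annotations where a chosen
fraction of complexes receives a shared-superfamily pair (every second
one an identical full architecture), chosen correlated pairs planted
into ≥ 2 complexes via distinct proteins, and the rest drawn uniformly
from a background pool; a rooted `is_a` tree with random annotations
propagated to ancestors; and age profiles where background proteins
follow a geometrically young-shifted distribution and a planted core
the old-shifted mirror (decay 0.45 per group). Protein identifiers are
zero-padded sequential strings so all outputs sort reproducibly.

One global seed fans out to per-stage child generators through
`SeedSequence([seed, crc32(stage_name)])`; regenerating a world with the
same seed and parameters is byte-identical on disk. Passing tests on
these worlds therefore demonstrates correctness of the *procedures*
(recovery of planted structure, calibration of null rejection rates),
not performance on real data, whose degree distributions, annotation
biases and experimental noise the generator deliberately does not model.

## Problem sizes used by the test-suite and acceptance script

Recovery experiments use 20–60 planted complexes (roughly 100–300
proteins) and 1 000 permutations; null calibrations use 40–200 replicate
worlds or draws at nominal levels 0.01/0.05 with 3-binomial-SE
tolerances. These sizes give each check clear statistical resolution
while keeping a full run in the order of seconds to minutes on one CPU;
production analyses default to 10 000 permutations.

## Known limitations

* MCL interpretation on near-degenerate converged matrices (overlapping
  attractor systems) relies on the documented mass/tie-break rule;
  alternative implementations may split borderline nodes differently.
* The empirical-p add-one convention makes single-test calibration
  conservative at very small n_rand.
* Gold standards may overlap, but predicted datasets (and therefore the
  membership shuffle) assume disjoint complexes.
* The generator's GO annotations are term-uniform, so synthetic GOSS
  weighting improves clustering only marginally; its purpose is
  correctness of the weighting path, not a realistic signal boost.
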