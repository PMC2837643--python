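# complexevo

Tools for predicting protein complexes from protein–protein interaction
(PPI) networks and asking how those complexes evolved: do homologous
proteins cluster together, do non-homologous domain pairs recur across
complexes, and are putative complex cores evolutionarily older than the
rest of the proteome?

The package is aimed at computational biologists who have pairwise
interaction data (or TAP-MS bait–prey records), domain-superfamily
assignments (CATH-style), GO annotations and orthologue tables for one
or more organisms, and who want a reproducible, permutation-tested
pipeline rather than a one-off script.

## What it computes

**Complex prediction (MCL-GO).** Bait–prey purifications are expanded to
pairwise interactions under the *spoke* model (bait to each prey) or the
*matrix* model (all pairs over bait and preys), unioned across resources,
and optionally weighted by functional similarity: each edge (u, v) gets
weight `1 + GOSS(u, v)`, where GOSS is the Resnik semantic similarity —
the information content `IC(c*) = −ln(n(c*)/n(root))` of the
most-informative common ancestor of the proteins' GO biological-process
terms, maximised over their term pairs. The weighted network is clustered
with the Markov Cluster algorithm (alternating expansion `M ← M²` and
inflation `M ← M^{∘I}` with column renormalisation); the inflation
parameter *I* sets cluster granularity and is tuned against a curated
gold standard.

**Benchmarking.** Clusters are scored against gold complexes through the
contingency table `T[i, j]` (members of complex *i* in cluster *j*):

    Sn  = Σ_i N_i · max_j (T_ij / N_i) / Σ_i N_i
    PPV = Σ_j T_j · max_i (T_ij / T_j) / Σ_j T_j        (T_j = Σ_i T_ij)
    Acc = √(Sn · PPV)

with a random baseline from shuffling proteins between clusters while
preserving cluster sizes.

**Evolutionary statistics.** All use the same null model — membership
shuffles preserving the complex size distribution — with empirical
p-values `(1 + #{null ≥ obs}) / (1 + n_rand)`:

* per-superfamily co-complex pair counts, Benjamini–Hochberg corrected,
  to find non-randomly distributed superfamilies;
* the fraction of complexes containing a homologous pair, at the shared-
  domain level and at the identical multi-domain-architecture level;
* correlated pairs of *non-homologous* superfamilies recurring across
  complexes, plus interaction and functional-similarity enrichment of
  the witnessing protein pairs;
* phylogenetic age profiles from bidirectional-best-hit orthologues
  (E ≤ 0.01), compared between protein classes by chi-square.

A synthetic-data module generates complete "planted worlds" (modular
PINs, TAP records, domain annotations with planted homologous/correlated
structure, a small GO DAG, orthologue age profiles) so the whole pipeline
is testable without any external download.

## Worked example

```python
import complexevo as ce

# a planted world: 20 complexes, dense within (0.9), sparse between (0.01)
net, truth = ce.generate_planted_pin(20, p_within=0.9, p_between=0.01, seed=11)

table = ce.inflation_sweep(net, truth, [1.4, 1.8, 2.2, 2.6, 3.0, 3.5, 4.0, 5.0],
                           n_random=1000, seed=7)
best = table.loc[table["accuracy"].idxmax()]
print(f"best I={best['inflation']}  Acc={best['accuracy']:.3f}  "
      f"random={best['random_mean']:.3f}±{best['random_sd']:.3f}")
```

prints

```
best I=2.2  Acc=0.970  random=0.299±0.018
```

i.e. at inflation 2.2 the recovered clusters match the planted complexes
almost perfectly (geometric mean of sensitivity and purity 0.97), some
36 standard deviations above what size-matched random clusters achieve
(≈0.30). A homology screen on a world with homologous pairs planted into
half the complexes:

```python
w = ce.generate_world(seed=3, planted_homolog_complex_fraction=0.5,
                      n_superfamilies=600)
res = ce.complexes_with_homolog_pairs(w.true_complexes, w.domain_annotation,
                                      n_rand=1000, seed=1)
print(f"{100 * res.fraction:.0f}% of complexes contain homologous pairs "
      f"(p = {res.permutation.p_value:.4g})")
```

prints `50% of complexes contain homologous pairs (p = 0.000999)` — the
planted fraction back, significant at the permutation floor of
1/(n_rand + 1).

The same stages are available from the shell:

```bash
complexevo simulate --seed 4 --out world --homolog-fraction 0.5
complexevo cluster --edges world/edges.tsv --inflation 2.2 --out complexes.tsv
complexevo benchmark --pred complexes.tsv --gold world/true_complexes.tsv
complexevo run --config pipeline.yaml     # full pipeline, report.json
```

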