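# pangem — partitioned pangenome graphs

`pangem` statistically partitions microbial pangenomes. Given a set of
annotated genomes of one species (GFF3 plus a gene → family mapping, or
directly a presence/absence matrix), it classifies every gene family as
**persistent** (present in almost all genomes), **shell** (intermediate
frequency, possibly several contrasted sub-patterns) or **cloud** (rare,
recently acquired), and characterizes how open the pangenome is. It is
aimed at comparative genomicists working with tens to thousands of
conspecific genomes, including fragmented draft assemblies.

## The model

The pangenome is represented two ways at once:

* a binary **P/A matrix** `X` (F families × N genomes), with
  `x_ij = 1` when family *i* has at least one member in genome *j*;
* a **pangenome graph** `G` whose nodes are families and whose edges
  link families with genes that are direct chromosomal neighbors in
  some genome, weighted by `w = (adjacency count) / N`. Because the
  graph is a union over genomes, an assembly gap in one genome is
  offset by the others.

Rows of `X` follow a K-component multivariate **Bernoulli mixture**:

    P(X_i) = Σ_k π_k Π_j ε_kj^|x_ij − μ_kj| (1 − ε_kj)^(1 − |x_ij − μ_kj|)

with binary centroids μ_k and dispersions ε_k (shared across genomes
within a component by default). Parameters are fitted by EM from a
triangular initialization that pins component 1 to the all-present
(persistent) pattern and component K to the all-absent (cloud) pattern.
The number of partitions K is chosen on a grid by **ICL** (BIC minus
classification entropy) after short EM runs, preferring the smallest K
within a margin δ_ICL of the best score.

On top of the mixture, a hidden **Markov random field** over the graph
rewards neighboring families for sharing a partition (spatial
coefficient β, default 2.5; hubs with degree > 10 are not smoothed).
The E-step becomes a mean-field fixed point — this is Neighboring EM
(NEM); β = 0 recovers the plain mixture exactly. For cohorts beyond
~500 genomes, partitioning runs on random genome chunks and labels are
decided by absolute-majority vote across chunks.

Pangenome dynamics are summarized by rarefaction: component sizes over
random genome subsets (30 replicates per size), fitted with Heaps' law
`F = κ·n^γ` (γ ≈ 0 means a closed, stabilized component) plus the IQR
area of the curve's interquartile ribbon as a stability measure.

## Worked example

```python
import pangem as pg

# synthetic species: 400 families × 30 genomes, islands at 5 hotspots
pa, genomes, truth = pg.generate_pangenome(F=400, N=30, seed=0)
graph = pg.build_graph(genomes)

sel = pg.select_K(pa, range(3, 13))          # -> K_hat = 3
est = pg.NEMPartitioner(n_partitions=sel.K_hat, beta=2.5).fit(pa, graph=graph)
print(est.partitioning_.counts())
# {'persistent': 110, 'shell': 85, 'cloud': 205}
print(est.weights_.round(3), est.dispersion_[:, 0].round(3))
# [0.275 0.213 0.512] [0.048 0.286 0.06 ]
```

The fitted mixing proportions and dispersions match the generator's
π = (0.3, 0.2, 0.5), ε = (0.05, 0.3, 0.05), and all 400 families get
their true partition back. Rarefaction on the same data shows why a
model-based persistent genome beats a fixed-threshold core:

```python
res = pg.rarefaction_curves(pa, graph, max_n=30, reps=10, seed=0, reselect_K=False)
print(res.heaps["persistent"].gamma)   # -0.0007  (stable estimate)
print(res.heaps["soft_core"].gamma)    #  0.41    (still climbing at n=30)
```

The persistent component's γ-tendency is already ≈ 0 while the
soft core (≥95% presence) is far from stabilized — the threshold method
underestimates the persistent genome at small sample sizes and its
curve carries a stair-step artifact (one extra tolerated absence every
20 genomes at 95%).

A CLI mirrors the library: `pangem synth`, `pangem build`,
`pangem partition --K auto --beta 2.5`, `pangem rarefaction`,
`pangem stats`.

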