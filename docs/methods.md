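# Methods

## Data model

A genome is an ordered set of contigs, each an ordered gene list
(sorted by start, ties broken by end then gene id); coordinates are
kept 1-based inclusive as in GFF3 but only the order is used. The P/A
matrix marks presence of *at least one* family member, so paralogs do
not inflate entries, and every row has presence in ≥1 genome (families
observed nowhere do not exist). The pangenome graph counts direct
adjacencies of family members per genome; strand is ignored, contigs
are linear unless flagged circular (adding the last→first closure), and
adjacent paralogs of one family produce a recorded self-loop. Edge
weight is total adjacency count over N, so conserved adjacencies have
weight 1 and repeated paralogous adjacencies can exceed 1.

## Bernoulli mixture (BinEM)

Family profiles are modeled as a K-component multivariate Bernoulli
mixture with binary centroids μ and dispersions ε ∈ [ε_floor, ½).
Defaults: constrained dispersion (one ε per component — the
per-genome-free variant is available behind a flag but over-fits),
ε_floor = 1e-4 so log densities stay finite, convergence when the
relative log-likelihood change drops below 1e-6, at most 100
iterations (10 inside K selection).

EM starts from the triangular initialization: uniform π, all-ones
centroids for the first ⌊K/2⌋ components and all-zeros after, and
dispersions ramping linearly to a peak at the central components
(ε_k = s·k/2 rising, s·(K−k+1)/2 falling, s = 1/⌈K/2⌉). The ramp is
scaled so its peak sits at the upper dispersion bound; this keeps the
persistent-like component first and the cloud-like component last from
the very first iteration, which fixes the label order (no label
switching). As a guard, components are re-sorted after convergence by
decreasing expected presence frequency.

**Dispersion ceiling.** ε is clamped at ½ − 1e-3, strictly below ½.
At ε = ½ a component's density is constant in the data, and for even K
the two central triangular-init components are exact mirrored twins
(μ all-ones vs all-zeros at the same ε = ½) that receive identical
responsibilities forever — EM can then never separate two antagonistic
shell patterns, and K selection skips the true K. The strict ceiling
breaks this symmetry deterministically; no jitter or multi-start is
needed.

Other numerical choices: densities and responsibilities are computed
in log space with log-sum-exp normalization; a centroid tie (weighted
presence mean exactly 0.5) resolves to 0; a component whose
responsibility mass vanishes is re-seeded from its triangular starting
values with a warning (this happens occasionally mid-run when a
pattern is absorbed, and is benign).

Assignment hardens posteriors only above 0.5; families with no
majority component go to the shell, the intermediate-frequency
partition, keeping the best shell component as a sub-label.

## Choosing K

For each K on a grid (3–20 by default) a 10-step EM run is scored by
ICL(K) = BIC(K) − H, with BIC = loglik − ½·dim·log F,
dim = K(N+2) constrained / K(2N+1) free, and H the total posterior
entropy. K̂ is the smallest K with ICL within
δ_ICL = 0.05·(max ICL − min ICL) of the maximum: entropy already
punishes overlapping components, and the margin keeps the selector
from buying negligible ICL gains with extra partitions. K ≥ 3 is
required for biological labels (the mixture machinery itself accepts
K = 2, used in tests).

## Graph smoothing (NEM)

Labels are given a Gibbs prior on the pangenome graph that rewards
equal labels across an edge with strength β·c·w, where β (default 2.5)
is the spatial-regularity coefficient and c = F/Σw a corrector keeping
the smoothing strength comparable across pangenome sizes. The
normalizing constant is intractable (K^F configurations), so the
E-step uses a synchronous mean-field fixed point

    t_ik ∝ π_k · p(X_i | k) · exp(β·c·Σ_{i′~i} w_{i~i′} t_{i′k}),

iterated up to 10 rounds per E-step (or until the largest posterior
change is < 1e-4). Synchronous updates were chosen over sequential
ones for determinism; the inner budget is exposed. Hub families with
more than 10 distinct neighbors are excluded from smoothing (their
edges carry little synteny signal) but are still labeled; the
corrector's denominator sums the weights of the smoothing-eligible
edges only, i.e. of the network the field actually sees. Convergence
tracks the fuzzy penalized criterion (mixture term plus ½·β·c·Σ w t·t,
computed as Σ log-sum-exp minus half the coupling); at β = 0 the
coupling vanishes and NEM reduces to BinEM *exactly* — same floats,
same labels. With soft posteriors, one smoothing step can in rare
cases flip a pair of hardened labels apart, so the
"neighbor agreement never decreases" guarantee is asserted on
frozen-density fixtures; on full pipelines the benefit is measured
statistically instead.

The prior-weight term of the Gibbs exponent is honored by keeping π_k
as the multiplicative prior factor of the mean-field update, the
equivalent mixture formulation.

## Chunked partitioning

Beyond ~500 genomes, genomes are shuffled into chunks (trailing chunk
merged into its predecessor when smaller than half a chunk; a flag
keeps it separate), each chunk is partitioned with columns, induced
graph and weights restricted to the chunk (weights renormalized by the
chunk's N), and labels are aggregated by vote. A family is decided
when a unique modal label holds at least half of the samplings where
the family was present (absolute majority; exact ties stay undecided).
Undecided families trigger fresh shuffling rounds, up to 10; anything
still undecided falls back to shell with a warning, consistent with
the global uncertain-goes-to-shell convention. Shell sub-labels
collapse to plain "shell" for voting, since sub-structure is only
identified within a run. With N ≤ chunk size the chunked path *is* the
plain pipeline. K is fixed in advance (select it on the full matrix or
a chunk).

## Rarefaction

For subset sizes n = 1…min(100, N), 30 random subsets (without
replacement) are drawn by default; each subset is freshly partitioned
— K re-selected between 3 and the full-data K, with a flag to fix it —
and the sizes of pangenome, persistent/shell/cloud, soft core/
accessory (threshold 0.95) and exact core/accessory are recorded.
Heaps' law F = κ·n^γ is fitted by nonlinear least squares
(`scipy.optimize.curve_fit`) on **all replicate points** with n ≥ 16
(smaller subsets are too variable), starting from κ₀ = mean count at
the smallest fitted size and γ₀ = 0; medians and quartiles are for
display and the IQR area, the trapezoidal integral of Q3 − Q1 over the
whole sampled range starting at n = 1. The soft-core minimum presence
⌈0.95·n⌉ is computed with a 1e-9 guard so that float round-off cannot
shift the stair step (0.95·20 must give 19).

## Synthetic pangenomes

The generator draws family profiles from a known mixture —
reference conditions π = (0.3, 0.2, 0.5), ε = (0.05, 0.3, 0.05) with
persistent/half-present-shell/cloud centroids, which yields the
asymmetric U-shaped family-frequency distribution typical of real
pangenomes — optionally in blocks of co-occurring families (members
copy the block's per-genome draw with probability ρ_block = 0.8,
emulating islands of co-transferred genes and giving the MRF signal to
exploit). Genomes are laid out as a fixed circular reference order of
persistent families, interrupted at 5 hotspot positions by the
accessory islands (block-mates adjacent, same hotspot in every
carrier), then linearized at a random per-genome origin. A degradation
step breaks adjacencies and drops genes independently, emulating
fragmented, incomplete assemblies; the benchmark "degraded island"
condition uses 300 families × 20 genomes, shell ε = 0.35, 6-family
islands, 20% fragmentation and 15% gene loss — enough noise that P/A
alone misassigns part of the shell while graph neighbors stay
informative.

What the generator does **not** emulate: sequence evolution, gene
length/intergenic structure, annotation and clustering errors upstream
of the family mapping, genome-size variation, phylogenetic correlation
between genomes (columns are exchangeable), or rearrangements of the
persistent backbone. Passing tests therefore demonstrate correctness
of the statistical machinery under the model's own assumptions, not
robustness to mis-clustered families or population structure.

Problem sizes in the test suite and the acceptance script (hundreds of
families, tens to ~1200 genomes) are chosen to exercise every code
path at desk scale; all statistical checks use fixed seeds.

## Known limitations

* ICL short runs inherit the triangular start; a multi-start option
  exists but is off by default, so pathological local optima at some K
  are conceivable.
* The mean-field criterion is not guaranteed monotone for synchronous
  updates; in practice traces are non-decreasing to ~1e-6 relative.
* High-dimensional regimes (F not ≫ N) are unsupported, as are genome
  weighting and sparse-partitioning variants.
* Genomic distance matrices for shell-structure correlation are user
  input; no sequence-based distances are computed.
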