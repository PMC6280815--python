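# Methods

## Forward model and simulation

Community dynamics follow the generalized Lotka-Volterra (gLV) system
`dx_i/dt = x_i (r_i + Σ_j a_ij x_j)`, with `a_ij` the per-capita effect of
taxon *j* on taxon *i*. Trajectories are integrated with scipy's LSODA at
`rtol=1e-8, atol=1e-10`; abundances are clipped below at a configurable
floor (default 0) and a terminal event aborts the integration if any
abundance exceeds the overflow guard (default 1e12), raising a divergence
error that names the first bad time. Numerical overflow inside a step is
treated as the same divergence condition.

## Interaction inference

The discretized gLV regression is, per taxon *i*,

```
(ln x_i(t+1) − ln x_i(t)) / Δt  ≈  r_i + Σ_j a_ij x̄_j(t)
```

with `x̄(t) = (x(t) + x(t+1))/2` the interval midpoint. Abundances are
floored at 1e-6 of the per-time-point total before taking logs, since the
log-difference is undefined at zero. Regressors are standardized
(centered, unit variance) inside the ridge solve so the penalty acts
uniformly on taxa whose abundances span orders of magnitude — without
standardization the design is dominated by near-constant columns and the
solve is badly conditioned; the intercept (growth rate) is unpenalized and
recovered on the original scale. Replicate series (e.g. one per site) over
the same taxa may be passed together, in which case their interval
equations are pooled; pooling several trajectories with distinct initial
conditions is what makes the coefficients identifiable from short series,
because a single near-equilibrium relaxation explores too few directions
of state space.

Candidate ensembles sample three knobs per candidate: ridge strength from
a log grid (1e-4 … 1, 9 points), an optional leave-one-interval subset
(only when more than 3 intervals are available), and a sparsification
threshold (0, 1%, 5% or 10% of the largest off-diagonal |a_ij|, below
which coefficients are zeroed). The first candidate is always the plain
fit. Each candidate is scored by forward-simulating it from the first
observed point and taking the mean Bray-Curtis dissimilarity between
observed and regenerated relative-abundance columns over time points
2..T; a diverging regeneration scores 1 (worst). The default ensemble
size is 1600 candidates with the best 100 entering the consensus.

The consensus keeps edge *u→v* (coefficient `a_vu`) iff a nonzero
coefficient of consistent sign occurs in at least the agreement fraction
(default 0.5) of the retained candidates; the weight is the mean over the
agreeing candidates and the sign is the sign of that mean.
Self-interactions `a_ii` are estimated — they carry the self-limitation
that stabilizes the model — but never exported as edges. Global networks
pool site networks at one rank: nodes are unioned, duplicated ordered
pairs are merged to the mean weight, and a pair whose mean is exactly zero
is sign-indeterminate and dropped with a warning.

## Topology panel and null model

Density and hub degrees are computed on the digraph; clustering (average
local), diameter, radius, Louvain communities and Newman-Girvan modularity
on the undirected unweighted projection, with eccentricities restricted to
the largest connected component (flagged) when the projection is
disconnected. Louvain runs at resolution 1.0 with seed 0 for
reproducibility. The null model is the uniform simple digraph with matched
node and edge counts, G(n, m), 100 replicates by default; each replicate's
full panel is recorded so the report can show real value vs ensemble
mean ± std per metric. Dense interaction networks (density ≈ 0.9) are
expected to sit within a few percent of their null on clustering and to
have modularity near zero; the comparison is the point of the report, not
a significance test.

## Motifs

A motif class is an isomorphism class of weakly connected digraphs without
self-loops; its canonical ID is the minimum over node permutations of the
row-major binary reading of the full adjacency matrix (9 bits for 3
nodes). Enumeration is exhaustive and vectorized: all `2^(n(n−1))`
labeled graphs are generated as bit vectors, weak connectivity is resolved
by a vectorized reachability iteration, and the canonical form is the
minimum encoding over all `n!` permutations (about 4 s for n = 5 on one
core). This yields 13 / 199 / 9364 classes for 3 / 4 / 5 nodes.
Censuses count each induced connected 3-node subgraph once, streaming
triples one anchor node at a time through a 64-entry lookup table, so
dense networks are counted exactly without materializing subgraphs;
counting is always exact (no sampling). Significance uses directed
degree-preserving double-edge swaps (10 attempted swaps per edge per
replicate, 100 replicates by default); the p-value of a class is the
fraction of randomized networks whose count reaches the observed count, so
an absent motif has p = 1. If the swap chain cannot move (e.g. a complete
digraph) the p-values are reported as 1 with a warning. Cross-rank
normalization divides each rank's count by the motif's total across ranks,
so a value of 1 marks a motif exclusive to one rank.

## Core, rare biosphere, diversity

Presence is `count > 0` with no minimum-count filter; the core is the set
of taxa present in every sample. Rare-biosphere status uses strict `<`
against the threshold (default 0.01 relative abundance) in **every**
sample; assessing the mean abundance instead is exposed as an option
(`mode="mean"`) since either reading is defensible. A taxon can be both
core and rare — the permanent rare taxa. Shannon entropy is reported in
nats so Pielou's `J = H / ln S` is exactly consistent (the base is
configurable). Chao1 is the classic `S + F1²/(2·F2)` with the standard
`S + F1(F1−1)/2` fallback when no doubletons exist. Rarefaction is the
exact hypergeometric expectation
`E[S_d] = Σ_i (1 − C(N−N_i, d)/C(N, d))`, evaluated in log space for
stability. Welch differential proportions use the two-sided Welch t-test
with Welch-Satterthwaite degrees of freedom and the inverted-t confidence
interval; groups with fewer than 2 samples get the effect estimate only
(no p, never flagged significant). The headline significance flag
compares raw p to 0.005; Benjamini-Hochberg q-values are reported
alongside but do not drive the flag.

## Synthetic study generator

The generator emulates a multi-site seasonal sampling campaign: default
3 sites × 4 time points (sample IDs `{site}{time}`, first time point
labeled dry, the rest wet).

*Abundance structure.* Per-taxon equilibrium abundances are lognormal
(σ = 1.5), split into an abundant block floored at twice the rare
threshold and a rare tail capped at 0.4× the threshold, so the realized
fraction of taxa below the threshold in every sample tracks the
`rb_target` dial (0.97 by default, matching heavy-tailed metagenomic
profiles) even after the dynamics perturb abundances. A requested
rb_target of 1 with too few taxa to sum to a full community is rejected as
impossible.

*Dynamics.* A random stable gLV model is built around that equilibrium:
self-limitation `a_ii = −d_i/x*_i` with `d_i ~ U(0.5, 1.5)`, sparse
Gaussian off-diagonal interactions (connectance 0.3) row-rescaled so the
community Jacobian at the equilibrium is strictly diagonally dominant
(hence stable), and `r = −A x*`. Each site starts from the equilibrium
jittered multiplicatively (`exp(U(−j, j))`, default j = 0.3) and is
simulated on a fine internal grid (default 40 steps over t ∈ [0, 3]) from
which the observed time points are subsampled — the observation design can
be much coarser than the dynamics. A diverging draw is retried with
off-diagonal interactions damped by half, with a warning.

*Observation.* Counts are taken at fixed depth (default 100,000):
deterministic rounding of expected counts when `noise_sd = 0` (so a system
started exactly at equilibrium yields identical columns), otherwise
Poisson draws with multiplicative lognormal noise. At least
`core_fraction` of genera are made present in every sample by flooring the
core block at one count — a rare taxon at one read out of 10^5 remains far
below the rare threshold, reproducing the permanent-rare overlap.

*Taxonomy and pathways.* Five-rank lineages are built by Dirichlet-
weighted parent assignment with rank-cardinality ratios (families ≈ 0.38
of genera, orders ≈ 0.21, classes ≈ 0.12, phyla ≈ 0.07) loosely following
observed metagenome rank counts; nesting guarantees non-increasing
cardinalities upward. Pathway fixtures assign disjoint Pfam-style domain
sets per pathway and give each sample a random domain subset.

All stage seeds derive from a single master seed through
`numpy.random.SeedSequence.spawn`, so studies are bit-reproducible.

*What the generator does not emulate.* Read-level artifacts (sequencing
error, assembly and binning noise, classifier bias), compositional closure
effects beyond fixed-depth sampling, environmental forcing of the dynamics
(the gLV parameters are time-invariant; dry/wet is a label, not a regime
change), and phylogenetic correlation of interaction strengths. Passing
tests therefore demonstrate algorithmic correctness and recoverability
under the stated model, not robustness to the full messiness of real
metagenomes.

## Validation strategy and problem sizes

Every combinatorial claim is tested against an independent oracle: motif
censuses against an O(n³) brute-force enumeration, Louvain modularity
against the exhaustive-partition optimum on ≤8-node fixtures, rarefaction
against Monte-Carlo subsampling, Welch statistics against the closed-form
computation, diameter/radius against hand-rolled BFS, consensus edges
against explicit vote counting. Parameter recovery uses noise-free studies
of 6 taxa observed at 24 time points across 3 replicate sites (initial
jitter 1.0, 48 internal steps): the best-scoring candidate must recover
the sign of every interaction above the weakest-tertile |a_ij| cutoff with
≥ 80% mean accuracy over 10 seeds. The deliberately coarse 4-point
single-site design is *not* sufficient for recovery — per-taxon regression
is underdetermined there — which is exactly why the consensus-ensemble
machinery exists for real designs and why validation uses the denser
observation grid. Pipeline tests run desk-scale configurations (tens of
genera, tens of candidates, single-digit null replicates); the analysis
constants default to the standard values (1600 candidates, top 100,
100 random networks, 100 motif randomizations, p-cuts 0.05 / 0.005,
rare threshold 0.01, display fraction 0.0005).

## Known limitations

- gLV inference from compositional counts inherits the usual closure
  caveat: normalizing by a time-varying total perturbs log-differences;
  with fixed sequencing depth the counts are compositional by
  construction. The inference is sign-scale invariant per regressor, but
  strong compositional shifts can still bias weak coefficients.
- The agreement-fraction consensus is one defensible merging rule among
  several; the ensemble weighting used by other tools is not uniquely
  defined, so the rule and its threshold are exposed in configuration.
- Degree-preserving randomization can fail to mix on very dense or very
  constrained digraphs; the census then reports uninformative p-values
  with a warning rather than sampling a biased null.
- Genus-level network inference on ~1400 taxa is computationally out of
  reach of the candidate-ensemble approach (the regression has more
  unknowns than equations by orders of magnitude); family rank and above
  are the intended operating range, mirroring practice.
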