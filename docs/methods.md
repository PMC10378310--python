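# Methods

This note documents the models, the defaults and the numerical choices behind
`spreadfs`, and what the synthetic-data conditions do and do not show.

## Networks

Three synthetic models generate the study conditions, all with N = 1000 nodes
and mean degree ⟨k⟩ = 6 at full scale:

* **BA** — preferential attachment starting from m isolated seed nodes; each
  of the n−m arriving nodes attaches m = ⟨k⟩/2 = 3 edges to distinct nodes
  with probability ∝ degree, so |E| = m(n−m) (2991 at N = 1000).  Draws are
  conditioned on minimum degree ≥ m: in a few percent of draws one of the
  zero-degree seed nodes never attracts later attachments and ends with
  degree < m, which would break the model's characteristic uniform k-shell
  index (= m); such draws are regenerated with an incremented seed.  The edge
  count is unaffected.
* **ER** — G(n, p) with p = ⟨k⟩/(n−1).  A sparse draw is almost never
  connected in full; the largest connected component (≈ 99%+ of nodes at
  ⟨k⟩ = 6) is kept and re-indexed, because closeness and the SIR dynamics
  need a connected graph.  The realised size is recorded in the network name.
* **WS** — ring lattice of degree k rewired with probability p = 0.2;
  rewiring conserves |E| = nk/2 but can rarely disconnect the graph, in which
  case the draw is regenerated with an incremented seed.

Real networks are read from whitespace-separated edge lists; self-loops and
duplicate rows are dropped with a logged count, tokens are densified to
0-based ids (numeric-aware, so 0-based numeric files round-trip exactly), and
a disconnected file is reduced to its largest component.

## Centralities

The feature table holds, per node: K, Ksum, K2sum, KS, C, B, CC, EC, PR (see
README for definitions).  Numerical conventions:

* **Ω₂(i)** (for K2sum) is the within-two-hops neighbourhood — nodes at
  shortest-path distance 1 or 2, i excluded — the standard reading of
  "two-hop neighbourhood"; an `exact_two_hop` switch restricts it to
  distance exactly 2.
* **Betweenness** is left as raw path counts (endpoints excluded).  Scale is
  irrelevant downstream because every classifier standardises features, and
  raw counts are the natural magnitudes of the measure.
* **PageRank** uses damping α = 0.85 and uniform teleport (1−α)/N — the
  conventional values; they are exposed in `CentralityConfig`.
* **Eigenvector centrality** comes from power iteration (tol 1e−10, max 10⁴
  iterations); when the spectrum defeats power iteration (bipartite-like
  graphs with eigenvalues ±λ₁) a dense symmetric eigensolver supplies the
  leading eigenvector.  Entries are made non-negative and normalised to unit
  Euclidean norm.
* Columns with variance < 1e−12 are dropped as non-informative; this is what
  removes KS on BA graphs (uniform shell index) and leaves 8 features there.

## SIR dynamics, threshold and labels

The dynamics are synchronous discrete-time SIR on the static graph: at each
step every infectious node attempts each susceptible neighbour independently
with probability β, then recovers with probability μ.  μ = 1 by default, so a
node is infectious for exactly one step, and the control parameter is
λ = β/μ.  The outbreak size ρ ∈ [1/N, 1] is the final recovered fraction.

The epidemic threshold is estimated by scanning λ and maximising the
variability Δ(λ) = √(⟨ρ²⟩ − ⟨ρ⟩²)/⟨ρ⟩ — the relative standard deviation of
ρ over runs seeded at uniformly random nodes, which peaks at criticality.
Defaults: 40 evenly spaced grid points in (0, 0.25] and 300 runs per point;
ties in Δ resolve to the smaller λ.  As a sanity anchor, the estimate sits
within a factor of two of the degree-based mean-field value
⟨k⟩/(⟨k²⟩ − ⟨k⟩) on the graphs tested.

Node influence is ⟨ρ_i⟩, the mean over `runs` simulations seeded at node i
(1000 at full scale, 200 in the reduced profile).  Every (node, run) pair
draws from an RNG substream keyed by (master_seed, node, run), so scores are
reproducible and independent of execution order.  The top round-half-up(f·N)
nodes by ⟨ρ_i⟩ are labelled +1; score ties break by descending degree, then
ascending id, making labels deterministic.

## Two-phase selection

**Phase 1 (FFS).**  k = 10 balanced replicates are drawn by undersampling the
majority class *without* replacement (duplicated support vectors would
distort SVM margins; a with-replacement flag exists).  On each replicate,
recursive feature elimination runs a linear SVM (C = 1) with stratified
10-fold cross-validation; features are standardised per fold on the training
folds only, importance is the summed |w| across folds, the CV score is the
mean positive-class F1, the least important feature is removed each round
(ties: higher column index), and the best subset is the survivors at the
score-maximising size (ties: smaller size).  If a class has fewer members
than folds, the fold count drops to the class size; fewer than 2 minority
members is a hard error (the selection genuinely cannot run).  Voting keeps
features with frequency strictly above ε = 0.5 across the k best subsets;
an empty result falls back to the maximum-frequency features.  k, ε, C and
the CV metric are not fixed by the study design; the defaults above are
exposed in `SelectionConfig`.

**Phase 2 (SFS).**  F* features are correlated pairwise (Pearson r), then
agglomerated into exactly two clusters by repeatedly merging the cluster
pair with the largest cross-pair |r| (single linkage on 1 − |r|; ties
resolve to the first pair in canonical column order, so the result is
deterministic).  ReliefF (k = 10 nearest hits/misses, Euclidean distance on
standardised features, miss contributions weighted by class priors) runs on
the full unbalanced training split — phase 2 is a filter and does no
resampling.  With γ = ⌊|F*|/2⌋, each cluster contributes its maximal-ReliefF
main feature (ties: higher phase-1 vote frequency, then canonical order) and,
if strictly larger than γ, a supplementary feature minimising |r| with the
main.  "2 clusters" and the γ rule are vacuous for |F*| ≤ 2, so the phase is
bypassed and F** = F*.

## Evaluation harness

Splits are stratified 70/30 — at f = 5% an unstratified test draw can lose
every positive and leave precision/recall undefined.  The evaluation
classifier is a linear SVM with class weights inverse to class frequency on
the raw training split (switchable to unweighted).  Contrast methods: each
single centrality, the full set, RFE-CV on the raw imbalanced split
("Imbalanced"), and ReliefF- and vote-frequency-rankings of F* truncated to
|F**| so that only the phase-2 criterion differs.  Ablations evaluate F*
alone and the phase-2 procedure applied to the full feature set.  Modal
subsets are taken per network over repeats and voted across networks per
model; ties prefer the smaller subset, then canonical column order.

## Problem sizes

Tests and the reproduction script use a reduced profile — N = 300, 200 SIR
runs per node, 300 runs per threshold grid point, 10 split repeats — chosen
so the full code path (including the O(N·runs) labelling loop, the dominant
cost) runs in minutes while keeping Monte-Carlo standard errors small
relative to the effects asserted.  The full-scale profile (N = 1000, 1000
runs, 30 repeats, 10 networks per model) is available as
`ExperimentConfig.full_scale()`.

## What the synthetic conditions show — and don't

The planted-feature datasets (one margin-separated informative column, a
verbatim duplicate, noise columns) verify the selection mechanics: the vote
concentrates on informative features, duplicates are split by the SVM weight
tie-break and excluded, noise stays out.  Real centrality columns are
mutually correlated in graded ways, so recovery there is a statement about
redundancy structure, not about any single "true" feature.  Synthetic BA/ER/
WS networks lack degree-degree correlations, community structure and
weighted/temporal contacts of real contact networks; results transfer at the
level of which *kinds* of centralities matter, not exact subsets.

## Known limitations

* Labels inherit Monte-Carlo noise near the threshold (λ ≈ λc), where
  outbreak sizes are maximally variable; classifier scores there fluctuate
  more across repeats.
* The exact final subsets are instance- and RNG-dependent (the repeat-level
  mode stabilises but does not eliminate this); properties, sizes and metric
  comparisons are the reproducible quantities.
* Only undirected, unweighted, static, connected graphs are supported, and
  only SIR dynamics with per-step recovery; no SEIR/incubation, no
  continuous-time dynamics.
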