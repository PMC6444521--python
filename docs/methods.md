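# Methods

## Data model

A cohort is a stack of T weighted structural connectivity matrices
`A_s ∈ R^{N×N}` (symmetric, nonnegative, zero diagonal — streamline-density-
like units) over a shared node table giving, per brain area, a centroid in
mm, a hemisphere label (L/R) and optionally a cognitive-system (RSN) label.
The node table is the single source of truth for node order; matrices
without headers are assumed to follow it. Edges are unordered node pairs
{i, j}, i < j; matrices are views. Validation is fail-loud: asymmetry beyond
1e-8, negative entries, or a nonzero diagonal are rejected (the diagonal can
be zeroed under an explicit flag). Connection length is the Euclidean
distance between centroids — a first-order proxy for curvilinear fiber
length.

## Group-network construction

All methods operate on the consensus matrix `C_ij = (1/T) Σ_s [A_ijs > 0]`.
Zero-consensus pairs are never retainable, even at τ = 0: retention is
always among edges expressed by at least one subject.

**Simple average.** Edge set `{C_ij > 0}`; weight = mean of `A_ijs` over the
expressing subjects only. No weight remapping.

**Uniform threshold (`tau_fixed`).** Keep `C_ij ≥ τ`, default τ = 0.5,
applied identically in both hemisphere classes (a uniform τ is
class-independent by definition).

**Density-matched threshold (`tau_avg`).** Separately for intra- and
inter-hemispheric pairs, the target edge count is
`M_k = round(mean subject edge count in class k)`. τ(k) is found by an
exact sweep over the distinct positive consensus values in the class,
minimizing `|#retained − M_k|`; ties are resolved toward the denser network
(erring toward inclusion of consistent edges). Because consensus takes at
most T distinct values, the achieved count can differ from the target by
more than one edge when many edges tie at the pivotal consensus level; the
provenance records both numbers.

**Distance-dependent threshold (`distance`).** Per class, the expressed-edge
lengths of all subjects are pooled *with per-subject multiplicity* (an edge
expressed by k subjects contributes k copies — the most direct reading of
combining subjects' edge lists; the choice is isolated in
`pooled_edge_lengths` for easy flipping). The pooled multiset is cut into
`M_k` equal-occupancy bins whose boundaries are its 0, 1/M, …, 1 quantiles.
Bins are processed short → long; in each bin the candidate set is every
not-yet-selected expressed pair of the class whose length falls in the
closed bin interval, and the candidate with maximal consensus is selected.
Ties go to the larger simple-average weight, residual ties to lexicographic
pair order, making the procedure fully deterministic. Empty bins are skipped
and counted in the provenance (the achieved density may fall below the
target by that amount). By construction the selected edge-length
distribution tracks the pooled subject distribution, while within each
length stratum the most consistently expressed connection wins.

**Two-step weight assignment** (all three thresholding methods). Retained
edges first carry their simple-average weight; they are then ranked
(ascending, ties by pair order) and rank r of M is reassigned the value at
quantile `(r−1)/(M−1)` of the sorted pooled positive subject weights, by
linear interpolation at fractional position `q·(P−1)`. This convention makes
two cases exact identities: when M = P the group weights are exactly the
sorted pooled weights, and for a cohort of identical subjects each edge
recovers the subject's own weight. A single retained edge receives the
pooled median. Rank order is preserved and the retained min/max equal the
pooled extremes, so the group-vs-pooled weight KS statistic is bounded by
`1/M + 1/P`.

## Network statistics

Binary and weighted analogs of the standard battery, on the conventions
used throughout network neuroscience:

- degree / strength `k_i = Σ_j A_ij`; total weight `2m = Σ_i k_i`;
- clustering `c_i = 2 t_i / (k_i (k_i − 1))` with `c_i = 0` for `k_i < 2`;
  the default counts binary triangles, a flag switches to the
  geometric-mean (Onnela) weighted form scaled by the maximum weight;
- weighted shortest paths use the reciprocal transform `L_ij = 1/W_ij`
  (zero-weight edges are an error under the transform); characteristic path
  length is the mean over pairs (infinite when disconnected, with a
  finite-pair mean also reported), diameter the largest finite entry,
  efficiency the mean of `1/D_ij` with disconnected pairs contributing 0;
- betweenness is normalized over ordered pairs by `(N−1)(N−2)`, so the
  center of a 3-path scores exactly 1;
- modularity `Q(γ) = (1/2m) Σ_{σi=σj} [A_ij − γ k_i k_j / 2m]`, null term
  including i = j — the convention under which two disconnected equal
  cliques score Q = 0.5 at γ = 1. Q(γ) is maximized by seeded Louvain runs,
  each polished by a greedy refinement that relocates single nodes
  (including splitting off singletons) and merges whole communities until
  no move improves Q; each repetition also refines a random initial
  partition, because Louvain's greedy first phase can lock nodes into pairs
  it can never split. The best-Q partition over repetitions is returned.
  On 200 random graphs with N ≤ 8 this matches exhaustive partition search
  exactly. The default sweep grid is γ = 0.7 … 2.1 in steps of 0.1; the
  measures CLI defaults to 100 repetitions per γ, while the evaluation
  helpers default to 20 (and some tests fewer) — at the cohort sizes used
  here the best-of-20 Q is already stable to ~1e-3;
- participation `p_i = 1 − Σ_σ (κ_iσ/k_i)²` against a γ = 1 Louvain
  partition by default (the partition feeding participation is a parameter);
- degree assortativity is the Pearson correlation of endpoint degrees over
  edges; undefined (NaN with a warning) on regular graphs.

## Evaluation battery

**Local distributions.** For each measure (degree, strength, clustering,
betweenness, edge length) the group network's distribution is compared with
every subject's by the two-sample KS statistic. Methods are contrasted by a
two-sided Wilcoxon signed-rank test on the per-subject KS values,
Bonferroni-corrected over measures (the nonparametric choice matches the
bounded KS scale). With one subject the contrast is flagged untestable.

**Global z-scores.** Each global statistic of the group network is z-scored
against the subject-level distribution; zero subject variance gives a
flagged NaN.

**System densities.** Inter-/intra-RSN connection density uses binary edge
counts over possible pairs (diagonal: `n_a(n_a−1)/2`), with a mean-weight
variant behind a flag; the subject reference is the elementwise average of
per-subject density matrices. Group-vs-subject agreement is the Pearson r
over the upper triangle plus diagonal. The within-minus-between density
difference between two group networks is tested against a null that
permutes the node order of each network independently and re-aggregates
under the fixed labels; p-values use the add-one estimator. When the two
networks are built from the *same* cohort their fluctuations are positively
correlated and this null is conservative (p stochastically above uniform);
for networks from independent cohorts the test is calibrated — the
acceptance suite measures a 3.6–5.6% rejection rate at α = 0.05 over 500
label-free runs.

**Hub redistribution.** Betweenness, degree, clustering and participation
are rank-transformed within each network (average ranks on ties); per-node
differences are aggregated by system and z-scored against a node→system
label-permutation null (a spatially naive approximation — no surface
geometry is available for spin-style nulls), with two-sided permutation
p-values corrected by Benjamini–Hochberg FDR at 5% across systems. When a
network is compared with itself all rank differences are zero and the null
is degenerate; z is defined as 0 in that case. Participation for both
networks uses the same Louvain seed so identical networks get identical
partitions.

## Synthetic cohorts

The generator reproduces the statistical structure the distance-dependent
method exploits, without any MRI machinery. Nodes are placed uniformly in
two blocks of extent 60 × 80 × 60 mm separated by a 4 mm inter-hemispheric
gap (roughly brain-sized). The population edge probability is
`π_ij = min(1, p0 · e^{−d_ij/δ})` with p0 = 0.7 and δ = 35 mm, boosted by
`(1 + β)` for same-system pairs when systems are planted; each subject
draws edges i.i.d. Bernoulli(π). Because subjects draw from a common π, the
expected consensus equals π and decays with distance (empirical Spearman
ρ(C, d) ≈ −0.78 at N = 200, T = 20) — so uniform thresholding's short-range
bias emerges by construction, not by fiat. Expressed edges get weights
`e^{−d/λ} · LogNormal(0, 0.5)` with λ = 60 mm: positive, heavy-tailed,
distance-decaying, as streamline densities are. Presets: `small`
(N = 60, T = 10), `default` (N = 200, T = 20; mean subject density ≈ 0.15,
inside the intended 0.02–0.20 band), `modular` (N = 140, T = 20, seven
planted systems, β = 0.5). Subjects are i.i.d. by default; a
`centroid_jitter` option perturbs per-subject geometry for robustness
checks.

What the generator does *not* emulate: tractography artifacts (gyral bias,
crossing-fiber failures), hemispheric asymmetries, spatially autocorrelated
system assignments, or subject-level covariates. Passing tests show the
methods behave as designed under distance-decaying consensus; they do not
certify performance on any particular empirical cohort.

## Numerical choices and degenerate inputs

- Quantiles everywhere use the sorted-value linear interpolation at
  position `q·(n−1)` (numpy default), chosen so the identity cases above
  are exact.
- Bin intervals are closed on both sides; an edge lying exactly on a shared
  boundary is a candidate for both bins but selectable once.
- All randomness flows through seeded `numpy` generators; the CLI forks one
  global seed into named substreams (simulation, Louvain, permutations) so
  stages are independently reproducible and reruns are byte-identical.
- Degenerate cases: a class with no expressed edges contributes nothing
  (warning); all-equal pooled lengths give a flagged degenerate binning;
  empty graphs are rejected by modularity; regular graphs give NaN
  assortativity; disconnected graphs report infinite path length alongside
  the finite-pair mean.
- Problem sizes in the test-suite and acceptance script (N = 40–200,
  T = 5–20, 200–10000 permutations, 500 calibration runs) were chosen as
  the smallest at which the cohort-level properties of interest are stable.

## Known limitations

- Consensus-based thresholding presumes sparse subject matrices; dense
  inputs (probabilistic tractography, functional connectivity) make the
  consensus saturate and are out of scope.
- Weight-based (rather than consensus-based) thresholding of the simple
  average is not implemented.
- Euclidean distance underestimates true fiber length for curved tracts;
  all distance-dependent machinery accepts any precomputed symmetric
  distance matrix if a better proxy is available.
- The hub-analysis null ignores spatial autocorrelation of system labels.
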