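# Methods

This note documents the models, the synthetic study conditions, the
numerical conventions, and the design choices behind `dimflow`, in the
spirit of a methods section a maintainer can audit.

## Paired edge comparison

The unit of comparison is the directed type-to-type connection, with its
synapse count split into left- and right-hemisphere contributions by the
source neuron's soma side (entry-nerve side for sensory neurons; medial
sources inherit the target's side; medial-to-medial weights are halved
onto both sides).  The two hemispheres serve as within-animal replicates,
so each sex contributes n = 2 observations per edge.

**Scale factor.**  Synapse counts differ systematically between datasets
for technical reasons, so male weights are multiplied by a factor s before
comparison.  s is estimated from matched edges above the noise thresholds
in both sexes.  The default estimator works in log space: the geometric
mean of the female/male weight ratio, i.e. the intercept of the unit-slope
principal axis of the (log male, log female) cloud.  A raw-space variant
(component ratio of the first principal axis of the centered weight cloud)
is available as `space="raw"`.  The log-space default is deliberate: edge
weights span four orders of magnitude and the strongest edges are exactly
where dimorphic effects concentrate, so the raw-space first principal axis
can be tilted by the dimorphic cloud (errors up to a factor of ~2 in
simulation), while the log-space estimator recovers the factor to ~1–3%.

**t statistic and p-values.**  t = (x̄_m − x̄_f)/s_p with s = |L − R|/√2
per sex (the n = 2 sample SD) and s_p = √((s_m² + s_f²)/2).  With zero
pooled SD the statistic is ±∞ for unequal means (p = 0) and 0 for equal
means (p = 1).  Two-sided p-values use Student's t with 3 degrees of
freedom; a symmetric alternative is the right model because either sex may
have the stronger connection.  BH adjustment runs over the tested
(above-noise) set only — thresholding precedes testing.

**Noise thresholds.**  Weak edges are unreliable across datasets: in the
default synthetic regime ~62% of weight-1 male edges are entirely absent
from the female dataset.  Classification uses fixed per-dataset
reliability thresholds, default 11 (male, the denser dataset) and 8
(female) raw synapses; an edge below both is *noisy* and excluded, while
an edge above threshold in one sex and absent in the other is a legitimate
dimorphism candidate.  A persistence-based estimator is also provided (the
smallest weight at which ≥90% of edges are also present in the other
dataset) and is validated against direct counting; under pure Poisson
hemisphere noise it returns much lower thresholds (2–3) than the fixed
defaults, because counting noise alone makes persistence recover quickly.
The fixed defaults are the operative choice: they keep degenerate
low-count edges (both hemispheres equal by chance, giving infinite t) out
of the tested set, which is what controls the empirical false discovery
rate against planted truth.

**Classification and reconciliation.**  Dimorphic ⟺ q ≤ 0.1 and relative
difference ≥ 30%, with rel_diff = |x̄_m − x̄_f|/max(x̄_m, x̄_f) so the
criterion is symmetric in the sexes (the denominator choice is ours).
Edge calls are then corrected with type-level labels: any non-noisy edge
touching a sex-specific type becomes dimorphic; any dimorphic call between
two isomorphic types is reset to isomorphic.  *Secondarily dimorphic*
types are morphologically isomorphic types whose dimorphic in- or
out-synapse fraction exceeds a configurable cutoff (default 0: any
dimorphic connection qualifies).

## Synthetic paired connectomes

The generator emulates the regime the statistics must survive, not any
particular brain:

- **Weights.**  Latent type-to-type weights are LogNormal(μ = −0.5,
  σ = 3.25): heavily right-skewed, median ≪ mean, with a large mass of
  sub-single-synapse edges whose observed counts flicker between datasets.
  The parametric form is a modelling choice; the calibrated targets are the
  stylized facts (skew; ~60% of weight-1 edges absent from the opposite
  dataset; persistence thresholds of the two datasets within a few
  synapses of each other).
- **Scale.**  Male weights are the latent weights times 1.72 (so the
  factor mapping male onto female is 0.5814).
- **Hemispheres.**  Left/right weights are independent Poisson draws
  around half the dataset-level mean (a log-normal alternative and a
  noise-off mode exist for sensitivity tests).
- **Planted dimorphism.**  5% of matched edges, restricted to edges with
  latent weight ≥ 40, receive a female-side fold change drawn uniformly
  from [2, 4], half upward and half downward (so scale estimation is not
  biased).  The weight floor and the fold mixture are power-driven study
  conditions: with two hemisphere replicates and a 3-df t test, an exactly
  2-fold change on a 20-synapse edge is statistically invisible (power
  ~25%), so planting effects where no test could find them would only
  measure the generator, not the method.  A consequence worth noting:
  planted dimorphic edges are among the strongest edges, so the dimorphic
  *synapse* fraction is much larger than the dimorphic *edge* fraction in
  the synthetic summaries.
- **Type labels.**  Every planted edge touches at least one
  morphologically dimorphic type (labels assigned greedily so the
  dimorphic set stays compact), sex-specific types exist in one dataset
  only with their own edges, and fru/dsx expression flags are enriched
  8-fold in non-isomorphic types.

What this generator does *not* emulate: spatial synapse positions,
morphology, correlated biological variation between hemispheres, or
cross-dataset overdispersion beyond counting noise.  Passing recovery
tests here therefore shows the pipeline is correct and calibrated under
counting noise; on real data, additional biological variance would lower
power and raise the empirical FDR of the uncorrected edge-level calls,
which is exactly what the type-label reconciliation step is for.

## Sensorimotor flow

Capacities are input-normalized weights rounded half-up to integers in
[0, 10000] (values below 0.00005 vanish); pseudo-source/sink edges carry
capacity 10000; inputs to sources and outputs from sinks are removed after
normalization.  Max flow uses Dinic's algorithm on integer capacities, so
conservation is exact in integer units and the value is bounded by
min(#sources, #sinks).  When multiple maximum flows exist the particular
assignment is solver-dependent; all tests assert assignment-independent
quantities (value, conservation, the layering residual) plus
planted-route recovery statistically.

Per-neuron through-flow is the node's inflow under the assignment.
Sensory preference for modality m is the mean through-flow over all
domains under source m (motor preference analogously); specificity is
max/sum of the preference vector; combined specificity is max/sum over all
pairings.  Utilization is the mean over pairings of through-flow divided
by node capacity, with node capacity = min(total in-capacity, total
out-capacity) on the input-normalized graph (sources/sinks count their
unit pseudo-capacity); the denominator convention is ours.

Pseudo-layers solve l(F − I) = −1·F by direct linear solve (least-squares
fallback for singular systems), where F is the column-input-normalized
flow adjacency; any flow cycles are cancelled first so F is acyclic, and
no-inflow nodes sit at layer 0.  On a chain the layers are exact hop
counts; in general each node is one unit deeper than the flow-weighted
mean of its inputs (residual ≤ 1e-8 enforced in tests).

The synthetic routing graph is a five-layer DAG (sensory → brain
interneurons → neck connective → cord interneurons → motor) with dedicated
strong chains for each planted (modality, domain) route plus sparse weak
background edges; edges only run to strictly deeper layers, so it is
acyclic by construction (a feedback option exists for robustness tests).
Real nervous systems have feedback; the DAG keeps brute-force oracles
exact while exercising identical code paths.

## Clustering and behaviour compatibility

The embedding is UMAP (20 neighbours, min_dist 0, Euclidean), deterministic
under a fixed seed, and pluggable (`method="pca"` for a fast linear
substitute); k-means sweeps k ∈ [2, 60] and keeps the silhouette-optimal
partition, with silhouette computed on the embedding coordinates and ties
broken toward smaller k.  Cluster labels are renumbered by average-linkage
leaf order on cosine distances of concatenated in+out cluster
connectivity; all-zero clusters are treated as mutually identical.  The
seven behaviour matrices implement the rule list verbatim over the default
modality/domain vocabulary, with "legs" = {front, middle, hind leg} and
broad-sense mechanosensation = {mechanosensory, tactile, proprioceptive};
a missing referenced label raises a configuration error.  Compatibility
scores L1-normalize both factors, making them invariant to positive
rescaling of either.

## Traversal

Input fractions are recomputed each round against the full fixed
input-normalized graph; only the traversed pool changes.  Per-neuron,
per-round draws are independent Bernoulli with probability
min(1, f/threshold); threshold → 0 degenerates to breadth-first search.
Layers are 1-based (seeds = layer 1).  Means and SDs are over the runs in
which a neuron was reached; the unreached fraction is reported separately
rather than imputed.  The 10,000 default repeats are simulated as one
batched matrix recurrence, so they cost seconds.

## Enrichment

Cluster p-values are exact hypergeometric tails P(X ≥ k) (no normal
approximation; validated against direct combinatorial summation for
N ≤ 60), computed for every cluster at every hierarchy level, with one BH
step across the whole hierarchy and enrichment declared at q ≤ α = 0.01.
The population is all categorized types (configurable).  In the
within-community synapse fraction, a boundary synapse counts once per
incident cluster; the per-level mean is synapse-weighted.  Coarsening a
nested hierarchy can only merge communities, so the mean within-community
fraction is non-decreasing across levels.

The hierarchy generator plants enrichment by routing a fixed share of
non-isomorphic types (odds 25:1 per enriched cluster, four enriched
clusters by default) into the designated clusters, dealing them
round-robin so all planted clusters are comparably loaded, and merging
enriched clusters with each other first so enrichment persists at coarser
levels.

## Problem sizes and determinism

Default sizes — 200 types / 5,000 matched edges for the paired comparison,
~200 nodes for the routing graph, 400 types / 3 levels for the hierarchy —
are chosen so every recovery analysis runs in seconds on one CPU while
leaving all statistical regimes (noise-dominated weak edges, powered
strong edges) populated.  All generators and pipeline stages are pure
functions of their seed; the CLI derives per-stage seeds by hashing the
global seed with the stage name, and identical config + seed reproduces
byte-identical outputs (verified by digest in the run manifest).

## Known limitations

- The persistence-estimated noise thresholds and the fixed defaults
  disagree under pure Poisson noise (see above); both are exposed, and the
  choice matters for edge-level FDR.
- Max-flow throughflow, preferences and layers depend on which maximum
  flow the solver returns when several exist.
- The behaviour annotations used in the compatibility AUC are derived from
  planted routes through the same rule matrices, so the AUC measures
  recovery of routing structure through the clustering, not an independent
  behavioural ground truth.
- Traversal is sign-blind (no inhibition) by design.
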