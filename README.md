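# dimflow

Graph analyses for paired male/female connectomes: detection of sexually
dimorphic connections, sensory-to-motor maximum-flow routing, flow-based
clustering with behavioural compatibility scoring, probabilistic traversal
layering, and hypergeometric cluster enrichment — exercised end-to-end on
synthetic connectome graphs with planted ground truth.

## Who this is for

Connectomics groups comparing two whole-CNS reconstructions of the same
species (e.g. a male and a female fly brain) face a common set of
questions: which type-to-type connections differ between the datasets
beyond technical noise, how information routes from each sensory modality
to each motor domain, and whether dimorphic cell types concentrate in
particular network communities.  `dimflow` implements that analysis stack
as a tested library plus a pipeline, with synthetic generators that let
every stage be validated against known ground truth before touching real
data.

## The statistics at the core

**Dimorphic edges.**  Connection weights (synapse counts) are split into
left/right hemisphere contributions, giving two within-animal replicates
per sex.  After rescaling the male weights by a cross-dataset scale factor
s (estimated from the principal axis of the matched weight cloud; males
have systematically more synapses), each edge A→B gets

t_AB = (x̄_m − x̄_f) / s_p,  s_p = √((s_m² + s_f²)/2),

where x̄ is the two-hemisphere mean and s = |left − right|/√2 the per-sex
SD.  Two-sided p-values use a t distribution with 3 degrees of freedom and
are Benjamini–Hochberg adjusted over all tested edges.  Edges below a
per-dataset reliability threshold in both sexes are *noisy* and excluded;
an edge is *dimorphic* iff q ≤ 0.1 and the relative difference
|x̄_m − x̄_f| / max(x̄_m, x̄_f) is at least 30%.  Edge calls are then
reconciled with type-level labels (edges touching sex-specific types are
dimorphic by definition; calls between two isomorphic types are treated as
variability).

**Sensorimotor flow.**  For each (sensory modality, motor domain) pair,
input-normalized connectivity (each edge's share of its target's total
input) becomes edge capacities in [0, 1], discretized to integers in
[0, 10000]; a pseudo-source feeds all sources and all sinks feed a
pseudo-sink through unit-capacity edges.  Exact max flow (Dinic's
algorithm) is renormalized to [0, 1].  Per neuron: mean through-flow per
modality/domain (preference), max/sum concentration (specificity), and a
pseudo-layering l solving (l+1)F = l on the input-normalized flow DAG F.

**Clusters and behaviour.**  Neck-connective types are embedded (UMAP, 20
neighbours, min_dist 0) by their flow profiles, k-means partitioned at the
silhouette-optimal k ∈ [2, 60], and scored against seven rule-based binary
modality×domain compatibility matrices (feeding, flight, grooming, escape,
walking, reproduction, VNC sensation) via ⟨L1-normalized flow,
L1-normalized rule⟩.

**Traversal layering.**  From a sensory seed pool, each round every
untraversed neuron with traversed-input fraction f joins independently
with probability min(1, f/0.3); the mean layer over 10,000 runs measures
distance from the sensory periphery.

**Enrichment.**  For nested community partitions, each cluster's
probability of holding at least its observed number of non-isomorphic
types is the exact hypergeometric tail, BH-adjusted jointly across the
hierarchy at α = 0.01.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (share one `--seed`; run in order):

```bash
python analysis/01_simulate_connectomes.py --seed 0
python analysis/02_dimorphic_edges.py      --seed 0
python analysis/03_sensorimotor_flow.py    --seed 0
```

which prints

```
planted 250 dimorphic edges among 5000 matched edges; true male->female scale factor 0.5814
estimated scale factor: 0.5840 (generator: 0.5814)
1876 noisy edges excluded; 1291 tested
dimorphic edge fraction: male 0.211, female 0.212
...
mean max-flow value: planted routes 2.889, background pairings 0.688
route interneurons whose top sensory preference matches their planted modality: 71/72
```

The generator planted a male/female weight ratio of 1.72 (so the true
factor mapping male onto female weights is 1/1.72 = 0.5814); the pipeline
recovers 0.5840 from the data alone.  Of 5,000 matched edges, the ~1,900
weakest are discarded as unreliable, and the dimorphic calls among the
rest recover the planted edges (the reported 21% of above-noise edges is
dominated by the planted 250, which sit on strong edges).  Planted
sensory→motor routes carry 4× the max flow of background pairings and are
recovered as the top modality preference for 71 of 72 route interneurons.

The same stages are available as a single CLI
(`dimflow all --out run_dir --seed 0`, with YAML config overrides) whose
manifest records parameters, derived per-stage seeds and output digests;
identical config + seed reproduces byte-identical outputs.

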