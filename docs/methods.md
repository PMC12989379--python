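# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions that make runs reproducible.

## Synthetic multi-omics cohorts

The generator emulates a cohort of patients with matched, already
normalized profiles in three layers: methylation beta values in [0,1],
and RNA / protein expression on a log2 scale. It does **not** model
read-level data, platform or batch effects, probe-to-gene mapping
ambiguity, or heavy-tailed expression noise; passing tests therefore
demonstrate that the *procedure* behaves as designed under its own
assumptions, not that any particular real cohort will yield the same
feature lists or cluster counts.

Design. Group sizes default to the two clinical designs of the emulated
study: 35 non-recurrent vs 55 recurrent patients, or 37/37/16 patients
of WHO grades 1–3. The inactive clinical variable is filled with a
fixed balanced pattern carrying no signal. Per-layer feature counts
default to 2000 CpGs / 1500 genes / 600 proteins — a cohort scaled down
roughly tenfold from genome-wide sizes so a full pipeline run takes
seconds while keeping the multiple-testing behaviour of thousands of
features.

Background features. Independent Gaussians around a per-feature
baseline (methylation: logit of a Uniform(0.2, 0.8) baseline beta;
RNA: Uniform(4, 10) log2 units; protein: Uniform(−1, 1) log2 ratios)
with per-layer residual SD (0.5 logit units for methylation, 1.0 for
RNA and protein). Methylation is generated on the logit scale and
squashed through the logistic function, which guarantees [0,1] without
truncation artifacts and keeps the values approximately normal where
the downstream t-tests operate.

Planted differential features (30 per layer by default, alternating
sign) receive a group-mean shift at the scale of the default selection
thresholds: Δβ 0.18, RNA log2FC 1.7, protein log2FC 1.0. In the
three-group design the shift grows linearly with grade so both
adjacent-grade contrasts see the configured effect. The methylation
shift is applied on the logit scale as logit(β₀+Δ) − logit(β₀), so the
realized group-mean Δβ is approximate (the logistic squash biases it by
a few hundredths at SD 0.5); tests budget for this. Effects at the
threshold scale give ≈50% recall with ≈100% precision — a deliberate
choice: it exercises both sides of the filter rather than making
selection trivially easy.

Planted modules (5 modules × 5 features per layer at loading λ = 0.9 by
default) share **one** standard-normal latent factor per module per
sample across all three layers: `value = λ·f + √(1−λ²)·ε`. Pairwise
within-module correlation is λ² = 0.81 in population, slightly
attenuated in the methylation layer by the logistic squash. A single
cross-layer factor is essential: it is what plants *inter-omic* edges
for the connectome to find. `module_mode="within_layer"` draws
independent per-layer factors instead and serves as the negative
control in the connectivity contrast. Differential and module features
occupy disjoint index blocks by default so recovery tests are
unconfounded; `overlap_diff_modules=True` makes the differential
features double as module members, the configuration used by the
demonstration drivers because it mirrors real cohorts (the features
that differ with outcome are the ones that co-vary across layers).

Reproducibility: one `SeedSequence` per dataset with deterministic
per-layer children; identical config + seed is bit-identical.
An optional `missing_rate` masks cells at random with NaN; the reader's
drop-feature policy handles them.

## Differential selection

Welch's unequal-variance t-test is the default (group sizes 35 vs 55
and 37 vs 16 are unbalanced; the pooled test is available behind
`pooled=True`). Filtering uses the raw two-sided p-value plus a
layer-scale effect threshold, with no multiple-testing correction by
default — matching the raw per-layer filters of the emulated analysis;
`adjust="bh"` switches the filter to Benjamini–Hochberg-adjusted p.

Effect ("fold change") semantics are a documented assumption: the
methylation threshold (0.18–0.2) is read as |Δβ| — implausible as a
ratio of betas, canonical as a beta difference — and RNA/protein
thresholds as |log2FC| on already-log2 data (so protein "1" = 2-fold);
`fc_mode="ratio"` instead interprets the configured number as a linear
ratio and compares |effect| to log2(FC). Features constant in both
groups (detected by exact equality, since the float variance of a
constant column can be a nonzero rounding residue) are recorded with
t = 0, p = 1, `passes=False` and a flag. Grade analysis runs G1-vs-G2
and G2-vs-G3 separately; the grade feature set is the union of passers
(configurable to intersection — the published combined counts do not
disambiguate the rule, so both are exposed).

## Connectome construction

Pearson correlations are computed over **all** cohort samples (not per
clinical group) across the namespaced union of selected features;
per-group networks can be built by subsetting samples upstream.
Thresholding applies to |r|, keeping negative correlations as edges
with a sign attribute: methylation–expression feature pairs are
biologically anticorrelated, and a signed-only rule (available as
`signed_only=True`) would delete exactly the cross-layer links the
analysis is about. Each edge carries r and its null p-value from
t = r√(n−2)/√(1−r²) on n−2 df; at n = 90 the thresholds r = 0.70 and
0.75 correspond to p = 1.63 × 10⁻¹⁴ and 1.79 × 10⁻¹⁷.

Centrality conventions: degree is the raw edge count; betweenness is
unweighted shortest-path betweenness normalized by (n−1)(n−2)/2 node
pairs; closeness is (k−1)/Σd within each connected component of size k;
eigenvector centrality is computed per component by power iteration on
A + I (the +I shift prevents oscillation on bipartite components) from
an all-ones start vector, at most 1000 iterations, convergence
tolerance 1e-10, max-normalized to 1 per component. Isolated nodes
score 0 in all four metrics. Hubs are ranked by the mean of the four
centralities min-max scaled over the graph (a combining rule this
package defines; the source analysis reports centralities without
one), ties broken lexicographically by node id.

Module detection defaults to connected components, with greedy
modularity maximization as the alternative; the published 7/6 cluster
counts are cohort-dependent and are reproduced as a *procedure*, not as
numbers. Cluster indices are assigned by decreasing size with
lexicographic tie-breaks; isolated nodes are excluded from the count.

## Integration, sample clustering, association

Selected features are z-scored per feature (sample SD, ddof = 1) into a
samples × features matrix. PCA components get a deterministic sign
(largest-magnitude loading positive); the clustering embedding keeps
the components covering 80% variance, capped at 10. Sample clustering
is k-means (k = 3 default) with 20 seeded restarts, labels canonicalized
by cluster size. This is a transparent stand-in for latent-variable
multi-omics clustering (iCluster-family methods): it reproduces the
analysis pattern — integrated matrix, embedding, k clusters,
cluster-clinical association — without re-implementing a published
package's model. Association testing uses Fisher's exact test for 2×2
tables, otherwise chi-square, replaced by a seeded Monte-Carlo
permutation chi-square (9999 permutations) when any expected cell is
below 5, since no exact r×c test is available in the stack.

## Enrichment

Hypergeometric upper tail P(X ≥ k) with BH adjustment across sets. The
universe defaults to the symbols actually measured in the supplied
layers rather than the collection's union, so enrichment is judged
against what could have been observed. Enrichr-style combined scores
(−ln p · z) require a rank-deviation z from the external service's
background ranking, which is not recomputable offline; the package
accepts a supplied z for compatibility and reports p and the odds ratio
as its primary outputs.

## Validation studies and their problem sizes

The studies in `omicnet.experiments` (also run by
`scripts/acceptance.py`) use these sizes, chosen so each study finishes
in seconds while keeping its statistical claim meaningful:

* module recovery — 100 replicates of a 90-sample cohort, 60 features
  per layer, 5 cross-layer modules × 5 features/layer at λ = 0.9,
  |r| ≥ 0.7, component clustering; ARI computed over planted module
  members. Pass condition ARI ≥ 0.9 in ≥ 95 replicates.
* type-I calibration — one null cohort, 20,000 features, 35 vs 55
  samples; rejections at p < 0.001 compared to the exact binomial
  99% interval [Binom(20000, 0.001)].
* inter-omic contrast — 100 paired replicates (same seed, same module
  geometry) of cross-layer vs within-layer factor sharing, 40 features
  per layer, 3 modules × 4; strict inequality of inter-omic edge
  fractions expected in ≥ 95 pairs.
* centrality equivalence — every connected graph on ≤ 7 nodes (one per
  isomorphism class; centralities are isomorphism-covariant) plus 200
  Erdős–Rényi graphs on ≤ 25 nodes, against a brute-force oracle
  (Floyd–Warshall + definitional path-count betweenness + dense
  eigendecomposition), tolerance 1e-8.

## Known limitations

* Gaussian noise everywhere; no outliers, batch structure, or missing-
  not-at-random patterns, so real-data robustness is untested here.
* The realized methylation Δβ is approximate (logit-scale planting).
* Greedy modularity inherits networkx's internal tie-handling; it is
  deterministic for a fixed input ordering but not guaranteed to break
  ties lexicographically in every degenerate case.
* Cohort-derived numbers of the emulated study (feature counts such as
  29/32/33, the 7/6 network clusters, service-computed combined
  scores) depend on the original patient data and an external
  enrichment service and are out of reach by design; the pipeline
  reproduces the procedures, and the simulation studies above define
  what "working" means.
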