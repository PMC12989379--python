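# omicnet

Multi-omics correlation-network ("connectome") analysis of tumor
recurrence and grade progression, with a planted-truth synthetic cohort
generator so every stage of the pipeline can be validated offline.

## The problem and who this is for

Meningiomas of the same histological WHO grade can behave very
differently, and single-omic marker lists capture little of the
coordinated biology behind recurrence. One systems-level alternative is
to treat matched DNA-methylation, RNA and protein profiles from one
patient cohort as layers of a single network: select the features that
differ between clinical groups, correlate every selected feature with
every other across patients, and study the resulting multi-layer graph —
its modules, its hubs, and how strongly its edges cross omic layers.
This package implements that workflow for computational biologists who
want a tested, reproducible version of the analysis and a simulation
harness that says exactly what the procedure can and cannot recover.

## The method

For each omic layer (methylation betas β ∈ [0,1]; log2-scale RNA and
protein expression) and each contrast (recurrence yes/no; WHO grade
G1 vs G2 and G2 vs G3), every feature is tested with Welch's two-group
*t*-test and filtered on a raw p-value and a layer-scale effect size
(Δβ for methylation, log2 fold change otherwise). Default cutoffs per
contrast and layer: recurrence p < 0.001 with Δβ ≥ 0.18 / log2FC ≥ 1.7
(RNA) / 1.0 (protein); G1–G2 0.001 with 0.2 / 1.8 / 1.0; G2–G3 0.005
with 0.18, and 0.01 with 1.6 / 1.0.

Selected features from all layers are placed on one axis and pairwise
Pearson correlations are computed across samples. Feature pairs with
|r| ≥ 0.70 (recurrence analysis) or |r| ≥ 0.75 (grade analysis) become
edges; under the null, r = 0.70 at n = 90 corresponds to
p = 1.63 × 10⁻¹⁴ via t = r√(n−2)/√(1−r²) on n−2 degrees of freedom
(r = 0.75 → 1.79 × 10⁻¹⁷). Node importance is scored by degree,
pair-normalized betweenness, within-component closeness, and a
per-component power-iteration eigenvector centrality; modules are
connected components (or greedy modularity communities); hubs are the
mean of the four min-max-scaled centralities; inter-omic connectivity
is the fraction of edges joining different layers.

Downstream, the selected features are z-scored into one integrated
matrix for PCA and seeded k-means sample clustering (k = 3), with
cluster-vs-clinical association tests (Fisher / chi-square /
permutation chi-square), and selected gene symbols are scored against
GMT gene-set collections with the hypergeometric upper tail
P(X ≥ k) under Benjamini–Hochberg control.

The synthetic generator produces matched three-layer cohorts with the
two clinical designs (35/55 recurrence; 37/37/16 grades), planted
group-mean shifts at the selection-threshold scales, and planted
cross-layer modules in which features of all three layers share one
latent factor per sample (`value = λ·f + √(1−λ²)·ε`, so within-module
correlation → λ²), giving known ground truth for every stage.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_differential_selection.py
python analysis/03_network_connectome.py
```

The recurrence arm simulates 90 patients (35 non-recurrent, 55
recurrent) with 2000 CpGs, 1500 genes and 600 proteins, 30 planted
differential features per layer and 5 cross-layer modules. Selection
then prints, per layer:

```
[recurrence]
  methylation   16 selected (planted 30; precision 1.00, recall 0.53)
  rna           15 selected (planted 30; precision 1.00, recall 0.50)
  protein       13 selected (planted 30; precision 1.00, recall 0.43)
```

— perfect precision with ~50% recall, the expected power when planted
effects sit exactly at the filter thresholds. The connectome step prints:

```
[recurrence] 44 nodes, 110 edges at |r|>=0.7; 4 modules; inter-omic edge fraction 0.75
  top hubs (mean of min-max-scaled centralities):
    methylation:cg0015     score 0.894 (deg 9, btw 0.062)
```

Three quarters of the edges cross omic layers because the planted
modules share their latent factor across layers — the same signature
the real analysis reads as coordinated multi-omic dysregulation. The
remaining drivers (`04_integration_clustering.py`,
`05_enrichment.py`, `06_validation_studies.py`) cluster the samples
(the k = 3 partition separates recurrence at Fisher/chi-square
p ≈ 2 × 10⁻¹⁹ while grade stays null), run the enrichment stage (the
planted gene set tops the list at p ≈ 2 × 10⁻¹²), and re-run the
calibration studies.

The same pipeline is scriptable in one call:

```bash
omicnet run-all --out-dir results/run --seed 1
```

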