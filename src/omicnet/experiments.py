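"""Seeded simulation experiments that validate the pipeline's behaviour.

These are the package's own calibration / recovery studies, run by the
``analysis/`` drivers and the acceptance script:

* planted-module recovery — can connected-component clustering of the
  thresholded correlation graph reconstruct known cross-layer modules?
* type-I-error calibration — does the Welch filter reject at its nominal
  rate on a null cohort?
* inter-omic connectivity contrast — do cross-layer modules produce a
  larger inter-omic edge fraction than matched within-layer modules?

Every experiment takes an explicit seed and derives per-replicate seeds
deterministically from it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import adjusted_rand_score

from omicnet.connectome import build_graph, detect_clusters, interomic_connectivity, standardize_and_correlate
from omicnet.differential import ThresholdSet, select_features
from omicnet.simulate import MultiOmicsDataset, SimulationConfig, simulate_dataset, simulate_null_dataset

#: study conditions of the planted-module recovery experiment:
#: 5 cross-layer modules x 5 features/layer at loading 0.9, cohort n=90,
#: |r| threshold 0.7, component clustering, plus background features.
RECOVERY_CONFIG = SimulationConfig(
    n_per_group=(35, 55),
    n_features={"methylation": 60, "rna": 60, "protein": 60},
    n_diff={"methylation": 0, "rna": 0, "protein": 0},
    n_modules=5,
    module_size=5,
    module_loading=0.9,
)


def _replicate_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def _connectome_clusters(dataset: MultiOmicsDataset, r_threshold: float, method: str = "components"):
    R = standardize_and_correlate(list(dataset.layers.values()))
    cg = build_graph(R, r_threshold, n_samples=len(dataset.sample_ids))
    cluster_of, n_clusters = detect_clusters(cg, method)
    return cg, cluster_of, n_clusters


def module_recovery_replicate(
    seed: int,
    config: SimulationConfig = RECOVERY_CONFIG,
    r_threshold: float = 0.7,
    method: str = "components",
) -> float:
    """Adjusted Rand index between recovered clusters and planted modules.

    The correlation network is built over all simulated features; the
    ARI is evaluated on the planted module members (their recovered
    component label vs true module index).
    """
    dataset = simulate_dataset(dataclasses.replace(config, seed=seed))
    _, cluster_of, _ = _connectome_clusters(dataset, r_threshold, method)
    members = sorted(dataset.truth.module_assignment)
    truth_labels = [dataset.truth.module_assignment[f] for f in members]
    found_labels = [cluster_of[f] for f in members]
    return float(adjusted_rand_score(truth_labels, found_labels))


def module_recovery_study(seed: int, n_replicates: int = 100, **kwargs) -> dict:
    aris = [
        module_recovery_replicate(s, **kwargs)
        for s in _replicate_seeds(seed, n_replicates)
    ]
    aris = np.asarray(aris)
    return {
        "n_replicates": n_replicates,
        "ari_values": aris,
        "median_ari": float(np.median(aris)),
        "n_success": int((aris >= 0.9).sum()),
    }


def type_i_error_study(
    seed: int,
    n_features: int = 20000,
    n_per_group: tuple[int, int] = (35, 55),
    p_threshold: float = 0.001,
) -> dict:
    """Null rejection rate of the Welch p-filter at one nominal level.

    A null cohort (no planted effects or modules) is simulated with the
    recurrence group sizes; every RNA feature is tested and the fraction
    with p below the threshold is returned with the exact binomial 99%
    interval around the nominal rate.
    """
    from scipy.stats import binom

    cfg = SimulationConfig(
        n_per_group=n_per_group,
        n_features={"methylation": 2, "rna": n_features, "protein": 2},
        n_diff={"methylation": 0, "rna": 0, "protein": 0},
        n_modules=0,
        seed=seed,
    )
    dataset = simulate_null_dataset(cfg)
    thresholds = ThresholdSet(
        contrast="recurrence",
        p_threshold={ly: p_threshold for ly in ("methylation", "rna", "protein")},
        effect_threshold={ly: 0.0 for ly in ("methylation", "rna", "protein")},
    )
    records = select_features(
        dataset.layers["rna"], dataset.clinical, "recurrence", thresholds
    )
    n_reject = int(records["passes"].sum())
    lo = int(binom.ppf(0.005, n_features, p_threshold))
    hi = int(binom.ppf(0.995, n_features, p_threshold))
    return {
        "n_features": n_features,
        "n_reject": n_reject,
        "rejection_rate": n_reject / n_features,
        "nominal": p_threshold,
        "binomial_99_interval": (lo, hi),
        "within_interval": lo <= n_reject <= hi,
    }


def interomic_contrast_replicate(
    seed: int,
    config: SimulationConfig | None = None,
    r_threshold: float = 0.7,
) -> tuple[float, float]:
    """(cross-layer, within-layer) inter-omic edge fractions, one seed.

    Two cohorts are simulated from the same seed and module geometry,
    differing only in whether module latent factors are shared across
    layers; each yields the inter-omic fraction of its thresholded graph
    (0 when the graph has no edges).
    """
    base = config or dataclasses.replace(
        RECOVERY_CONFIG, n_features={"methylation": 40, "rna": 40, "protein": 40},
        n_modules=3, module_size=4,
    )
    fractions = []
    for mode in ("cross_layer", "within_layer"):
        ds = simulate_dataset(
            dataclasses.replace(base, seed=seed, module_mode=mode)
        )
        cg, _, _ = _connectome_clusters(ds, r_threshold)
        if cg.graph.number_of_edges() == 0:
            fractions.append(0.0)
        else:
            fractions.append(interomic_connectivity(cg)[0])
    return fractions[0], fractions[1]


def interomic_contrast_study(seed: int, n_replicates: int = 100, **kwargs) -> dict:
    pairs = [
        interomic_contrast_replicate(s, **kwargs)
        for s in _replicate_seeds(seed, n_replicates)
    ]
    cross = np.array([p[0] for p in pairs])
    within = np.array([p[1] for p in pairs])
    return {
        "n_replicates": n_replicates,
        "mean_cross_fraction": float(cross.mean()),
        "mean_within_fraction": float(within.mean()),
        "n_cross_greater": int((cross > within).sum()),
    }
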