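"""Integrated multi-omics matrix, PCA and sample clustering.

The selected features from all layers are concatenated into one
samples-by-features matrix, each feature z-scored across samples, and
the cohort is embedded with PCA and partitioned with seeded k-means on
the leading components. This is a deliberately transparent stand-in for
latent-variable multi-omics clustering (iCluster-style methods): it
reproduces the analysis pattern — an integrated matrix, a low-dimensional
embedding, k sample clusters, cluster-vs-clinical association tests —
with fully documented, deterministic machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from omicnet.errors import ConfigError, IntegrationError
from omicnet.io import ClinicalTable, OmicsLayer

log = logging.getLogger(__name__)


@dataclass
class IntegratedMatrix:
    """Samples x concatenated-features matrix, z-scored per feature."""

    values: pd.DataFrame  # index sample ids, columns namespaced feature ids
    feature_origin: dict[str, str]  # feature id -> layer


def integrate(
    layers: list[OmicsLayer], feature_subset: list[str] | None = None
) -> IntegratedMatrix:
    """Concatenate and z-score selected features from all layers.

    ``feature_subset`` is a list of namespaced feature ids; ``None``
    keeps everything. Zero-variance features are dropped with a warning;
    an empty result raises IntegrationError. Columns are z-scored with
    the sample standard deviation (ddof=1).
    """
    sample_ids = layers[0].sample_ids
    for ly in layers[1:]:
        if ly.sample_ids != sample_ids:
            raise IntegrationError("integrate: layers are not sample-aligned")
    stacked = pd.concat([ly.namespaced() for ly in layers], axis=0)
    origin = {}
    for ly in layers:
        for col in ly.namespaced().index:
            origin[col] = ly.layer_name
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in stacked.index]
        if missing:
            raise IntegrationError(f"integrate: unknown feature ids {missing[:5]}")
        stacked = stacked.loc[feature_subset]
    mat = stacked.T  # samples x features
    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning(
            "integrate: dropped %d zero-variance features", int((~keep).sum())
        )
        mat = mat.loc[:, keep]
        sd = sd[keep]
    if mat.shape[1] == 0:
        raise IntegrationError("integrate: no features left after filtering")
    z = (mat - mat.mean(axis=0)) / sd
    return IntegratedMatrix(
        values=z, feature_origin={c: origin[c] for c in z.columns}
    )


def pca_scores(m: IntegratedMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores and explained-variance fractions.

    Components are ordered by decreasing variance with a deterministic
    sign convention: the loading of largest magnitude on each component
    is made positive.
    """
    n_samples, n_features = m.values.shape
    if k > min(n_samples - 1, n_features):
        raise ConfigError(
            f"k: {k} components exceed min(samples-1, features) = "
            f"{min(n_samples - 1, n_features)}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(m.values.to_numpy(dtype=float))
    for j in range(k):
        load = pca.components_[j]
        pivot = np.argmax(np.abs(load))
        if load[pivot] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    score_df = pd.DataFrame(
        scores, index=m.values.index, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return score_df, pca.explained_variance_ratio_.copy()


def n_components_for(m: IntegratedMatrix, target_fraction: float = 0.8, cap: int = 10) -> int:
    """Smallest component count explaining the target variance, capped."""
    kmax = min(m.values.shape[0] - 1, m.values.shape[1])
    _, frac = pca_scores(m, kmax)
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, target_fraction) + 1)
    return min(k, cap, kmax)


def cluster_samples(scores: pd.DataFrame, k: int, seed: int) -> pd.Series:
    """Seeded k-means sample clustering on PCA scores.

    20 restarts; labels canonicalized by cluster size descending (ties
    broken by smallest member sample index) and numbered from 1, so the
    labelling is deterministic under a fixed seed.
    """
    if k < 2:
        raise ConfigError("k: need at least 2 clusters")
    if k > len(scores):
        raise ConfigError("k: more clusters than samples")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    raw = km.fit_predict(scores.to_numpy(dtype=float))
    order = sorted(
        range(k),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=scores.index, name="cluster")


def cluster_clinical_association(
    labels: pd.Series,
    clinical: ClinicalTable,
    variable: str = "recurrence",
    seed: int = 0,
    n_permutations: int = 9999,
) -> tuple[pd.DataFrame, float, float, str]:
    """Test cluster labels against a clinical variable.

    Returns (contingency table, statistic, p, test name). Fisher's
    exact test for 2x2 tables; otherwise a chi-square test of
    independence, replaced by a seeded Monte-Carlo permutation
    chi-square when any expected cell falls below 5 (no exact r-x-c
    test is available).
    """
    if variable not in ("recurrence", "grade"):
        raise ConfigError(f"variable: unknown clinical variable {variable!r}")
    if labels.nunique() < 2:
        raise ConfigError("association: need at least 2 clusters")
    outcome = clinical.table.loc[labels.index, variable]
    table = pd.crosstab(labels, outcome)
    if table.shape == (2, 2):
        odds, p = stats.fisher_exact(table.to_numpy())
        return table, float(odds), float(p), "fisher_exact"
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected < 5).any():
        rng = np.random.default_rng(seed)
        lab_codes = pd.factorize(labels)[0]
        out_codes = pd.factorize(outcome)[0]
        n_lab = lab_codes.max() + 1
        n_out = out_codes.max() + 1

        def chi2_stat(oc: np.ndarray) -> float:
            c = np.bincount(lab_codes * n_out + oc, minlength=n_lab * n_out)
            c = c.reshape(n_lab, n_out).astype(float)
            exp = c.sum(1, keepdims=True) * c.sum(0, keepdims=True) / c.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(exp > 0, (c - exp) ** 2 / exp, 0.0)
            return float(terms.sum())

        observed = chi2_stat(out_codes)
        count = sum(
            chi2_stat(rng.permutation(out_codes)) >= observed - 1e-12
            for _ in range(n_permutations)
        )
        p = (count + 1) / (n_permutations + 1)
        return table, float(observed), float(p), "permutation_chi2"
    return table, float(chi2), float(p), "chi2"
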