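"""Per-layer differential feature selection (DMRs, DEGs, DEPs).

Each feature is tested with a two-group t-test (Welch unequal-variance
by default — the safer choice for the unbalanced 35/55 and 37/16 group
sizes; the pooled-variance test is available behind ``pooled=True``) and
filtered on a raw p-value plus an effect-size threshold. Effect-size
semantics are layer-specific:

* methylation — delta-beta, the difference of group-mean beta values;
* rna / protein — log2 fold change, i.e. the difference of group means
  on already-log2-scaled expression (``fc_mode="ratio"`` instead reads
  the threshold as a linear ratio and compares |effect| to log2(FC)).

No multiple-testing correction is applied by default, matching the raw
per-layer p-value filters used in the emulated study; Benjamini-Hochberg
adjusted p-values can be added with ``adjust="bh"`` (filtering then uses
the adjusted p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from omicnet import LAYERS
from omicnet.errors import ConfigError, ContrastError
from omicnet.io import ClinicalTable, OmicsLayer, namespace_feature

log = logging.getLogger(__name__)

CONTRASTS = ("recurrence", "g1_vs_g2", "g2_vs_g3")

#: published per-layer selection thresholds: contrast -> layer -> (p, effect)
DEFAULT_THRESHOLDS: dict[str, dict[str, tuple[float, float]]] = {
    "recurrence": {
        "methylation": (0.001, 0.18),
        "rna": (0.001, 1.7),
        "protein": (0.001, 1.0),
    },
    "g1_vs_g2": {
        "methylation": (0.001, 0.2),
        "rna": (0.001, 1.8),
        "protein": (0.001, 1.0),
    },
    "g2_vs_g3": {
        "methylation": (0.005, 0.18),
        "rna": (0.01, 1.6),
        "protein": (0.01, 1.0),
    },
}


@dataclass(frozen=True)
class ThresholdSet:
    """Per-layer p-value and effect-size cutoffs for one contrast."""

    contrast: str
    p_threshold: dict[str, float] = field(default_factory=dict)
    effect_threshold: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls, contrast: str) -> "ThresholdSet":
        if contrast not in DEFAULT_THRESHOLDS:
            raise ConfigError(f"contrast: unknown contrast {contrast!r}")
        table = DEFAULT_THRESHOLDS[contrast]
        return cls(
            contrast=contrast,
            p_threshold={ly: table[ly][0] for ly in LAYERS},
            effect_threshold={ly: table[ly][1] for ly in LAYERS},
        )

    def for_layer(self, layer: str) -> tuple[float, float]:
        p = self.p_threshold[layer]
        e = self.effect_threshold[layer]
        if not (0.0 < p < 1.0):
            raise ConfigError(f"p_threshold: must lie in (0,1) for {layer}")
        if e < 0:
            raise ConfigError(f"effect_threshold: must be nonnegative for {layer}")
        return p, e


def welch_t(x, y, pooled: bool = False) -> tuple[float, float, float]:
    """Two-group t-test: returns (t statistic, df, two-sided p).

    Welch's unequal-variance statistic with Welch-Satterthwaite degrees
    of freedom by default; Student's pooled-variance test with
    ``pooled=True``. Two groups with zero variance and equal means
    return (0, n-2, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ContrastError("welch_t: each group needs at least 2 values")
    if (x == x[0]).all() and (y == y[0]).all():
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        return float(np.inf * np.sign(np.mean(y) - np.mean(x))), float(
            x.size + y.size - 2
        ), 0.0
    res = stats.ttest_ind(y, x, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def effect_size(layer: str, mean_a: float, mean_b: float) -> float:
    """Signed layer-scale effect: delta-beta or log2 fold change (b - a)."""
    if layer == "methylation" and not (0 <= mean_a <= 1 and 0 <= mean_b <= 1):
        raise ConfigError("effect_size: methylation means must lie in [0,1]")
    return float(mean_b - mean_a)


def _effect_cutoff(layer: str, fc: float, fc_mode: str) -> float:
    """Translate a configured FC threshold into effect (group-diff) units."""
    if layer == "methylation" or fc_mode == "log2":
        return fc
    if fc_mode == "ratio":
        if fc <= 0:
            raise ConfigError("effect_threshold: ratio-mode FC must be positive")
        return float(np.log2(fc)) if fc >= 1 else float(-np.log2(fc))
    raise ConfigError(f"fc_mode: unknown mode {fc_mode!r}")


def select_features(
    layer: OmicsLayer,
    clinical: ClinicalTable,
    contrast: str,
    thresholds: ThresholdSet | None = None,
    fc_mode: str = "log2",
    pooled: bool = False,
    adjust: str = "none",
) -> pd.DataFrame:
    """Test every feature of one layer for one contrast.

    Returns one row per feature (sorted by p ascending): group means,
    signed effect, t, df, p (and BH-adjusted p when requested), a
    ``zero_variance`` flag and the ``passes`` verdict
    (p < p_threshold AND |effect| >= effect_threshold).
    """
    if thresholds is None:
        thresholds = ThresholdSet.default(contrast)
    if thresholds.contrast != contrast:
        raise ConfigError("thresholds: contrast does not match requested contrast")
    p_thr, fc_thr = thresholds.for_layer(layer.layer_name)
    eff_thr = _effect_cutoff(layer.layer_name, fc_thr, fc_mode)

    if list(layer.sample_ids) != list(clinical.sample_ids):
        raise ContrastError("select_features: layer and clinical samples not aligned")
    mask_a, mask_b, label_a, label_b = clinical.group_mask(contrast)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ContrastError(
            f"contrast {contrast}: groups {label_a}/{label_b} have "
            f"{int(mask_a.sum())}/{int(mask_b.sum())} samples (need >= 2 each)"
        )

    values = layer.values.to_numpy(dtype=float)
    a = values[:, mask_a]
    b = values[:, mask_b]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    na, nb = a.shape[1], b.shape[1]

    res = stats.ttest_ind(b, a, axis=1, equal_var=pooled)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)

    # detect constant-in-both-groups features by exact equality; a float
    # variance of a constant column can be a nonzero rounding residue
    zero_var = (a == a[:, :1]).all(axis=1) & (b == b[:, :1]).all(axis=1)
    if zero_var.any():
        t = np.where(zero_var, 0.0, t)
        p = np.where(zero_var, 1.0, p)
        df = np.where(zero_var, na + nb - 2, df)

    effect = mean_b - mean_a
    p_filter = p
    out = pd.DataFrame(
        {
            "feature_id": [
                namespace_feature(layer.layer_name, f) for f in layer.feature_ids
            ],
            "symbol": layer.feature_ids,
            "layer": layer.layer_name,
            "contrast": contrast,
            "group_a": label_a,
            "group_b": label_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "effect": effect,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "zero_variance": zero_var,
        }
    )
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        out["adjusted_p"] = multipletests(p, method="fdr_bh")[1]
        p_filter = out["adjusted_p"].to_numpy()
    elif adjust != "none":
        raise ConfigError(f"adjust: unknown mode {adjust!r}")

    out["passes"] = (p_filter < p_thr) & (np.abs(effect) >= eff_thr) & ~zero_var
    out = out.sort_values(["p_value", "feature_id"], kind="mergesort").reset_index(
        drop=True
    )
    log.info(
        "select_features(%s, %s): %d/%d features pass (p<%g, |effect|>=%g)",
        layer.layer_name,
        contrast,
        int(out["passes"].sum()),
        len(out),
        p_thr,
        eff_thr,
    )
    return out


def select_grade_features(
    layer: OmicsLayer,
    clinical: ClinicalTable,
    thresholds_12: ThresholdSet | None = None,
    thresholds_23: ThresholdSet | None = None,
    combine: str = "union",
    **kwargs,
) -> pd.DataFrame:
    """Grade-progression selection: run G1-vs-G2 and G2-vs-G3, combine.

    The grade feature set is the union of passers of the two adjacent
    contrasts by default (``combine="intersection"`` for the stricter
    rule). Returns the concatenated per-contrast records with a
    ``passes_combined`` column marking membership in the combined set.
    """
    if combine not in ("union", "intersection"):
        raise ConfigError(f"combine: unknown mode {combine!r}")
    rec12 = select_features(layer, clinical, "g1_vs_g2", thresholds_12, **kwargs)
    rec23 = select_features(layer, clinical, "g2_vs_g3", thresholds_23, **kwargs)
    pass12 = set(rec12.loc[rec12["passes"], "feature_id"])
    pass23 = set(rec23.loc[rec23["passes"], "feature_id"])
    combined = pass12 | pass23 if combine == "union" else pass12 & pass23
    both = pd.concat([rec12, rec23], ignore_index=True)
    both["passes_combined"] = both["feature_id"].isin(combined)
    return both


def volcano_table(records: pd.DataFrame, cap: float = 300.0) -> pd.DataFrame:
    """Plot-ready volcano export: (feature, effect, -log10 p, passes)."""
    if records.empty:
        raise ConfigError("volcano_table: no records")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(records["p_value"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "feature_id": records["feature_id"],
            "effect": records["effect"],
            "neg_log10_p": np.minimum(neglog, cap),
            "passes": records["passes"],
        }
    ).reset_index(drop=True)
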