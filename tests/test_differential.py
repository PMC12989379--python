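"""Welch-test selection: oracle agreement, power, calibration, thresholds."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicnet.differential import (
    DEFAULT_THRESHOLDS,
    ThresholdSet,
    effect_size,
    select_features,
    select_grade_features,
    volcano_table,
    welch_t,
)
from omicnet.errors import ConfigError, ContrastError
from omicnet.simulate import SimulationConfig, simulate_dataset, simulate_null_dataset

from oracles import welch_oracle


class TestWelchT:
    def test_identical_groups_give_t0_p1(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_drive_p_to_zero(self):
        rng = np.random.default_rng(0)
        for eps in (1e-2, 1e-4, 1e-6):
            x = rng.normal(0, eps, 4)
            y = 1 + rng.normal(0, eps, 4)
            p = welch_t(x, y)[2]
            assert p < eps  # p vanishes as the groups separate
        t, _, p = welch_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert np.isinf(t) and p == 0.0

    def test_textbook_example_matches_closed_form(self):
        x = [1.1, 2.0, 3.2, 4.1]
        y = [2.9, 4.2, 5.1, 6.3]
        t, df, p = welch_t(x, y)
        to, dfo, po = welch_oracle(x, y)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == pytest.approx(dfo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_matches_oracle_on_1000_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            nx = rng.integers(2, 40)
            ny = rng.integers(2, 40)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.2, 3), nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.2, 3), ny)
            t, df, p = welch_t(x, y)
            to, dfo, po = welch_oracle(x, y)
            assert abs(t - to) < 1e-10
            assert abs(df - dfo) < 1e-10
            assert abs(p - po) < 1e-10

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
    )
    def test_property_agrees_with_oracle(self, x, y):
        # squared standard errors underflow below ~1e-150, so restrict
        # the property to numerically meaningful variances
        if np.var(x, ddof=1) + np.var(y, ddof=1) < 1e-12:
            return
        t, df, p = welch_t(x, y)
        to, dfo, po = welch_oracle(x, y)
        assert t == pytest.approx(to, rel=1e-9, abs=1e-10)
        # the beta-function oracle itself carries ~1e-9 error when p -> 1
        assert p == pytest.approx(po, rel=1e-6, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ContrastError):
            welch_t([1.0], [1.0, 2.0])


def test_effect_size_semantics():
    assert effect_size("methylation", 0.30, 0.52) == pytest.approx(0.22)
    assert effect_size("rna", 5.0, 6.7) == pytest.approx(1.7)
    assert effect_size("protein", 2.0, 2.0) == 0.0
    with pytest.raises(ConfigError):
        effect_size("methylation", -0.1, 0.5)


def test_default_thresholds_reproduce_published_table():
    expected = {
        "recurrence": {"methylation": (0.001, 0.18), "rna": (0.001, 1.7),
                       "protein": (0.001, 1.0)},
        "g1_vs_g2": {"methylation": (0.001, 0.2), "rna": (0.001, 1.8),
                     "protein": (0.001, 1.0)},
        "g2_vs_g3": {"methylation": (0.005, 0.18), "rna": (0.01, 1.6),
                     "protein": (0.01, 1.0)},
    }
    assert DEFAULT_THRESHOLDS == expected
    ts = ThresholdSet.default("recurrence")
    assert ts.for_layer("rna") == (0.001, 1.7)


class TestSelectFeatures:
    def test_planted_features_recovered_with_high_power(self):
        """Effect 2.0 log2FC at n=45/45, sd=1: noncentral-t power ~ 1.

        delta = 2.0 / sqrt(1/45 + 1/45) = 9.49, so p < 0.001 and
        |effect| >= 1.7 hold for nearly every planted feature; require
        >= 45 of 50.
        """
        cfg = SimulationConfig(
            n_per_group=(45, 45),
            n_features={"methylation": 2, "rna": 200, "protein": 2},
            n_diff={"methylation": 0, "rna": 50, "protein": 0},
            effect_rna=2.0,
            n_modules=0,
            seed=17,
        )
        ds = simulate_dataset(cfg)
        rec = select_features(ds.layers["rna"], ds.clinical, "recurrence")
        planted = {
            f"rna:{fid}" for fid, _ in ds.truth.diff_features["rna"]["recurrence"]
        }
        passed = set(rec.loc[rec["passes"], "feature_id"])
        assert len(planted & passed) >= 45

    def test_null_pass_count_within_binomial_band(self):
        cfg = SimulationConfig(
            n_per_group=(35, 55),
            n_features={"methylation": 2, "rna": 20000, "protein": 2},
            seed=23,
        )
        ds = simulate_null_dataset(cfg)
        ts = ThresholdSet(
            contrast="recurrence",
            p_threshold={ly: 0.001 for ly in ("methylation", "rna", "protein")},
            effect_threshold={ly: 0.0 for ly in ("methylation", "rna", "protein")},
        )
        rec = select_features(ds.layers["rna"], ds.clinical, "recurrence", ts)
        from scipy.stats import binom

        n_pass = int(rec["passes"].sum())
        assert binom.ppf(0.005, 20000, 0.001) <= n_pass <= binom.ppf(0.995, 20000, 0.001)

    def test_passes_is_exactly_the_threshold_biconditional(self, small_dataset):
        ts = ThresholdSet.default("recurrence")
        for name, layer in small_dataset.layers.items():
            rec = select_features(layer, small_dataset.clinical, "recurrence", ts)
            p_thr, e_thr = ts.for_layer(name)
            expected = (
                (rec["p_value"] < p_thr)
                & (rec["effect"].abs() >= e_thr)
                & ~rec["zero_variance"]
            )
            assert (rec["passes"] == expected).all()
            assert rec["p_value"].is_monotonic_increasing

    def test_selection_monotone_in_thresholds(self, small_dataset):
        layer = small_dataset.layers["rna"]
        clin = small_dataset.clinical
        counts = []
        for p_thr, e_thr in [(0.05, 0.5), (0.01, 0.5), (0.01, 1.0), (0.001, 1.7)]:
            ts = ThresholdSet(
                contrast="recurrence",
                p_threshold={ly: p_thr for ly in ("methylation", "rna", "protein")},
                effect_threshold={ly: e_thr for ly in ("methylation", "rna", "protein")},
            )
            rec = select_features(layer, clin, "recurrence", ts)
            counts.append(int(rec["passes"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_zero_variance_feature_flagged_not_passing(self, small_dataset):
        layer = small_dataset.layers["rna"]
        vals = layer.values.copy()
        vals.iloc[0] = 3.14
        from omicnet.io import OmicsLayer

        rec = select_features(
            OmicsLayer(layer_name="rna", values=vals),
            small_dataset.clinical,
            "recurrence",
        )
        row = rec[rec["symbol"] == vals.index[0]].iloc[0]
        assert row["zero_variance"] and not row["passes"]
        assert row["p_value"] == 1.0 and row["t_stat"] == 0.0

    def test_empty_contrast_group_raises(self, small_dataset):
        clin = small_dataset.clinical
        clin2 = clin.table.assign(grade=1)
        from omicnet.io import ClinicalTable

        with pytest.raises(ContrastError):
            select_features(
                small_dataset.layers["rna"],
                ClinicalTable(table=clin2),
                "g1_vs_g2",
            )

    def test_bh_adjustment_filters_on_adjusted_p(self, small_dataset):
        rec = select_features(
            small_dataset.layers["rna"], small_dataset.clinical, "recurrence",
            adjust="bh",
        )
        assert (rec["adjusted_p"] >= rec["p_value"] - 1e-15).all()


def test_grade_union_combines_both_contrasts():
    cfg = SimulationConfig(
        n_per_group=(37, 37, 16),
        n_features={"methylation": 2, "rna": 150, "protein": 2},
        n_diff={"methylation": 0, "rna": 20, "protein": 0},
        effect_rna=2.0,
        n_modules=0,
        seed=31,
    )
    ds = simulate_dataset(cfg)
    rec = select_grade_features(ds.layers["rna"], ds.clinical)
    union = set(rec.loc[rec["passes_combined"], "feature_id"])
    p12 = set(rec.loc[(rec["contrast"] == "g1_vs_g2") & rec["passes"], "feature_id"])
    p23 = set(rec.loc[(rec["contrast"] == "g2_vs_g3") & rec["passes"], "feature_id"])
    assert union == p12 | p23
    inter = select_grade_features(ds.layers["rna"], ds.clinical, combine="intersection")
    assert set(inter.loc[inter["passes_combined"], "feature_id"]) == p12 & p23


def test_volcano_table_caps_and_preserves_flags():
    rec = pd.DataFrame(
        {
            "feature_id": [f"rna:g{i}" for i in range(3)],
            "effect": [1.0, -2.0, 0.5],
            "p_value": [0.001, 1.0, 0.0],
            "passes": [True, False, True],
        }
    )
    vt = volcano_table(rec)
    assert len(vt) == 3
    assert vt["neg_log10_p"].tolist() == pytest.approx([3.0, 0.0, 300.0])
    assert vt["passes"].tolist() == [True, False, True]
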