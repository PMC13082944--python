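"""Phenotype statistics: normalisation, pairs, plasma cleaning, PCA, dosing."""

import numpy as np
import pandas as pd
import pytest

from hecpipe.mcw import MCWConfig
from hecpipe.phenotypes import (
    DoseModel,
    clean_plasma,
    consumption_pairs,
    dose_equivalent,
    fasting_pairs,
    litter_stats,
    metabolite_pca,
    normalize_trait,
    pearson_r,
)
from hecpipe.mcw import mbmcw_test


class TestNormalizeTrait:
    def test_body_weight_per_day_of_age(self):
        assert normalize_trait(30.0, age_days=60) == pytest.approx(0.5)

    def test_glucose_unit_chain(self):
        assert normalize_trait(120.0, age_days=60, body_weight=30.0) == pytest.approx(
            120 / 30 / 60
        )

    def test_zero_age_rejected(self):
        with pytest.raises(ValueError):
            normalize_trait(10.0, age_days=0)

    def test_zero_body_weight_rejected(self):
        with pytest.raises(ValueError):
            normalize_trait(10.0, age_days=10, body_weight=0.0)


class TestMatchedPairs:
    def _series(self, values, ids):
        return pd.Series(values, index=ids, dtype=float)

    def test_exposure_weight_loss_gives_negative_bi(self):
        groups = pd.Series(
            {"e1": "TWD", "e2": "TWD", "e3": "TWD", "c1": "DMSO", "c2": "DMSO", "c3": "DMSO"}
        )
        pre = self._series([30, 31, 32, 30, 31, 32], groups.index)
        post = self._series([27, 28, 29, 29.5, 30.5, 31.5], groups.index)
        x, y = fasting_pairs(pre, post, groups, "TWD")
        res = mbmcw_test(x, y)
        assert res.bias_index < 0

    def test_identical_groups_give_zero(self):
        groups = pd.Series({"e1": "IAS", "e2": "IAS", "c1": "DMSO", "c2": "DMSO"})
        pre = self._series([30, 31, 30, 31], groups.index)
        post = self._series([29, 30, 29, 30], groups.index)
        x, y = fasting_pairs(pre, post, groups, "IAS")
        assert mbmcw_test(x, y).bias_index == 0.0

    def test_incomplete_pair_excluded(self):
        groups = pd.Series({"e1": "IAS", "e2": "IAS", "c1": "DMSO"})
        pre = self._series([30, np.nan, 30], groups.index)
        post = self._series([29, 28, 29], groups.index)
        x, y = fasting_pairs(pre, post, groups, "IAS")
        assert len(x) == 1 and len(y) == 1

    def test_one_subject_groups_take_exact_path(self):
        groups = pd.Series({"e1": "IAS", "c1": "DMSO"})
        pre = self._series([30, 30], groups.index)
        post = self._series([28, 29], groups.index)
        x, y = fasting_pairs(pre, post, groups, "IAS")
        assert mbmcw_test(x, y).path == "exact"

    def test_consumption_refill_anomaly_flagged(self, caplog):
        groups = pd.Series({"k1": "TWD", "c1": "DMSO"})
        entry = pd.Series({"k1": 200.0, "c1": 200.0})
        exit_ = pd.Series({"k1": 220.0, "c1": 150.0})
        with caplog.at_level("WARNING"):
            consumption_pairs(entry, exit_, groups, "TWD")
        assert any("refill" in rec.message for rec in caplog.records)


class TestCleanPlasma:
    def test_out_of_range_zeroed_in_range_untouched(self):
        panel = pd.DataFrame({"leptin": [350.0, 120.0], "insulin": [40.0, 60.0]},
                             index=["m1", "m2"])
        mask = pd.DataFrame({"leptin": [True, False], "insulin": [False, True]},
                            index=["m1", "m2"])
        out = clean_plasma(panel, mask)
        assert out.loc["m1", "leptin"] == 350.0
        assert out.loc["m2", "leptin"] == 0.0
        assert out.loc["m1", "insulin"] == 0.0


class TestMetabolitePca:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 2, 30)
        panel = pd.DataFrame({"a": base, "b": 2 * base + 1})
        scores, loadings, var = metabolite_pca(panel)
        assert var[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.lognormal(size=(25, 6)),
                             columns=[f"m{i}" for i in range(6)])
        _, loadings, _ = metabolite_pca(panel)
        gram = loadings.to_numpy().T @ loadings.to_numpy()
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_reconstruction_of_scaled_matrix(self):
        rng = np.random.default_rng(2)
        panel = pd.DataFrame(rng.lognormal(size=(20, 5)),
                             columns=[f"m{i}" for i in range(5)])
        scores, loadings, _ = metabolite_pca(panel, scale=True)
        x = panel.to_numpy()
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        assert np.allclose(scores.to_numpy() @ loadings.to_numpy().T, x, atol=1e-8)

    def test_incomplete_metabolites_dropped(self):
        rng = np.random.default_rng(3)
        panel = pd.DataFrame(rng.lognormal(size=(10, 3)), columns=["a", "b", "c"])
        panel.loc[3, "b"] = 0.0  # zeroed (out of range) -> not complete-case
        _, loadings, _ = metabolite_pca(panel)
        assert "b" not in loadings.index

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        panel = pd.DataFrame(rng.lognormal(size=(15, 4)),
                             columns=[f"m{i}" for i in range(4)])
        s1, l1, _ = metabolite_pca(panel)
        s2, l2, _ = metabolite_pca(panel)
        pd.testing.assert_frame_equal(s1, s2)
        for comp in l1.columns:
            assert l1[comp].abs().max() == l1[comp].max()

    def test_too_few_complete_metabolites_rejected(self):
        panel = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            metabolite_pca(panel)


class TestPearson:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_r(x, [2 * v for v in x])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(5)
        r, _ = pearson_r(rng.normal(size=100), rng.normal(size=100))
        assert abs(r) < 0.3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDoseEquivalent:
    def test_reference_drinking_water_dose(self):
        dose, ratio = dose_equivalent(DoseModel(concentration_nM=50.0))
        assert dose == pytest.approx(0.0048, abs=0.0002)
        assert float(f"{dose:.1g}") == 0.005  # one significant figure
        assert round(ratio) == 5

    def test_low_dose_ratio_fifty(self):
        dose, ratio = dose_equivalent(DoseModel(concentration_nM=5.0))
        assert float(f"{ratio:.1g}") == 50  # one significant figure

    def test_linear_in_concentration_and_intake_inverse_in_weight(self):
        base, _ = dose_equivalent(DoseModel(concentration_nM=50.0))
        double_conc, _ = dose_equivalent(DoseModel(concentration_nM=100.0))
        assert double_conc == pytest.approx(2 * base)
        double_intake, _ = dose_equivalent(
            DoseModel(concentration_nM=50.0, water_intake_L_per_day=0.02)
        )
        assert double_intake == pytest.approx(2 * base)
        double_weight, _ = dose_equivalent(
            DoseModel(concentration_nM=50.0, body_weight_kg=0.06)
        )
        assert double_weight == pytest.approx(base / 2)

    def test_zero_concentration_gives_zero_dose(self):
        dose, ratio = dose_equivalent(DoseModel(concentration_nM=0.0))
        assert dose == 0.0 and np.isinf(ratio)

    def test_chloride_salt_also_rounds_to_paper_value(self):
        dose, _ = dose_equivalent(DoseModel(concentration_nM=50.0, molecular_weight=325.5))
        assert float(f"{dose:.1g}") == 0.005


class TestLitterStats:
    def _litters(self, sizes_by_group):
        rows = []
        for group, sizes in sizes_by_group.items():
            for i, n in enumerate(sizes):
                rows.append({"litter_id": f"{group}{i}", "group": group,
                             "n_pups": n, "n_females": n // 2})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_bi(self):
        litters = self._litters({"IAS": [6, 7, 8], "DMSO": [6, 7, 8]})
        res = litter_stats(litters, "IAS")
        assert res["litter_size"].bias_index == 0.0

    def test_all_female_litters_have_unit_ratio(self):
        litters = self._litters({"IAS": [4], "DMSO": [4]})
        litters["n_females"] = litters["n_pups"]
        res = litter_stats(litters, "IAS")
        assert res["sex_ratio"].bias_index == 0.0  # both ratios 1 -> no bias

    def test_planted_size_shift_recovered_with_sign(self):
        rng = np.random.default_rng(6)
        litters = self._litters(
            {"TWD": list(rng.poisson(9, 8)), "DMSO": list(rng.poisson(5, 8))}
        )
        res = litter_stats(litters, "TWD", config=MCWConfig(seed=1))
        assert res["litter_size"].bias_index > 0.5
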