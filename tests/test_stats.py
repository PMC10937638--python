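"""Normalisation, detection filtering, and the regression battery."""

import numpy as np
import pandas as pd
import pytest

from cometab.abundance import collapse_to_species, map_filter_normalise
from cometab.stats import (
    MetabolomeTable,
    creatinine_normalise,
    demographics_table,
    filter_detected,
    flux_group_regression,
    fractional_abundance_regression,
    logratio_test,
    metabolite_group_regression,
    normalize_pqn,
)
from cometab.synth import SynthConfig, make_abundance_counts, make_metabolome


@pytest.fixture(scope="module")
def metabolome():
    return make_metabolome(SynthConfig(seed=11))


@pytest.fixture(scope="module")
def abundance_data():
    cfg = SynthConfig(seed=7, n_species=40)
    counts, cov, truth = make_abundance_counts(cfg)
    sp = collapse_to_species(counts)
    ab = map_filter_normalise(sp, truth["model_species"])
    return sp, ab, cov, truth


class TestPQN:
    def test_identical_samples_unchanged(self):
        conc = pd.DataFrame(np.tile([1.0, 2.0, 4.0], (5, 1)),
                            index=[f"S{i}" for i in range(5)], columns=list("abc"))
        cov = pd.DataFrame({"age": 70, "sex": "f", "bmi": 25, "group": "HC"}, index=conc.index)
        out = normalize_pqn(MetabolomeTable(conc, cov))
        pd.testing.assert_frame_equal(out.concentrations, conc)

    def test_scaled_sample_restored_with_fixed_reference(self, metabolome):
        tab, _ = metabolome
        ref = tab.concentrations.replace(0, np.nan).median(axis=0)
        scaled = tab.concentrations.copy()
        scaled.iloc[0] *= 2
        a = normalize_pqn(tab, reference=ref).concentrations
        b = normalize_pqn(MetabolomeTable(scaled, tab.covariates), reference=ref).concentrations
        pd.testing.assert_frame_equal(a, b)

    def test_scale_equivariance_data_driven_reference(self, metabolome):
        """With the default (median-spectrum) reference the property holds
        up to the tiny shift the sample itself induces in the median."""
        tab, _ = metabolome
        scaled = tab.concentrations.copy()
        scaled.iloc[0] *= 3
        a = normalize_pqn(tab).concentrations.iloc[0]
        b = normalize_pqn(MetabolomeTable(scaled, tab.covariates)).concentrations.iloc[0]
        ratio = (b / a).dropna()
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_planted_dilution_factors_recovered(self):
        """Known dilution factors on a shared log-normal profile are
        recovered to a few percent from 50 metabolites."""
        rng = np.random.default_rng(42)
        n, p = 40, 50
        profile = np.exp(rng.normal(0, 1, size=p))  # shared spectrum
        noise = np.exp(rng.normal(0, 0.25, size=(n, p)))  # biological scatter
        factors = np.exp(rng.normal(0, 0.5, size=n))
        conc = pd.DataFrame(profile[None, :] * noise * factors[:, None],
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"m{j}" for j in range(p)])
        cov = pd.DataFrame({"age": 70, "sex": "f", "bmi": 25, "group": "HC"}, index=conc.index)
        out = normalize_pqn(MetabolomeTable(conc, cov))
        implied = (conc / out.concentrations).median(axis=1).to_numpy()
        rel = implied / factors
        rel /= np.median(rel)  # factors identifiable up to a global scale
        assert np.median(np.abs(rel - 1)) < 0.05
        assert np.all(np.abs(rel - 1) < 0.2)

    def test_all_missing_sample_rejected(self):
        conc = pd.DataFrame([[1.0, 2.0], [0.0, 0.0]], index=["S1", "S2"], columns=["a", "b"])
        cov = pd.DataFrame({"age": 70, "sex": "f", "bmi": 25, "group": "HC"}, index=conc.index)
        with pytest.raises(ValueError, match="S2"):
            normalize_pqn(MetabolomeTable(conc, cov))


class TestFilterDetected:
    def test_strictly_more_than_half_rule(self):
        idx = [f"S{i}" for i in range(10)]
        conc = pd.DataFrame(
            {
                "kept": [1.0] * 6 + [0.0] * 4,       # 60% non-zero
                "boundary": [1.0] * 5 + [0.0] * 5,   # exactly 50%: removed
                "removed": [1.0] * 4 + [0.0] * 6,    # 40%
            },
            index=idx,
        )
        cov = pd.DataFrame({"age": 70, "sex": "f", "bmi": 25, "group": "HC"}, index=idx)
        out = filter_detected(MetabolomeTable(conc, cov))
        assert list(out.concentrations.columns) == ["kept"]
        assert out.concentrations["kept"].isna().sum() == 4  # zeros recoded missing

    def test_survivor_count_matches_counting_oracle(self, metabolome):
        tab, truth = metabolome
        out = filter_detected(tab)
        expected = ((tab.concentrations > 0).mean(axis=0) > 0.5).sum()
        assert out.concentrations.shape[1] == expected
        assert set(out.concentrations.columns) == set(truth["detectable"])


class TestMetaboliteRegression:
    def test_constant_response_null(self):
        idx = [f"S{i}" for i in range(60)]
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            {
                "age": rng.normal(70, 5, 60),
                "sex": rng.choice(["male", "female"], 60),
                "bmi": rng.normal(26, 3, 60),
                "group": ["HC", "SCD", "MCI", "AD"] * 15,
            },
            index=idx,
        )
        conc = pd.DataFrame({"flat": np.full(60, 2.0)}, index=idx)
        res = metabolite_group_regression(MetabolomeTable(conc, cov))
        assert res.loc["flat", "coef_ad_vs_ref"] == pytest.approx(0.0, abs=1e-10)
        assert res.loc["flat", "wald_p"] > 0.99

    def test_planted_effect_recovered_single_draw(self, metabolome):
        tab, truth = metabolome
        res = metabolite_group_regression(filter_detected(tab))
        for met, eff in truth["planted"].items():
            assert res.loc[met, "coef_ad_vs_ref"] == pytest.approx(eff, abs=0.25)
            assert res.loc[met, "q_ad_vs_hc"] < 0.05

    def test_sparse_metabolite_skipped_with_warning(self, metabolome):
        tab, _ = metabolome
        conc = tab.concentrations.copy()
        conc["rare"] = np.nan
        conc.iloc[:5, conc.columns.get_loc("rare")] = 1.0
        with pytest.warns(UserWarning, match="rare"):
            res = metabolite_group_regression(MetabolomeTable(conc, tab.covariates))
        assert "rare" not in res.index

    def test_row_order_invariance(self, metabolome):
        tab, _ = metabolome
        f = filter_detected(tab)
        res1 = metabolite_group_regression(f)
        perm = f.concentrations.sample(frac=1, random_state=3)
        shuffled = MetabolomeTable(perm, f.covariates.loc[perm.index])
        res2 = metabolite_group_regression(shuffled)
        pd.testing.assert_frame_equal(res1.sort_index(), res2.sort_index(), rtol=1e-8)


class TestFractionalRegression:
    def test_planted_enrichment_recovered(self, abundance_data):
        _, ab, cov, truth = abundance_data
        res = fractional_abundance_regression(ab.abundances, cov["group"], cov["apoe"])
        for sp in truth["up"]:
            assert res.loc[sp, "direction"] == "increased"
            assert res.loc[sp, "p"] < 0.05
        for sp in truth["down"]:
            assert res.loc[sp, "direction"] == "decreased"
            assert res.loc[sp, "p"] < 0.05

    def test_constant_taxon_skipped(self, abundance_data):
        _, ab, cov, _ = abundance_data
        df = ab.abundances.copy()
        df.loc["flat_taxon"] = 0.01
        with pytest.warns(UserWarning, match="flat_taxon"):
            res = fractional_abundance_regression(df, cov["group"], cov["apoe"])
        assert "flat_taxon" not in res.index

    def test_presence_filter(self, abundance_data):
        _, ab, cov, _ = abundance_data
        df = ab.abundances.copy()
        rare = np.zeros(df.shape[1])
        rare[: int(0.45 * df.shape[1])] = 0.01  # present in 45% of samples
        df.loc["rare_taxon"] = rare
        res = fractional_abundance_regression(df, cov["group"], cov["apoe"])
        assert "rare_taxon" not in res.index


class TestLogRatio:
    def test_identical_groups_t_near_zero(self):
        counts = pd.DataFrame(
            {f"S{i}": {"a": 10, "b": 20, "c": 30} for i in range(20)}
        )
        group = pd.Series(["HC"] * 10 + ["AD"] * 10, index=counts.columns)
        res = logratio_test(counts, ["a"], ["b"], group)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_equal_sums_give_zero_logratios(self):
        counts = pd.DataFrame({f"S{i}": {"a": 15, "b": 15} for i in range(8)})
        group = pd.Series(["HC"] * 4 + ["AD"] * 4, index=counts.columns)
        res = logratio_test(counts, ["a"], ["b"], group)
        assert np.allclose(res.logratios, 0.0)

    def test_planted_shift_detected(self, abundance_data):
        sp, _, cov, truth = abundance_data
        res = logratio_test(sp.counts, truth["up"], truth["down"], cov["group"])
        assert res.pvalue < 0.01
        assert res.statistic > 0  # up_set enriched in AD

    def test_zero_denominator_samples_excluded(self):
        counts = pd.DataFrame(
            {"S1": {"a": 5, "b": 5}, "S2": {"a": 5, "b": 0}, "S3": {"a": 4, "b": 6},
             "S4": {"a": 6, "b": 4}}
        )
        group = pd.Series(["HC", "HC", "AD", "AD"], index=counts.columns)
        res = logratio_test(counts, ["a"], ["b"], group)
        assert res.n_excluded == 1
        assert "S2" not in res.logratios.index

    def test_overlapping_sets_rejected(self):
        counts = pd.DataFrame({"S1": {"a": 1, "b": 1}})
        with pytest.raises(ValueError):
            logratio_test(counts, ["a"], ["a"], pd.Series({"S1": "AD"}))


class TestFluxRegression:
    def _data(self, n=48, effect=20.0, sd=10.0, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(n)]
        group = pd.Series(["HC"] * (n // 2) + ["AD"] * (n // 2), index=idx)
        apoe = pd.Series(rng.choice(["E3", "E4"], n), index=idx)
        sex = pd.Series(rng.choice(["male", "female"], n), index=idx)
        flux = pd.DataFrame(
            {"for_urine": rng.normal(100, sd, n) + np.where(group == "AD", effect, 0.0)},
            index=idx,
        )
        return flux, group, apoe, sex

    def test_planted_difference_estimated(self):
        flux, group, apoe, sex = self._data()
        res = flux_group_regression(flux, group, apoe, sex)
        assert res.loc["for_urine", "coef_case"] == pytest.approx(20.0, abs=8.0)

    def test_constant_flux_skipped(self):
        flux, group, apoe, sex = self._data()
        flux["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            res = flux_group_regression(flux, group, apoe, sex)
        assert "flat" not in res.index

    def test_confounded_design_flagged(self):
        flux, group, apoe, _ = self._data()
        sex = pd.Series(np.where(group == "AD", "male", "female"), index=group.index)
        with pytest.warns(UserWarning, match="rank"):
            res = flux_group_regression(flux, group, apoe, sex)
        assert res.loc["for_urine", "flag"] == "rank_deficient"
        assert np.isnan(res.loc["for_urine", "coef_case"])


class TestHelpers:
    def test_creatinine_normalise(self):
        raw = pd.DataFrame({"a": [2.0, 4.0]}, index=["S1", "S2"])
        crea = pd.Series([2.0, 8.0], index=["S1", "S2"])
        out = creatinine_normalise(raw, crea)
        assert out["a"].tolist() == [1.0, 0.5]
        with pytest.raises(ValueError):
            creatinine_normalise(raw, pd.Series([0.0, 1.0], index=raw.index))

    def test_demographics_table(self, metabolome):
        tab, _ = metabolome
        cov = tab.covariates.copy()
        cov["group"] = np.where(cov["group"] == "AD", "AD", "HC")
        out = demographics_table(cov)
        assert {"age", "bmi", "sex"} <= set(out.index)
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
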