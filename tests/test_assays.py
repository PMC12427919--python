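"""CETSA fitting, translational-efficiency statistics, dose-response tools."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from translight.assays import (
    ItdrCurve,
    cetsa_hits,
    classify_genes,
    classify_responsiveness,
    comparison_circles,
    curves_from_table,
    delta_te,
    fit_4pl,
    fit_itdr,
    normalize_counts,
    welch_t,
)
from translight.synthetic import (
    DOSE_PANEL_CONCENTRATIONS_UM,
    synth_cetsa,
    synth_ribo,
)

CONC = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])


class TestItdr:
    def test_flat_noiseless_curve_is_null(self):
        fit = fit_itdr(ItdrCurve("P", CONC, np.ones((2, 7))))
        assert abs(fit.amplitude) < 1e-6 and fit.p > 0.5

    def test_noiseless_amplitude_recovery(self):
        y = 1.0 + 0.5 / (1.0 + (3.0 / CONC) ** 1.0)
        fit = fit_itdr(ItdrCurve("P", CONC, np.tile(y, (2, 1))))
        assert fit.amplitude == pytest.approx(0.5, abs=1e-3)
        assert fit.ec50_um == pytest.approx(3.0, rel=1e-2)

    def test_amplitude_above_threshold_with_small_padj_is_target(self):
        tab, _ = synth_cetsa(
            20, {"P0000": 0.25}, noise_cv=0.02, seed=4
        )
        fits = [fit_itdr(c) for c in curves_from_table(tab)]
        targets, volcano = cetsa_hits(fits)
        assert "P0000" in {f.protein_id for f in targets}
        row = volcano.set_index("protein_id").loc["P0000"]
        assert row["p_adj"] < 0.05 and abs(row["amplitude"]) > 0.2

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            ItdrCurve("P", [1.0, 3.0, 10.0], np.ones((1, 3)))

    def test_empty_hit_call(self):
        targets, volcano = cetsa_hits([])
        assert targets == [] and len(volcano) == 0


class TestNormalization:
    def test_identical_columns_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        _, f = normalize_counts(m)
        assert np.allclose(f, 1.0)

    def test_doubled_column_factor_ratio_two(self):
        m = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        norm, f = normalize_counts(m)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        assert np.allclose(norm["a"], norm["b"])

    def test_all_zero_matrix_error(self):
        with pytest.raises(ValueError):
            normalize_counts(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))

    def test_fallback_to_totals_when_no_common_gene(self):
        m = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.warns(UserWarning, match="total-count"):
            normalize_counts(m)


class TestDeltaTe:
    def _cond(self, cols):
        return pd.Series({c: "control" if "ctrl" in c else "treated" for c in cols})

    def test_identical_groups_give_zero_lfc(self):
        counts = pd.DataFrame(
            {"ctrl_1": [100, 50], "ctrl_2": [110, 55],
             "trt_1": [100, 50], "trt_2": [110, 55]},
            index=["g1", "g2"],
        )
        res = delta_te(counts, counts.copy(), self._cond(counts.columns))
        assert np.allclose(res["lfc_mrna"], 0.0)
        assert np.allclose(res["delta_te"], 0.0)

    def test_delta_te_identity_holds_exactly(self):
        mrna, rpf, cond, _ = synth_ribo(300, 30, seed=14)
        res = delta_te(mrna, rpf, cond)
        assert np.allclose(res["delta_te"], res["lfc_rpf"] - res["lfc_mrna"])

    def test_mrna_up_translation_flat_gives_negative_delta_te(self):
        mrna, rpf, cond, truth = synth_ribo(
            400, 40, mrna_lfc=1.5, rpf_lfc=0.0, dispersion=0.01, seed=15
        )
        res = delta_te(mrna, rpf, cond)
        aff = truth.loc[truth.is_positive, "entity_id"]
        assert res.loc[aff, "delta_te"].mean() == pytest.approx(-1.5, abs=0.2)

    def test_unmatched_gene_sets_rejected(self):
        mrna, rpf, cond, _ = synth_ribo(50, 5, seed=16)
        with pytest.raises(ValueError):
            delta_te(mrna.iloc[:-1], rpf, cond)

    def test_permutation_route_runs(self):
        mrna, rpf, cond, _ = synth_ribo(50, 5, seed=17)
        res = delta_te(mrna, rpf, cond, test="permutation", n_perm=99)
        assert res["p_mrna"].between(0, 1).all()


class TestClassification:
    def _frame(self, lm, pm, lr, pr):
        return pd.DataFrame(
            {"lfc_mrna": [lm], "p_mrna": [pm], "lfc_rpf": [lr], "p_rpf": [pr],
             "delta_te": [lr - lm]}, index=["g"]
        )

    @pytest.mark.parametrize(
        "lm,pm,lr,pr,expected",
        [
            (1.5, 1e-4, 0.1, 0.8, "mrna_only"),
            (0.1, 0.8, -1.5, 1e-4, "rpf_only"),
            (1.5, 1e-4, -1.5, 1e-4, "both"),
            (0.2, 0.3, 0.1, 0.6, "none"),
            (1.5, 0.3, 0.1, 0.6, "none"),  # large but not significant
        ],
    )
    def test_class_rules(self, lm, pm, lr, pr, expected):
        out = classify_genes(self._frame(lm, pm, lr, pr))
        assert out["class"].iloc[0] == expected

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_genes(self._frame(0, 1, 0, 1), lfc_threshold=0)


class TestDoseResponse:
    CONC10 = np.array(DOSE_PANEL_CONCENTRATIONS_UM)

    def test_noiseless_pec50_recovery(self):
        y = 0.1 + 0.9 / (1.0 + (self.CONC10 / 3.16) ** 2.0)
        fit = fit_4pl(self.CONC10, y)
        assert fit.pec50 == pytest.approx(5.5, abs=0.02)
        assert fit.hill == pytest.approx(-2.0, rel=1e-3)
        assert fit.top == pytest.approx(1.0, abs=1e-3)
        assert fit.bottom == pytest.approx(0.1, abs=1e-3)

    def test_constant_curve_flagged(self):
        fit = fit_4pl(self.CONC10, np.ones(10))
        assert not fit.converged
        assert not classify_responsiveness(fit)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_4pl(np.array([0.0, 1, 2, 3, 4]), np.ones(5))

    def test_responsiveness_rules(self):
        def mkfit(ec50, hill):
            f = fit_4pl(
                self.CONC10, 0.1 + 0.9 / (1.0 + (self.CONC10 / ec50) ** (-hill))
            )
            return f

        assert classify_responsiveness(mkfit(2.0, -2.0), "methods")
        assert not classify_responsiveness(mkfit(20.0, -2.0), "methods")
        # steep potent curve: the two rules disagree by construction
        steep = mkfit(2.0, -5.0)
        assert not classify_responsiveness(steep, "methods")
        assert classify_responsiveness(steep, "steep")
        with pytest.raises(ValueError):
            classify_responsiveness(steep, "bogus")


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2878, abs=1e-4)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestComparisonCircles:
    def test_equal_means_not_significant(self):
        circles, dec = comparison_circles({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        assert not dec["significant"].any()
        assert all(c.radius > 0 for c in circles)

    def test_matches_tukey_hsd_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = {
                f"g{j}": rng.normal(rng.normal(0, 1.5), 1.0, int(rng.integers(3, 9)))
                for j in range(k)
            }
            _, dec = comparison_circles(groups)
            data = np.concatenate(list(groups.values()))
            labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
            hsd = pairwise_tukeyhsd(data, labels)
            ref = {
                tuple(sorted((str(r[0]), str(r[1])))): bool(r[6])
                for r in hsd.summary().data[1:]
            }
            for row in dec.itertuples():
                key = tuple(sorted((row.group_a, row.group_b)))
                assert ref[key] == row.significant

    def test_two_equal_n_groups_match_pooled_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(29)
        for _ in range(200):
            a = rng.normal(0, 1, 6)
            b = rng.normal(rng.normal(0, 1), 1, 6)
            _, dec = comparison_circles({"a": a, "b": b})
            t_sig = stats.ttest_ind(a, b).pvalue < 0.05
            assert dec["significant"].iloc[0] == t_sig

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            comparison_circles({"a": [1.0], "b": [1.0, 2.0]})
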