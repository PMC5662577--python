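import math

import numpy as np
import pytest
from scipy import stats

import dopplervi as dv
from dopplervi import study


def brute_force_roc(scores, labels):
    """Exhaustive Youden search: every observed value as candidate,
    positive iff score >= cutoff, ties to the lower cutoff."""
    best = None
    for c in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if y and s >= c)
        fn = sum(1 for s, y in zip(scores, labels) if y and s < c)
        tn = sum(1 for s, y in zip(scores, labels) if not y and s < c)
        fp = sum(1 for s, y in zip(scores, labels) if not y and s >= c)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    return best


class TestTwoSampleT:
    # 22%-offset central row of the study: benign (84, 11.9, 15.1),
    # malignant (27, 21.7, 19.6)
    BEN = dv.GroupSummary(84, 11.9, 15.1)
    MAL = dv.GroupSummary(27, 21.7, 19.6)

    def test_welch_matches_hand_formulas_to_1e10(self):
        res = dv.two_sample_t(self.MAL, self.BEN, "welch")
        qa, qb = 19.6**2 / 27, 15.1**2 / 84
        t_hand = (21.7 - 11.9) / math.sqrt(qa + qb)
        df_hand = (qa + qb) ** 2 / (qa**2 / 26 + qb**2 / 83)
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == pytest.approx(df_hand, abs=1e-10)
        assert res.t == pytest.approx(2.380875304820775, abs=1e-10)
        assert res.df == pytest.approx(36.45111853336398, abs=1e-8)
        assert res.p == pytest.approx(0.02261474309454701, abs=1e-12)
        assert res.p < 0.05

    @pytest.mark.parametrize("variant,equal_var", [("welch", False), ("pooled", True)])
    def test_agrees_with_scipy_from_stats(self, variant, equal_var):
        res = dv.two_sample_t(self.MAL, self.BEN, variant)
        ref = stats.ttest_ind_from_stats(
            21.7, 19.6, 27, 11.9, 15.1, 84, equal_var=equal_var
        )
        assert res.t == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_identical_summaries_give_null_result(self):
        g = dv.GroupSummary(10, 5.0, 2.0)
        res = dv.two_sample_t(g, g)
        assert res.t == 0.0 and res.p == 1.0

    def test_degenerate_variance_equal_means(self):
        res = dv.two_sample_t(dv.GroupSummary(5, 3.0, 0.0), dv.GroupSummary(7, 3.0, 0.0))
        assert res.p == 1.0

    def test_degenerate_variance_unequal_means(self):
        res = dv.two_sample_t(dv.GroupSummary(5, 4.0, 0.0), dv.GroupSummary(7, 3.0, 0.0))
        assert res.p == 0.0 and math.isinf(res.t)

    def test_tiny_groups_rejected(self):
        with pytest.raises(dv.ValidationError):
            dv.two_sample_t(dv.GroupSummary(1, 1.0, 0.0), dv.GroupSummary(5, 2.0, 1.0))


class TestOptimumOffset:
    def test_study_summaries_select_22_uniquely(self):
        res = dv.optimum_offset(study.REGIONAL_VI_SUMMARIES, alpha=0.05)
        assert res.selected == 22.0
        assert res.qualifying == (22.0,)
        # recomputed significance pattern: the central difference is
        # significant up to 24%, the peripheral one only at 22% and 25%,
        # so 22% is the unique offset where both coincide
        for pct, (p_per, p_cen) in res.p_values.items():
            assert (p_cen < 0.05) == (pct <= 24)
            assert (p_per < 0.05) == (pct in (22.0, 25.0))

    def test_identical_groups_select_nothing(self):
        g = dv.GroupSummary(20, 10.0, 5.0)
        summaries = {
            pct: dv.RegionalGroupSummaries(g, g, g, g) for pct in (5.0, 10.0, 15.0)
        }
        res = dv.optimum_offset(summaries)
        assert res.selected is None and res.qualifying == ()

    def test_one_region_significant_does_not_qualify(self):
        far = dv.GroupSummary(30, 50.0, 5.0)
        near = dv.GroupSummary(30, 10.0, 5.0)
        summaries = {10.0: dv.RegionalGroupSummaries(near, far, near, near)}
        assert dv.optimum_offset(summaries).selected is None

    def test_bad_alpha_rejected(self):
        with pytest.raises(dv.ValidationError):
            dv.optimum_offset(study.REGIONAL_VI_SUMMARIES, alpha=1.5)


class TestSummarizeCohort:
    def test_known_values(self):
        gsu = dv.GSUFeatures(False, False, False, False)
        recs = [
            dv.NoduleRecord("B1", False, 10.0, {22.0: (10.0, 5.0)}, gsu),
            dv.NoduleRecord("B2", False, 12.0, {22.0: (14.0, 7.0)}, gsu),
            dv.NoduleRecord("M1", True, 20.0, {22.0: (20.0, 15.0)}, gsu),
            dv.NoduleRecord("M2", True, 24.0, {22.0: (26.0, 21.0)}, gsu),
        ]
        s = dv.summarize_cohort(recs)[22.0]
        assert s.peripheral_benign.mean == 12.0
        assert s.peripheral_benign.sd == pytest.approx(np.std([10, 14], ddof=1))
        assert s.central_malignant.mean == 18.0
        assert s.central_malignant.n == 2


class TestRocCutoff:
    def test_perfect_separation(self):
        res = dv.roc_cutoff([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert res.cutoff == 10
        assert res.sensitivity == res.specificity == 1.0
        assert res.auc == 1.0

    def test_identical_scores_degenerate(self):
        res = dv.roc_cutoff([5.0] * 6, [True, False] * 3)
        assert res.youden == 0.0

    @pytest.mark.parametrize("n", [20, 57, 200])
    def test_equals_exhaustive_brute_force(self, n):
        rng = np.random.default_rng(n)
        scores = np.round(rng.uniform(0, 40, n), 1)
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        res = dv.roc_cutoff(scores, labels)
        j, c, sens, spec = brute_force_roc(list(scores), list(labels))
        assert res.cutoff == c
        assert res.youden == pytest.approx(j, abs=1e-12)
        assert (res.sensitivity, res.specificity) == (sens, spec)

    def test_single_class_rejected(self):
        with pytest.raises(dv.ValidationError):
            dv.roc_cutoff([1.0, 2.0], [True, True])


class TestDiagnosticArithmetic:
    def test_gsu_row_metrics(self):
        m = dv.diagnostic_metrics(dv.ConfusionCounts(tp=26, fp=45, tn=39, fn=1)).rounded()
        assert (m.sensitivity, m.specificity, m.npv, m.ppv, m.accuracy) == (
            96.3, 46.4, 97.5, 36.6, 58.6,
        )

    def test_combined_vi_row_accuracy(self):
        m = dv.diagnostic_metrics(dv.ConfusionCounts(tp=19, fp=24, tn=60, fn=8))
        assert dv.round_half_up(m.accuracy) == 71.2

    def test_edge_case_without_positive_calls(self):
        m = dv.diagnostic_metrics(dv.ConfusionCounts(tp=0, fp=0, tn=1, fn=1))
        assert m.sensitivity == 0 and m.specificity == 100
        assert m.accuracy == 50 and m.ppv is None

    @pytest.mark.parametrize(
        "rates,expected",
        [
            ((96.3, 46.4, 27, 84), (26, 45, 39, 1)),
            ((100, 100, 5, 5), (5, 0, 5, 0)),
            ((0, 0, 3, 3), (0, 3, 0, 3)),
        ],
    )
    def test_counts_from_rates(self, rates, expected):
        c = dv.counts_from_rates(*rates)
        assert (c.tp, c.fp, c.tn, c.fn) == expected

    @pytest.mark.parametrize("table", ["SINGLE_VI_PERFORMANCE", "RULE_PERFORMANCE"])
    def test_published_tables_are_internally_consistent(self, table):
        # rates -> integer counts -> recomputed metrics reproduces every
        # published cell at 1 decimal
        for row in getattr(study, table).values():
            counts = dv.counts_from_rates(
                row["sensitivity"], row["specificity"], study.N_MALIGNANT, study.N_BENIGN
            )
            m = dv.diagnostic_metrics(counts).rounded()
            for key in ("sensitivity", "specificity", "npv", "ppv", "accuracy"):
                assert getattr(m, key) == row[key], (table, row, key)

    def test_half_up_rounding_convention(self):
        assert dv.round_half_up(56.25) == 56.3
        assert dv.round_half_up(56.24999) == 56.2


class TestGSUFeatureTest:
    def _cohort(self, k_mal, n_mal, k_ben, n_ben):
        def rec(i, mal, flag):
            return dv.NoduleRecord(
                f"{'M' if mal else 'B'}{i}", mal, None, {},
                dv.GSUFeatures(flag, False, False, False),
            )
        return (
            [rec(i, True, i < k_mal) for i in range(n_mal)]
            + [rec(i, False, i < k_ben) for i in range(n_ben)]
        )

    def test_microcalcification_prevalences(self):
        res = dv.gsu_feature_test(self._cohort(21, 27, 6, 84), "microcalcification")
        assert res.prevalence_malignant == pytest.approx(77.8, abs=0.05)
        assert res.prevalence_benign == pytest.approx(7.1, abs=0.05)
        assert res.p < 0.05

    def test_identical_prevalences_null(self):
        res = dv.gsu_feature_test(self._cohort(5, 10, 5, 10), "microcalcification")
        assert res.chi_square == 0.0 and res.p == 1.0

    def test_perfect_separation_hand_formula(self):
        # 2x2 table (10,0;0,10): chi2 = N (ad-bc)^2 / (r1 r2 c1 c2) = 20
        res = dv.gsu_feature_test(self._cohort(10, 10, 0, 10), "microcalcification")
        assert res.chi_square == pytest.approx(20.0)
        assert res.p < 0.001

    def test_unknown_feature_rejected(self):
        with pytest.raises(dv.ValidationError):
            dv.gsu_feature_test(self._cohort(1, 2, 1, 2), "halo_sign")


class TestCohortIO:
    def test_round_trip_preserves_records(self, tmp_path):
        recs = dv.generate_cohort(dv.CohortSpec(n_benign=5, n_malignant=3, seed=7))
        p = tmp_path / "cohort.csv"
        dv.write_cohort(recs, p)
        back = dv.read_cohort(p)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.nodule_id == b.nodule_id and a.malignant == b.malignant
            assert a.overall_vi == pytest.approx(b.overall_vi)
            assert a.gsu == b.gsu
            for pct in a.vi_by_offset:
                assert a.vi_by_offset[pct] == pytest.approx(b.vi_by_offset[pct])

    def test_missing_vi_round_trips_as_none(self, tmp_path):
        gsu = dv.GSUFeatures(True, False, False, False)
        recs = [dv.NoduleRecord("N1", True, 12.0, {22.0: (17.0, None)}, gsu)]
        p = tmp_path / "c.csv"
        dv.write_cohort(recs, p)
        assert dv.read_cohort(p)[0].vi_by_offset[22.0] == (17.0, None)

    def test_missing_columns_are_a_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("nodule_id,malignant\nA,1\n")
        with pytest.raises(dv.SchemaError):
            dv.read_cohort(p)
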