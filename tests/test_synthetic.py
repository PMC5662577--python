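import numpy as np
import pytest

import dopplervi as dv
from dopplervi import study
from dopplervi.synthetic import DOPPLER_PALETTE


class TestPhantom:
    def test_zero_targets_paint_no_color(self):
        res = dv.generate_phantom(
            dv.PhantomSpec(seed=3, target_peripheral_vi=0, target_central_vi=0)
        )
        assert res.color_count_total == 0
        prof = dv.profile_nodule(res.image, res.roi, 22, mode="distance")
        assert (prof.overall_vi, prof.peripheral_vi, prof.central_vi) == (0, 0, 0)

    def test_full_targets_saturate_the_roi(self):
        res = dv.generate_phantom(
            dv.PhantomSpec(seed=3, target_peripheral_vi=100, target_central_vi=100)
        )
        assert res.color_count_total == res.roi.pixel_count
        prof = dv.profile_nodule(res.image, res.roi, 22, mode="distance")
        assert prof.overall_vi == 100.0

    def test_measured_vi_within_2pp_of_targets(self):
        # region areas >= 1000 px, so Bernoulli sampling error is small
        res = dv.generate_phantom(dv.PhantomSpec(seed=5))
        assert res.partition.peripheral.pixel_count >= 1000
        assert res.partition.central.pixel_count >= 1000
        mask = dv.extract_roi_from_outline(res.image)
        prof = dv.profile_nodule(res.image, mask, 22, mode="distance")
        assert prof.peripheral_vi == pytest.approx(30.0, abs=2.0)
        assert prof.central_vi == pytest.approx(10.0, abs=2.0)

    def test_same_seed_reproduces_same_image(self):
        a = dv.generate_phantom(dv.PhantomSpec(seed=9))
        b = dv.generate_phantom(dv.PhantomSpec(seed=9))
        c = dv.generate_phantom(dv.PhantomSpec(seed=10))
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert not np.array_equal(a.image.pixels, c.image.pixels)

    def test_palette_spreads_exceed_60(self):
        for r, g, b in DOPPLER_PALETTE:
            assert max(r, g, b) - min(r, g, b) >= 60

    def test_blob_too_large_for_frame_rejected(self):
        with pytest.raises(dv.ValidationError):
            dv.generate_phantom(dv.PhantomSpec(height=96, width=96, mean_radius=60))

    def test_infeasible_target_in_empty_region_rejected(self):
        with pytest.raises(dv.ValidationError, match="infeasible"):
            dv.generate_phantom(
                dv.PhantomSpec(seed=1, offset_pct=60, target_central_vi=10)
            )


class TestCohort:
    def test_zero_sd_pins_values_to_the_means(self):
        g = dv.GroupSummary
        summaries = {
            22.0: dv.RegionalGroupSummaries(
                g(84, 18.2, 0.0), g(27, 26.5, 0.0), g(84, 11.9, 0.0), g(27, 21.7, 0.0)
            )
        }
        recs = dv.generate_cohort(
            dv.CohortSpec(
                regional_summaries=summaries,
                overall_benign=g(84, 16.6, 0.0),
                overall_malignant=g(27, 23.8, 0.0),
                seed=2,
            )
        )
        for r in recs:
            per, cen = r.vi_by_offset[22.0]
            if r.malignant:
                assert (per, cen, r.overall_vi) == (26.5, 21.7, 23.8)
            else:
                assert (per, cen, r.overall_vi) == (18.2, 11.9, 16.6)

    def test_prevalence_one_sets_feature_everywhere(self):
        spec = dv.CohortSpec(
            gsu_prevalence_malignant={**study.GSU_PREVALENCE_MALIGNANT,
                                      "microcalcification": 1.0},
            seed=4,
        )
        recs = dv.generate_cohort(spec)
        assert all(r.gsu.microcalcification for r in recs if r.malignant)

    def test_sample_means_follow_the_law_of_large_numbers(self):
        # parameters far from the [0, 100] bounds, so truncation is inert
        # and sample group means must sit within a few SEs of the spec
        g = dv.GroupSummary
        summaries = {
            10.0: dv.RegionalGroupSummaries(
                g(400, 50.0, 10.0), g(400, 60.0, 10.0),
                g(400, 40.0, 10.0), g(400, 55.0, 10.0),
            )
        }
        recs = dv.generate_cohort(
            dv.CohortSpec(
                n_benign=400, n_malignant=400,
                regional_summaries=summaries,
                overall_benign=g(400, 45.0, 8.0), overall_malignant=g(400, 58.0, 8.0),
                seed=6,
            )
        )
        got = dv.summarize_cohort(recs)[10.0]
        se = 10.0 / np.sqrt(400)
        assert got.peripheral_benign.mean == pytest.approx(50.0, abs=3 * se)
        assert got.peripheral_malignant.mean == pytest.approx(60.0, abs=3 * se)
        assert got.central_benign.mean == pytest.approx(40.0, abs=3 * se)
        assert got.central_malignant.mean == pytest.approx(55.0, abs=3 * se)
        assert got.peripheral_benign.sd == pytest.approx(10.0, rel=0.15)

    def test_truncation_resamples_into_bounds(self):
        recs = dv.generate_cohort(dv.CohortSpec(seed=8))
        for r in recs:
            assert 0.0 <= r.overall_vi <= 100.0
            for per, cen in r.vi_by_offset.values():
                assert 0.0 <= per <= 100.0 and 0.0 <= cen <= 100.0

    def test_values_correlated_across_offsets_within_a_nodule(self):
        # shared latent factor: a nodule's central VI at 5% and 25% offsets
        # must be positively correlated across the cohort
        recs = dv.generate_cohort(dv.CohortSpec(n_benign=300, n_malignant=2, seed=12))
        ben = [r for r in recs if not r.malignant]
        a = np.array([r.vi_by_offset[5.0][1] for r in ben])
        b = np.array([r.vi_by_offset[25.0][1] for r in ben])
        assert np.corrcoef(a, b)[0, 1] > 0.2

    def test_seed_determinism(self):
        a = dv.generate_cohort(dv.CohortSpec(seed=5))
        b = dv.generate_cohort(dv.CohortSpec(seed=5))
        assert all(
            x.overall_vi == y.overall_vi and x.gsu == y.gsu for x, y in zip(a, b)
        )
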