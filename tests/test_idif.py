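"""IDIF extraction, merged-TAC CSV workflow, gap model, plasma integral."""

import io

import numpy as np
import pytest

from wbpatlak import (GapModel, InputFunction, KineticParams, NoiseModel,
                      PhantomSpec, Region, TimeActivityCurve, build_schedule,
                      cumulative_plasma_integral, extract_idif, feng4_default,
                      fit_gap_model, frame_average, integrate_input,
                      merge_tacs, read_tac_csv, render_phantom, split_tac,
                      write_tac_csv)
from wbpatlak.idif import GapFitError


def aorta_phantom():
    regions = (
        Region("tissue", "sphere", (4, 4, 4), 12.0,
               params=KineticParams(0.08, 0.2, 0.05, 0.05)),
        Region("aorta", "box", bounds=((8, 11), (8, 12), (0, 4)), params=None),
    )
    return PhantomSpec((16, 16, 16), 4.0, regions, "aorta", 5.5)


class TestExtractIdif:
    def test_noiseless_idif_equals_frame_averaged_input(self, feng,
                                                        two_short_schedule):
        spec = aorta_phantom()
        img = render_phantom(spec, feng, two_short_schedule, None)
        idif = extract_idif(img, spec.masks()["aorta"])
        truth = frame_average(feng, two_short_schedule).activity
        assert np.allclose(idif.activity, truth, rtol=1e-12)

    def test_single_voxel_voi_returns_that_voxel(self, feng, two_short_schedule):
        spec = aorta_phantom()
        img = render_phantom(spec, feng, two_short_schedule, NoiseModel(0.5, 2))
        mask = np.zeros((16, 16, 16), bool)
        mask[9, 9, 2] = True
        idif = extract_idif(img, mask)
        assert np.array_equal(idif.activity, img.data[9, 9, 2])

    def test_voi_averaging_shrinks_noise_roughly_sqrt_n(self, feng,
                                                        two_short_schedule):
        spec = aorta_phantom()
        truth = frame_average(feng, two_short_schedule).activity
        mask100 = spec.masks()["aorta"]          # 100 voxels
        assert mask100.sum() == 100
        mask1 = np.zeros_like(mask100)
        mask1[9, 9, 2] = True
        err100, err1 = [], []
        for seed in range(40):
            img = render_phantom(spec, feng, two_short_schedule,
                                 NoiseModel(0.5, seed))
            err100.append(extract_idif(img, mask100).activity[-1] - truth[-1])
            err1.append(extract_idif(img, mask1).activity[-1] - truth[-1])
        ratio = np.std(err1) / np.std(err100)
        assert 5.0 < ratio < 20.0                # ~10x for 100 voxels

    def test_empty_voi_rejected(self, feng, two_short_schedule):
        spec = aorta_phantom()
        img = render_phantom(spec, feng, two_short_schedule, None)
        with pytest.raises(ValueError, match="empty"):
            extract_idif(img, np.zeros((16, 16, 16), bool))


class TestMergeAndCsv:
    def test_merge_then_split_recovers_inputs(self, feng, two_short_schedule):
        tac = frame_average(feng, two_short_schedule, source="aorta_idif")
        early, late = split_tac(tac, at=6.0)
        merged = merge_tacs(early, late)
        e2, l2 = split_tac(merged, at=6.0)
        assert np.array_equal(e2.activity, early.activity)
        assert np.array_equal(l2.frame_start, late.frame_start)

    def test_csv_round_trip_is_bit_exact(self, merged_idif_triexp):
        buf = io.StringIO()
        write_tac_csv(merged_idif_triexp, buf)
        back = read_tac_csv(io.StringIO(buf.getvalue()))
        assert np.array_equal(back.activity, merged_idif_triexp.activity)
        assert np.array_equal(back.frame_start, merged_idif_triexp.frame_start)
        assert np.array_equal(back.frame_end, merged_idif_triexp.frame_end)

    def test_merged_curve_matches_standard_idif_on_shared_frames(
            self, feng, standard_schedule, merged_idif_triexp):
        std = frame_average(feng, standard_schedule, source="aorta_idif")
        tsd = frame_average(feng, build_schedule("two_short"),
                            source="aorta_idif")
        merged = merge_tacs(*split_tac(tsd, at=6.0))
        shared = [i for i, fr in enumerate(standard_schedule.frames)
                  if fr in build_schedule("two_short").frames]
        assert np.allclose(std.activity[shared], merged.activity, rtol=1e-12)

    def test_overlapping_merge_rejected(self, feng, standard_schedule):
        tac = frame_average(feng, standard_schedule, source="aorta_idif")
        with pytest.raises(ValueError, match="overlap"):
            merge_tacs(tac, tac)


class TestFitGapModel:
    def test_recovers_triexponential_rates_from_two_windows(
            self, triexp_input, merged_idif_triexp):
        gap = fit_gap_model(merged_idif_triexp, "tri_exponential")
        fitted = np.sort(gap.rates)[::-1]
        truth = np.array([3.0, 0.12, 0.010])
        assert np.allclose(fitted, truth, rtol=0.01)

    def test_constant_tac_reduces_to_flat_model(self):
        t = np.arange(20.0)
        tac = TimeActivityCurve(t, t + 1.0, np.full(20, 4.2), "merged")
        gap = fit_gap_model(tac, "tri_exponential")
        assert gap.curve(10.0) == pytest.approx(4.2, rel=1e-3)
        assert gap.integral(0.0, 10.0) == pytest.approx(42.0, rel=1e-3)

    def test_noisy_fits_agree_at_late_times_within_noise_scale(
            self, feng, two_short_schedule):
        spec = aorta_phantom()
        curves = []
        for seed in (1, 2):
            img = render_phantom(spec, feng, two_short_schedule,
                                 NoiseModel(0.5, seed))
            idif = extract_idif(img, spec.masks()["aorta"])
            gap = fit_gap_model(merge_tacs(*split_tac(idif, 6.0)))
            curves.append(gap.curve(np.linspace(60, 75, 16)))
        level = feng.evaluate(67.5)
        assert np.max(np.abs(curves[0] - curves[1])) < 0.1 * level

    def test_too_few_samples_rejected(self):
        tac = TimeActivityCurve([0.0, 1.0], [1.0, 2.0], [5.0, 4.0], "merged")
        with pytest.raises(GapFitError):
            fit_gap_model(tac)

    def test_json_round_trip(self, merged_idif_triexp):
        gap = fit_gap_model(merged_idif_triexp)
        back = GapModel.from_json(gap.to_json())
        assert back.family == gap.family
        assert np.allclose(back.rates, gap.rates)
        assert back.curve(30.0) == pytest.approx(gap.curve(30.0))

    def test_input_model_refit_recovers_feng_curve(self, feng,
                                                   two_short_schedule):
        tac = frame_average(feng, two_short_schedule, source="aorta_idif")
        merged = merge_tacs(*split_tac(tac, 6.0))
        gap = fit_gap_model(merged, "input_model_refit")
        t = np.linspace(8.0, 58.0, 26)
        assert np.allclose(gap.curve(t), feng.evaluate(t), rtol=0.01)


class TestCumulativePlasmaIntegral:
    def test_fully_sampled_constant_gives_ct(self):
        t = np.arange(10.0)
        tac = TimeActivityCurve(t, t + 1.0, np.full(10, 2.0), "aorta_idif")
        assert cumulative_plasma_integral(tac, None, 7.5) == pytest.approx(15.0)

    def test_zero_time_gives_zero(self, merged_idif_triexp):
        gap = fit_gap_model(merged_idif_triexp)
        assert cumulative_plasma_integral(merged_idif_triexp, gap, 0.0) == 0.0

    def test_gap_bridged_integral_matches_exact_within_two_percent(
            self, triexp_input, merged_idif_triexp):
        gap = fit_gap_model(merged_idif_triexp)
        got = cumulative_plasma_integral(merged_idif_triexp, gap, 67.5)
        exact = integrate_input(triexp_input, 67.5)
        assert got == pytest.approx(exact, rel=0.02)

    def test_monotone_and_continuous_across_gap_boundaries(
            self, merged_idif_triexp):
        gap = fit_gap_model(merged_idif_triexp)
        t = np.linspace(0.0, 75.0, 1501)
        vals = np.array([cumulative_plasma_integral(merged_idif_triexp, gap, x)
                         for x in t])
        assert np.all(np.diff(vals) >= -1e-9)
        for edge in (6.0, 60.0):
            lo = cumulative_plasma_integral(merged_idif_triexp, gap, edge - 1e-6)
            hi = cumulative_plasma_integral(merged_idif_triexp, gap, edge + 1e-6)
            assert hi - lo < 1e-3

    def test_gap_without_model_raises(self, merged_idif_triexp):
        with pytest.raises(ValueError, match="gap"):
            cumulative_plasma_integral(merged_idif_triexp, None, 30.0)

    def test_standard_and_two_short_integrals_agree_noiseless(
            self, triexp_input, standard_schedule, merged_idif_triexp):
        # the mechanism behind near-unity protocol agreement
        std = frame_average(triexp_input, standard_schedule,
                            source="aorta_idif")
        gap = fit_gap_model(merged_idif_triexp)
        for t in (62.5, 67.5, 72.5):
            a = cumulative_plasma_integral(std, None, t)
            b = cumulative_plasma_integral(merged_idif_triexp, gap, t)
            assert abs(b / a - 1) < 0.02
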