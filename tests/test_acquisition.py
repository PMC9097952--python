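"""Frame schedules, exact frame averaging, phantom rendering and noise."""

import numpy as np
import pytest
from scipy.integrate import quad

from wbpatlak import (InputFunction, KineticParams, NoiseModel, PhantomSpec,
                      Region, build_schedule, frame_average, load_dynamic,
                      render_phantom, save_dynamic)


class TestBuildSchedule:
    def test_last_three_frames_cover_60_to_75(self, standard_schedule):
        assert standard_schedule.frames[-3:] == ((60.0, 65.0), (65.0, 70.0),
                                                 (70.0, 75.0))

    def test_two_short_covers_first_six_and_last_fifteen_minutes(
            self, two_short_schedule):
        starts = two_short_schedule.starts
        ends = two_short_schedule.ends
        early = ends <= 6.0 + 1e-9
        assert starts[0] == 0.0 and ends[early][-1] == pytest.approx(6.0)
        assert tuple(two_short_schedule.frames[-3:]) == ((60.0, 65.0),
                                                         (65.0, 70.0),
                                                         (70.0, 75.0))

    def test_whole_body_pass_structure(self, standard_schedule):
        durs = standard_schedule.durations
        assert int(np.sum(np.isclose(durs, 2.0))) == 5
        assert int(np.sum(np.isclose(durs, 5.0))) == 11

    def test_cardiac_subframes_tile_first_six_minutes(self, standard_schedule):
        early = [f for f in standard_schedule.frames if f[1] <= 6.0 + 1e-9]
        assert early[0][0] == 0.0
        assert early[-1][1] == pytest.approx(6.0)
        for (s0, e0), (s1, e1) in zip(early, early[1:]):
            assert s1 == pytest.approx(e0)

    def test_two_short_is_subset_of_standard(self, standard_schedule,
                                             two_short_schedule):
        assert set(two_short_schedule.frames) <= set(standard_schedule.frames)


class _LinearCurve:
    """a*t with its exact integral — a frame-averaging oracle helper."""

    def __init__(self, a):
        self.a = a

    def integral(self, t):
        return self.a * np.asarray(t, float) ** 2 / 2


class TestFrameAverage:
    def test_constant_curve_gives_constant_frames(self, standard_schedule):
        f = InputFunction("tri_exponential", {"amplitudes": [3.0], "rates": [0.0]},
                          t_peak_offset=0.0)
        tac = frame_average(f, standard_schedule)
        assert np.allclose(tac.activity, 3.0, rtol=1e-12)

    def test_linear_curve_gives_midpoint_values(self, standard_schedule):
        tac = frame_average(_LinearCurve(2.0), standard_schedule)
        assert np.allclose(tac.activity, 2.0 * tac.midpoints, rtol=1e-12)

    def test_matches_quadrature_per_frame(self, feng, standard_schedule):
        tac = frame_average(feng, standard_schedule)
        for (s, e), v in zip(standard_schedule.frames, tac.activity):
            ref = quad(lambda x: feng.evaluate(x), s, e, limit=200)[0] / (e - s)
            assert v == pytest.approx(ref, rel=1e-8)


def tiny_phantom(vb_only=False):
    p = (KineticParams(0.0, 0.1, 0.0, 0.0) if vb_only else
         KineticParams(0.08, 0.2, 0.05, 0.05))
    regions = (
        Region("tissue", "sphere", (4, 4, 4), 14.0, params=p),
        Region("cold", "sphere", (11, 11, 11), 10.0,
               params=KineticParams(0.0, 0.1, 0.0, 0.0)),
        Region("aorta", "box", bounds=((4, 5), (10, 11), (2, 12)), params=None),
    )
    return PhantomSpec((16, 16, 16), 4.0, regions, "aorta", 5.5)


class TestRenderPhantom:
    def test_noiseless_aorta_voxels_carry_frame_averaged_input(
            self, feng, two_short_schedule):
        spec = tiny_phantom()
        img = render_phantom(spec, feng, two_short_schedule, None)
        cp = frame_average(feng, two_short_schedule).activity
        mask = spec.masks()["aorta"]
        assert np.allclose(img.data[mask], cp[None, :], rtol=1e-12)

    def test_zero_kinetics_region_is_zero_without_noise(
            self, feng, two_short_schedule):
        spec = tiny_phantom()
        img = render_phantom(spec, feng, two_short_schedule, None)
        assert np.all(img.data[spec.masks()["cold"]] == 0.0)

    def test_same_seed_reproduces_bitwise(self, feng, two_short_schedule):
        spec = tiny_phantom()
        a = render_phantom(spec, feng, two_short_schedule, NoiseModel(0.4, 11))
        b = render_phantom(spec, feng, two_short_schedule, NoiseModel(0.4, 11))
        assert np.array_equal(a.data, b.data)

    def test_restricting_standard_equals_simulating_two_short(
            self, feng, standard_schedule, two_short_schedule):
        # both protocol arms come from one simulated session: shared frames
        # carry identical values, noise included
        spec = tiny_phantom()
        noise = NoiseModel(0.4, 23)
        full = render_phantom(spec, feng, standard_schedule, noise)
        direct = render_phantom(spec, feng, two_short_schedule, noise)
        sub = full.restrict([(0.0, 6.0), (60.0, 75.0)])
        assert sub.schedule.frames == direct.schedule.frames
        assert np.array_equal(sub.data, direct.data)

    def test_noise_sd_scales_inversely_with_sqrt_frame_duration(self, feng):
        from wbpatlak.acquisition import FrameSchedule
        sched = FrameSchedule(((60.0, 61.0), (61.0, 65.0)), "standard")
        spec = PhantomSpec(
            (16, 16, 16), 4.0,
            (Region("tissue", "box", bounds=((0, 15), (0, 15), (0, 13)),
                    params=KineticParams(0.08, 0.2, 0.05, 0.05)),
             Region("aorta", "box", bounds=((0, 15), (0, 15), (14, 15)),
                    params=None)),
            "aorta", 5.5)
        noiseless = render_phantom(spec, feng, sched, None)
        noisy = render_phantom(spec, feng, sched, NoiseModel(0.5, 3))
        mask = spec.masks()["tissue"]
        resid = (noisy.data - noiseless.data)[mask]      # ~3,600 draws/frame
        sd_ratio = resid[:, 0].std() / resid[:, 1].std()
        assert sd_ratio == pytest.approx(2.0, rel=0.05)  # sqrt(4 min / 1 min)

    def test_overlapping_regions_rejected(self, feng, two_short_schedule):
        spec = PhantomSpec(
            (16, 16, 16), 4.0,
            (Region("a", "sphere", (8, 8, 8), 20.0,
                    params=KineticParams(0.1, 0.2, 0.05, 0.05)),
             Region("b", "sphere", (9, 8, 8), 20.0,
                    params=KineticParams(0.1, 0.2, 0.05, 0.05)),
             Region("aorta", "box", bounds=((0, 1), (0, 1), (0, 1)),
                    params=None)),
            "aorta", 5.5)
        with pytest.raises(ValueError, match="overlap"):
            render_phantom(spec, feng, two_short_schedule, None)


class TestNiftiRoundTrip:
    def test_save_load_preserves_data_schedule_and_meta(
            self, feng, two_short_schedule, tmp_path):
        img = render_phantom(tiny_phantom(), feng, two_short_schedule,
                             NoiseModel(0.3, 5))
        save_dynamic(img, tmp_path / "dyn.nii")
        back = load_dynamic(tmp_path / "dyn.nii")
        assert back.schedule.frames == img.schedule.frames
        assert back.meta["seed"] == 5
        assert np.allclose(back.data, img.data, rtol=1e-6)  # float32 storage
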