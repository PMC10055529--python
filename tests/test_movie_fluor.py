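"""Two-channel movie rendering, demultiplexing and ΔF/F extraction."""

import numpy as np
import pytest

from flodm.acquisition import AcquisitionSpec
from flodm.fluor import (
    CircularRoi,
    ManifestError,
    RoiSet,
    compute_dff,
    demultiplex,
    extract_roi_traces,
    ratio_image,
    unmix,
)
from flodm.synthetic.movie import (
    interleaved_schedule,
    make_expression_field,
    render_two_channel_movie,
)


@pytest.fixture()
def field():
    return make_expression_field(shape=(48, 64), n_rois=3, roi_radius_px=5,
                                 seed=4)


def _zero_dff(field, T):
    return {c: np.zeros((field.n_rois(c), T)) for c in ("green", "red")}


class TestMovieRender:
    def test_quiet_identity_render_reproduces_baselines(self, field):
        acq = AcquisitionSpec(crosstalk=((1.0, 0.0), (0.0, 1.0)))
        times = np.arange(-2, 3.0, 0.5)
        frames, manifest = render_two_channel_movie(
            _zero_dff(field, times.size), field, acq, times, noise=False
        )
        np.testing.assert_allclose(frames[0], field.baseline["green"])
        np.testing.assert_allclose(frames[1], field.baseline["red"])
        np.testing.assert_allclose(frames[-2], field.baseline["green"])

    def test_crosstalk_bleeds_red_activity_into_green(self, field):
        # closed-form mixing: green pixel gains 0.1 x red dFF x red baseline
        acq = AcquisitionSpec(crosstalk=((0.9, 0.1), (0.1, 0.9)))
        times = np.array([-1.0, 5.0])
        dff = _zero_dff(field, 2)
        dff["red"][0, 1] = 10.0  # red ROI 1 up 10% at t=5
        frames, _ = render_two_channel_movie(dff, field, acq, times, noise=False)
        mask = field.roi_mask("red", 1) & (field.labels["green"] == 0)
        green_gain = frames[2][mask].mean() - frames[0][mask].mean()
        expected = 0.1 * 0.10 * field.baseline["red"][mask].mean()
        assert green_gain == pytest.approx(expected, rel=1e-6)

    def test_80fps_schedule_same_channel_spacing(self):
        acq = AcquisitionSpec(frame_rate_fluor_hz=80.0)
        sched = interleaved_schedule(40, acq)
        greens = [f["t_sec"] for f in sched if f["channel"] == "green"]
        assert np.allclose(np.diff(greens), 0.025)

    def test_photon_conservation_under_row_stochastic_mixing(self, field):
        # total green+red counts per pixel equal the unmixed render's total
        times = np.arange(0, 2.0, 0.5)
        dff = _zero_dff(field, times.size)
        dff["green"][:, :] = 5.0
        dff["red"][:, :] = -3.0
        mixed, _ = render_two_channel_movie(
            dff, field, AcquisitionSpec(crosstalk=((0.9, 0.1), (0.1, 0.9))),
            times, noise=False,
        )
        unmixed, _ = render_two_channel_movie(
            dff, field, AcquisitionSpec(crosstalk=((1.0, 0.0), (0.0, 1.0))),
            times, noise=False,
        )
        np.testing.assert_allclose(
            mixed[0] + mixed[1], unmixed[0] + unmixed[1], rtol=1e-12
        )

    def test_mask_shape_mismatch_raises(self, field):
        times = np.arange(0, 2.0, 0.5)
        dff = _zero_dff(field, times.size)
        dff["red"] = dff["red"][:, :-1]
        with pytest.raises(ValueError, match="mismatch"):
            render_two_channel_movie(dff, field, AcquisitionSpec(), times)


class TestDemultiplex:
    def test_round_trip_preserves_channel_frames(self, field):
        acq = AcquisitionSpec()
        times = np.arange(-2, 2.0, 0.5)
        frames, manifest = render_two_channel_movie(
            _zero_dff(field, times.size), field, acq, times, seed=9
        )
        split = demultiplex(frames, manifest)
        assert len(split["green"]["frames"]) + len(split["red"]["frames"]) == len(
            frames
        )
        np.testing.assert_array_equal(split["green"]["frames"], frames[0::2])
        np.testing.assert_array_equal(split["red"]["frames"], frames[1::2])
        np.testing.assert_allclose(split["green"]["t_min"], times)

    def test_degenerate_all_green_schedule_warns(self, field):
        frames = np.ones((4, 8, 8))
        manifest = {
            "frames": [
                {"index": i, "channel": "green", "t_sec": i * 0.0125,
                 "t_min": i * 0.5}
                for i in range(4)
            ]
        }
        with pytest.warns(UserWarning, match="red"):
            split = demultiplex(frames, manifest)
        assert split["red"]["frames"].shape[0] == 0

    def test_schedule_gap_raises_manifest_error(self):
        frames = np.ones((4, 8, 8))
        manifest = {"frames": [{"index": 0, "channel": "green", "t_sec": 0.0}]}
        with pytest.raises(ManifestError, match="missing"):
            demultiplex(frames, manifest)


class TestDff:
    def test_simple_arithmetic(self):
        movie = np.full((12, 4, 4), 100.0)
        t = np.arange(-5, 1.0, 0.5)
        movie[-1] = 103.0
        dff = compute_dff(movie, t, baseline_window=(-5, -0.5))
        assert dff[-1, 0, 0] == pytest.approx(3.0)

    def test_constant_movie_is_zero_and_bleach_flat(self):
        movie = np.full((10, 4, 4), 50.0)
        t = np.arange(-5, 0.0, 0.5)
        dff = compute_dff(movie, t, baseline_window=(-5, -2), bleach_correct=True)
        np.testing.assert_allclose(dff, 0.0, atol=1e-9)

    def test_gain_invariance(self, rng):
        movie = 100.0 + rng.random((20, 6, 6)) * 50
        t = np.arange(-5, 5.0, 0.5)
        a = compute_dff(movie, t)
        b = compute_dff(movie * 7.3, t)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_baseline_centering(self, rng):
        movie = 100.0 + rng.normal(0, 3, size=(40, 5, 5))
        t = np.arange(-10, 10.0, 0.5)
        dff = compute_dff(movie, t, baseline_window=(-10, 0))
        base = (t >= -10) & (t <= 0)
        np.testing.assert_allclose(dff[base].mean(axis=0), 0.0, atol=1e-9)

    def test_bleach_correction_recovers_flat_baseline(self):
        t = np.arange(-10, 20.0, 0.5)
        decay = np.exp(-0.01 * (t - t[0]))
        movie = 200.0 * decay[:, None, None] * np.ones((t.size, 4, 4))
        dff = compute_dff(movie, t, bleach_correct=True)
        np.testing.assert_allclose(dff, 0.0, atol=0.05)

    def test_nonpositive_baseline_masked_with_warning(self):
        movie = np.full((10, 3, 3), 10.0)
        movie[:, 1, 1] = 0.0
        t = np.arange(-5, 0.0, 0.5)
        with pytest.warns(UserWarning, match="non-positive"):
            dff = compute_dff(movie, t, baseline_window=(-5, -0.5))
        assert np.isnan(dff[:, 1, 1]).all()


class TestRatioImage:
    def test_baseline_post_is_near_zero(self, rng):
        movie = 100.0 + rng.normal(0, 0.5, size=(30, 6, 6))
        t = np.arange(-10, 5.0, 0.5)
        img = ratio_image(movie, t, t_post=-5.0)
        assert np.abs(img).max() < 2.0

    def test_out_of_span_post_time_raises(self):
        movie = np.full((10, 3, 3), 1.0)
        t = np.arange(-5, 0.0, 0.5)
        with pytest.raises(ValueError, match="outside"):
            ratio_image(movie, t, t_post=40.0)

    def test_suppression_is_negative_in_expressing_mask_only(self, field):
        # clozapine-like: astrocytic (green) dFF drops, background unchanged
        times = np.arange(-10, 30.0, 0.5)
        dff = _zero_dff(field, times.size)
        dff["green"][:, times > 5] = -10.0
        frames, manifest = render_two_channel_movie(
            dff, field, AcquisitionSpec(crosstalk=((1.0, 0.0), (0.0, 1.0))),
            times, noise=False,
        )
        green = demultiplex(frames, manifest)["green"]
        img = ratio_image(green["frames"], green["t_min"], t_post=25.0)
        roi = field.labels["green"] > 0
        assert img[roi].mean() == pytest.approx(-10.0, abs=0.2)
        assert abs(img[~roi]).max() < 0.2


class TestRoiTraces:
    def test_uniform_frame_value_reproduced(self):
        dff_movie = np.full((8, 20, 20), 2.0)
        t = np.arange(0, 4.0, 0.5)
        rois = RoiSet(rois=(CircularRoi("r1", "green", 10, 10, 4),))
        out = extract_roi_traces(dff_movie, t, rois)
        np.testing.assert_allclose(out.value, 2.0)

    def test_overlapping_roi_mixes_by_area(self):
        dff_movie = np.zeros((4, 10, 20))
        dff_movie[:, :, :10] = 4.0  # left half at 4%, right at 0%
        t = np.arange(0, 2.0, 0.5)
        label = np.zeros((10, 20), dtype=int)
        label[4, 8:12] = 1  # 2 px in each half
        rois = RoiSet.from_labels(label, "green")
        out = extract_roi_traces(dff_movie, t, rois)
        np.testing.assert_allclose(out.value, 2.0)  # area-weighted mixture

    def test_empty_roi_raises_with_name(self):
        dff_movie = np.zeros((4, 10, 10))
        t = np.arange(0, 2.0, 0.5)
        label = np.zeros((10, 10), dtype=int)
        label[0, 0] = 2  # roi 1 missing entirely
        rois = RoiSet.from_labels(label, "green")
        with pytest.raises(ValueError, match="roi1"):
            extract_roi_traces(dff_movie, t, rois)

    def test_crosstalk_artifact_bounded_by_mixing_coefficient(self):
        # red-only event with 10% crosstalk in a co-expressing region:
        # the induced green-trace artifact is at most 0.1x the red amplitude
        from flodm.synthetic.movie import ExpressionField, make_expression_field

        base = make_expression_field(shape=(48, 64), n_rois=3,
                                     roi_radius_px=5, seed=4)
        field = ExpressionField(
            shape=base.shape,
            labels={"green": base.labels["red"], "red": base.labels["red"]},
            baseline={"green": base.baseline["red"],
                      "red": base.baseline["red"]},
        )
        acq = AcquisitionSpec(crosstalk=((0.9, 0.1), (0.1, 0.9)))
        times = np.arange(-10, 20.0, 0.5)
        dff = _zero_dff(field, times.size)
        dff["red"][:, times > 0] = 8.0
        frames, manifest = render_two_channel_movie(dff, field, acq, times,
                                                    noise=False)
        green = demultiplex(frames, manifest)["green"]
        gdff = compute_dff(green["frames"], green["t_min"])
        rois = field.labels["red"] > 0
        artifact = gdff[:, rois].mean(axis=1).max()
        assert 0 < artifact <= 0.1 * 8.0 + 1e-9

    def test_unmix_inverts_declared_matrix(self, rng):
        M = ((0.9, 0.1), (0.15, 0.85))
        g_true = rng.random((4, 4)) + 1
        r_true = rng.random((4, 4)) + 1
        g_mix = 0.9 * g_true + 0.1 * r_true
        r_mix = 0.15 * g_true + 0.85 * r_true
        g, r = unmix(g_mix, r_mix, M)
        np.testing.assert_allclose(g, g_true, atol=1e-12)
        np.testing.assert_allclose(r, r_true, atol=1e-12)
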