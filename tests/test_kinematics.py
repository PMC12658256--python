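"""Contour, midline, excursion and spectrogram-tracking behaviour."""

import numpy as np
import pytest
from scipy.signal import stft

import finlogger as fl
from finlogger.errors import AmbiguousDetection, NoFishDetected
from finlogger.kinematics import _parabolic_peak  # noqa: F401  (used indirectly)


def _ellipse_frame(a=100, b=25, shape=(200, 400), level=30, bg=230):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cx, cy = shape[1] / 2, shape[0] / 2
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    frame = np.full(shape, bg, dtype=np.uint8)
    frame[mask] = level
    return frame


class TestDetectFishContour:
    def test_blank_frame_raises_no_fish(self):
        with pytest.raises(NoFishDetected):
            fl.detect_fish_contour(np.full((100, 100), 230, dtype=np.uint8))

    def test_ellipse_area_and_ratio(self):
        contour = fl.detect_fish_contour(_ellipse_frame(),
                                         area_range=(1000, 1e6),
                                         ratio_range=(2, 10))
        assert contour.area == pytest.approx(np.pi * 100 * 25, rel=0.02)
        assert contour.length_width_ratio == pytest.approx(4.0, rel=0.05)

    def test_small_speck_rejected_fish_kept(self):
        frame = _ellipse_frame()
        frame[5:9, 5:9] = 10  # dark speck below the area filter
        contour = fl.detect_fish_contour(frame, area_range=(1000, 1e6),
                                         ratio_range=(2, 10))
        assert contour.area == pytest.approx(np.pi * 100 * 25, rel=0.02)

    def test_two_passing_objects_is_ambiguous(self):
        frame = _ellipse_frame(shape=(400, 400))
        frame[300:360, :] = _ellipse_frame(shape=(400, 400))[170:230, :]
        with pytest.raises(AmbiguousDetection):
            fl.detect_fish_contour(frame, area_range=(1000, 1e6),
                                   ratio_range=(2, 10))


class TestExtractMidline:
    def test_straight_silhouette_midline_is_collinear(self):
        spec = fl.SwimmerSpec(tail_beat_amp=0.0, head_yaw_amp=0.0,
                              opercular_amp=0.0)
        frames, truth = fl.generate_swim_video(spec, duration=1.0, seed=0)
        ar, rr = fl.kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        contour = fl.detect_fish_contour(frames.frames[0], area_range=ar,
                                         ratio_range=rr)
        midline = fl.extract_midline(contour)
        assert np.ptp(midline.points[:, 1]) < 1.0

    def test_sinusoidal_midline_recovered_within_one_pixel(self, default_video):
        _, _, truth, track = default_video
        i = 30
        est = track.points[i]
        truth_y = np.interp(est[:, 0], truth["midline"][i][:, 0],
                            truth["midline"][i][:, 1])
        rmse = np.sqrt(np.mean((est[:, 1] - truth_y) ** 2))
        assert rmse < 1.0

    def test_head_is_the_wider_end(self, default_video):
        _, _, truth, track = default_video
        # generator stores midlines head-first; extracted head x must match
        assert abs(track.points[0, 0, 0] - truth["midline"][0][0, 0]) < 5.0

    def test_mirrored_frame_mirrors_the_midline(self):
        spec = fl.SwimmerSpec()
        frames, truth = fl.generate_swim_video(spec, duration=1.0, seed=2)
        ar, rr = fl.kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        frame = frames.frames[0]
        width = frame.shape[1]
        c1 = fl.detect_fish_contour(frame, area_range=ar, ratio_range=rr)
        c2 = fl.detect_fish_contour(frame[:, ::-1], area_range=ar,
                                    ratio_range=rr)
        m1 = fl.extract_midline(c1)
        m2 = fl.extract_midline(c2)
        assert np.allclose(m1.points[:, 0], width - 1 - m2.points[:, 0],
                           atol=1.0)
        assert np.allclose(m1.points[:, 1], m2.points[:, 1], atol=0.5)

    def test_degenerate_contour_raises(self):
        tiny = fl.Contour(xy=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                          area=0.5, length_width_ratio=1.0)
        with pytest.raises(Exception, match="degenerate"):
            fl.extract_midline(tiny)


class TestLandmarkExcursion:
    def test_rigid_fish_gives_constant_series(self):
        spec = fl.SwimmerSpec(tail_beat_amp=0.0, head_yaw_amp=0.0,
                              opercular_amp=0.0)
        frames, truth = fl.generate_swim_video(spec, duration=1.0, seed=0)
        ar, rr = fl.kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        track = fl.track_video(frames, area_range=ar, ratio_range=rr)
        exc = fl.landmark_excursion(track, 0.8)
        assert np.ptp(exc.lateral_excursion) < 0.5

    def test_excursion_tracks_generator_truth(self, default_video):
        _, _, truth, track = default_video
        exc = fl.landmark_excursion(track, 0.8)
        err = exc.lateral_excursion - truth["tail_excursion_px"]
        assert np.sqrt(np.mean(err ** 2)) < 1.5

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, bad, default_video):
        _, _, _, track = default_video
        with pytest.raises(ValueError):
            fl.landmark_excursion(track, bad)


class TestHeadWidthSeries:
    def test_rigid_fish_constant_width(self):
        spec = fl.SwimmerSpec(tail_beat_amp=0.0, head_yaw_amp=0.0,
                              opercular_amp=0.0)
        frames, truth = fl.generate_swim_video(spec, duration=1.0, seed=0)
        ar, rr = fl.kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        track = fl.track_video(frames, area_range=ar, ratio_range=rr)
        hw = fl.head_width_series(track)
        assert np.ptp(hw) < 1.5
        assert np.all(hw >= 0)

    def test_opercular_modulation_frequency_recovered(self):
        spec = fl.SwimmerSpec(opercular_freq=2.0)
        frames, truth = fl.generate_swim_video(spec, duration=3.0, seed=1)
        ar, rr = fl.kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        track = fl.track_video(frames, area_range=ar, ratio_range=rr)
        hw = fl.head_width_series(track)
        hw = hw - hw.mean()
        f = np.fft.rfftfreq(hw.size, 1.0 / 75.0)
        assert f[np.abs(np.fft.rfft(hw)).argmax()] == pytest.approx(2.0,
                                                                    abs=0.35)


class TestSpectroKinematics:
    def test_pure_sinusoid_frequency_and_amplitude(self):
        t = np.arange(600) / 75.0
        series = 10.0 * np.sin(2 * np.pi * 3.0 * t)
        track = fl.spectro_kinematics(series, fps=75.0)
        assert np.allclose(track.frequency, 3.0, atol=0.1)
        assert np.allclose(track.amplitude, 10.0, atol=0.5)

    def test_constant_series_has_zero_amplitude_track(self):
        track = fl.spectro_kinematics(np.full(300, 7.0), fps=75.0)
        assert np.all(track.amplitude == 0.0)

    def test_chirp_frequency_track_is_nondecreasing(self):
        fps = 75.0
        t = np.arange(int(8 * fps)) / fps
        series = np.sin(2 * np.pi * (2.0 * t + 0.125 * t ** 2))  # 2 -> 4 Hz
        track = fl.spectro_kinematics(series, fps=fps)
        diffs = np.diff(track.frequency)
        assert np.all(diffs > -0.1)
        assert track.frequency[-1] > track.frequency[0] + 1.0

    def test_agrees_with_scipy_stft_peak(self):
        fps = 75.0
        t = np.arange(600) / fps
        series = 6.0 * np.sin(2 * np.pi * 4.2 * t)
        track = fl.spectro_kinematics(series, fps=fps)
        f, _, Z = stft(series, fs=fps, window="hann", nperseg=64, noverlap=63,
                       boundary=None, padded=False)
        peak_bins = f[np.abs(Z[1:]).argmax(axis=0) + 1]
        assert abs(track.frequency.mean() - peak_bins.mean()) < fps / 64

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fl.spectro_kinematics(np.zeros(30), fps=75.0)

    def test_frequency_bounded_by_nyquist_amplitude_nonnegative(self, rng):
        series = rng.normal(0, 1, 400)
        track = fl.spectro_kinematics(series, fps=75.0)
        assert np.all(track.frequency <= 37.5)
        assert np.all(track.amplitude >= 0)


class TestSummaryAndMirror:
    def test_summary_recovers_truth_and_converts_units(self, default_video):
        spec, _, truth, track = default_video
        exc = fl.landmark_excursion(track, 0.8)
        hw = fl.head_width_series(track)
        tail = fl.spectro_kinematics(exc, 75.0)
        head = fl.spectro_kinematics(hw, 75.0)
        s = fl.summarize_kinematics(tail, head)
        assert s.tbf == pytest.approx(truth["tbf_hz"], abs=0.1)
        assert s.tba == pytest.approx(truth["tba_px"], rel=0.1)
        assert s.hwf == pytest.approx(truth["hwf_hz"], abs=0.1)
        s_cm = fl.summarize_kinematics(tail, head, pixel_scale=10.0)
        assert s_cm.tba == pytest.approx(s.tba / 10.0)
        assert s_cm.units == "cm"

    def test_mirror_invariance_of_summary_statistics(self, default_video):
        spec, frames, truth, track = default_video
        ar, rr = fl.kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        mirrored = fl.FrameSequence(frames=frames.frames[:, ::-1, :].copy(),
                                    fps=frames.fps)
        mtrack = fl.track_video(mirrored, area_range=ar, ratio_range=rr)
        exc = fl.landmark_excursion(track, 0.8)
        mexc = fl.landmark_excursion(mtrack, 0.8)
        # vertical flip negates the excursion sign
        assert np.allclose(exc.lateral_excursion, -mexc.lateral_excursion,
                           atol=1.0)
        s = fl.summarize_kinematics(fl.spectro_kinematics(exc, 75.0),
                                    fl.spectro_kinematics(
                                        fl.head_width_series(track), 75.0))
        m = fl.summarize_kinematics(fl.spectro_kinematics(mexc, 75.0),
                                    fl.spectro_kinematics(
                                        fl.head_width_series(mtrack), 75.0))
        assert m.tbf == pytest.approx(s.tbf, rel=1e-3)
        assert m.tba == pytest.approx(s.tba, rel=2e-2)
        assert m.hwf == pytest.approx(s.hwf, rel=1e-3)
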