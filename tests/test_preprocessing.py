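"""Windowing, band power, image interpolation, whitening and the two
database builds."""

import numpy as np
import pytest

from eegnet import preprocessing as pp
from eegnet.synthetic import SynthSpec, gen_cohort, gen_eeg


def make_record(duration_s, fs=64.0, label="interictal", n_channels=2,
                seed=0):
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    return pp.EEGRecord(
        data=rng.normal(size=(n_channels, n)), fs=fs,
        channel_names=tuple(f"CH{i}" for i in range(n_channels)),
        intervals=[(0.0, duration_s, label)] if duration_s else [],
    )


class TestSegmentation:
    def test_six_hours_at_two_seconds_gives_10800_windows(self):
        # counts depend only on duration / window, so a low sampling rate
        # keeps the check cheap
        rec = make_record(360 * 60, fs=4.0, label="preictal")
        segs = pp.segment_record(rec, 2.0, "preictal")
        assert len(segs) == 10_800

    def test_empty_record_yields_no_segments(self):
        rec = pp.EEGRecord(data=np.zeros((2, 0)), fs=64.0,
                           channel_names=("A", "B"), intervals=[])
        assert pp.segment_record(rec, 2.0) == []

    def test_trailing_remainder_discarded(self):
        rec = make_record(5.0)
        segs = pp.segment_record(rec, 2.0)
        assert len(segs) == 2
        assert [s.t_start_s for s in segs] == [0.0, 2.0]

    def test_window_longer_than_record_yields_nothing(self):
        assert pp.segment_record(make_record(1.0), 2.0) == []

    def test_label_filter_selects_matching_intervals(self):
        rng = np.random.default_rng(0)
        rec = pp.EEGRecord(
            data=rng.normal(size=(1, 64 * 20)), fs=64.0,
            channel_names=("A",),
            intervals=[(0.0, 8.0, "preictal"), (8.0, 20.0, "interictal")],
        )
        assert len(pp.segment_record(rec, 2.0, "preictal")) == 4
        assert len(pp.segment_record(rec, 2.0, "interictal")) == 6

    def test_count_conservation_across_intervals(self):
        """floor(duration / window) per labelled interval."""
        rng = np.random.default_rng(1)
        fs = 32.0
        durations = [3.1, 7.9, 2.0, 11.5]
        edges = np.concatenate([[0.0], np.cumsum(durations)])
        rec = pp.EEGRecord(
            data=rng.normal(size=(1, int(edges[-1] * fs) + 1)), fs=fs,
            channel_names=("A",),
            intervals=[(edges[i], edges[i + 1], "ictal")
                       for i in range(len(durations))],
        )
        segs = pp.segment_record(rec, 2.0, "ictal")
        assert len(segs) == sum(int(d // 2.0) for d in durations)


class TestBandPower:
    def test_pure_alpha_tone_lands_in_alpha_band(self):
        fs, t = 256.0, np.arange(512) / 256.0
        seg = np.sin(2 * np.pi * 10.0 * t)[None]
        bp = pp.band_power(seg, fs=fs)
        assert bp[1, 0] > 1e3
        assert bp[0, 0] < 1e-6 * bp[1, 0]
        assert bp[2, 0] < 1e-6 * bp[1, 0]

    def test_all_zero_segment_has_zero_power(self):
        assert np.all(pp.band_power(np.zeros((3, 512))) == 0.0)

    def test_equal_amplitude_tones_give_equal_band_powers(self):
        fs, t = 256.0, np.arange(512) / 256.0
        seg = (np.sin(2 * np.pi * 5.0 * t) + np.sin(2 * np.pi * 20.0 * t))[None]
        bp = pp.band_power(seg, fs=fs)
        assert bp[0, 0] == pytest.approx(bp[2, 0], rel=0.01)

    def test_band_above_nyquist_rejected(self):
        bad = (pp.BandDefinition("hf", 20.0, 40.0),)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.band_power(np.zeros((1, 64)), bands=bad, fs=64.0)

    def test_total_band_power_bounded_by_spectral_power(self, rng):
        """Parseval-style: band powers never exceed the total DFT power."""
        seg = rng.normal(size=(4, 512))
        bp = pp.band_power(seg, fs=256.0)
        centred = seg - seg.mean(axis=1, keepdims=True)
        total = (np.abs(np.fft.rfft(centred, axis=1)) ** 2).sum(axis=1)
        assert np.all(bp.sum(axis=0) <= total + 1e-9)


class TestLowpass:
    def test_high_tone_removed_low_tone_kept(self):
        fs, n = 256.0, 512
        t = np.arange(n) / fs
        for f0, survives in ((40.0, False), (10.0, True)):
            spec = np.fft.rfft(np.sin(2 * np.pi * f0 * t))
            out = pp.lowpass_mask(spec, 30.0, fs, n_samples=n)
            power = np.abs(out) ** 2
            assert (power.sum() > 1.0) == survives

    def test_cutoff_at_nyquist_is_identity(self, rng):
        spec = np.fft.rfft(rng.normal(size=256))
        out = pp.lowpass_mask(spec, 128.0, 256.0, n_samples=256)
        assert np.array_equal(out, spec)


class TestSpectralImage:
    def test_constant_field_reproduced_exactly(self):
        img = pp.to_spectral_image(np.full((3, 23), 7.0))
        assert img.shape == (3, 64, 64)
        assert np.allclose(img, 7.0, atol=1e-9)

    def test_bicubic_reproduces_linear_ramp(self):
        # a layout covering all 25 grid cells makes the embedded field an
        # exact plane, which degree-3 splines reproduce
        names = tuple(f"E{i}" for i in range(25))
        layout = {f"E{r * 5 + c}": (r, c) for r in range(5) for c in range(5)}
        knots = pp.knot_pixels()
        ramp = np.array([[2.0 * knots[c] + 0.5 * knots[r]
                          for r in range(5) for c in range(5)]] * 3)
        img = pp.to_spectral_image(ramp, channel_names=names, layout=layout)
        cols, rows = np.meshgrid(np.arange(64.0), np.arange(64.0))
        assert np.allclose(img[0], 2.0 * cols + 0.5 * rows, atol=1e-6)

    def test_knot_pixels_match_inputs_exactly(self, rng):
        powers = rng.random((3, 23)) * 10
        img = pp.to_spectral_image(powers)
        knots = pp.knot_pixels()
        grid = pp._grid_embed(powers[1], pp.CHB_CHANNELS, pp.CHANNEL_GRID)
        for i in range(5):
            for j in range(5):
                assert img[1, knots[i], knots[j]] == pytest.approx(
                    grid[i, j], abs=1e-9)

    def test_non_finite_powers_rejected(self):
        bad = np.full((3, 23), np.nan)
        with pytest.raises(ValueError, match="finite"):
            pp.to_spectral_image(bad)

    def test_identical_segments_give_identical_pixels(self, rng):
        seg = rng.normal(size=(23, 512))
        img1 = pp.to_spectral_image(pp.band_power(seg))
        img2 = pp.to_spectral_image(pp.band_power(seg.copy()))
        assert np.array_equal(img1, img2)


class TestZCA:
    def test_whitened_covariance_is_identity(self, rng):
        X = rng.normal(size=(200, 10)) @ rng.normal(size=(10, 10))
        tr = pp.fit_zca(X, epsilon=1e-8)
        W = pp.apply_zca(tr, X)
        cov = np.cov(W, rowvar=False)
        assert np.abs(cov - np.eye(10)).max() < 1e-5

    def test_white_input_gives_near_identity_transform(self, rng):
        X = rng.normal(size=(5000, 6))
        tr = pp.fit_zca(X, epsilon=1e-6)
        assert np.abs(tr.matrix - np.eye(6)).max() < 0.1

    def test_repeated_image_collapses_to_zero(self):
        X = np.tile(np.arange(8.0), (5, 1))
        tr = pp.fit_zca(X, epsilon=1e-3)
        W = pp.apply_zca(tr, X)
        assert np.abs(W).max() < 1e-9

    def test_round_trip_recovers_originals(self, rng):
        X = rng.normal(size=(50, 12))
        tr = pp.fit_zca(X, epsilon=1e-5)
        back = pp.inverse_zca(tr, pp.apply_zca(tr, X))
        assert np.abs(back - X).max() / np.abs(X).max() < 1e-8

    def test_zero_epsilon_with_rank_deficiency_raises(self, rng):
        X = rng.normal(size=(4, 10))  # rank <= 3 after centring
        with pytest.raises(np.linalg.LinAlgError):
            pp.fit_zca(X, epsilon=0.0)

    def test_sklearn_transformer_wrapper(self, rng):
        X = rng.normal(size=(40, 3, 4, 4))
        est = pp.ZCAWhitening(epsilon=1e-4).fit(X)
        W = est.transform(X)
        assert W.shape == X.shape
        assert np.allclose(est.inverse_transform(W), X, atol=1e-6)

    def test_matrix_is_symmetric(self, rng):
        tr = pp.fit_zca(rng.normal(size=(30, 8)), epsilon=1e-4)
        assert np.allclose(tr.matrix, tr.matrix.T)


class TestDatabaseBuilds:
    def small_cohort(self, n_patients=2, minutes=2.0, seed=0):
        spec = SynthSpec(seed=seed)
        return gen_cohort(spec, n_patients=n_patients, preictal_events=1,
                          preictal_min=2 * minutes, interictal_min=minutes,
                          ictal_min=minutes)

    def test_binary_build_counts_and_balance(self):
        ds = pp.build_database_one(self.small_cohort(n_patients=1),
                                   minutes_per_class=2.0)
        assert len(ds) == 120
        assert ds.class_counts() == {"interictal": 60, "preictal": 60}
        assert ds.pixels.shape == (120, 3, 64, 64)

    def test_insufficient_duration_names_patient_and_shortfall(self):
        cohort = self.small_cohort(n_patients=1)
        with pytest.raises(ValueError, match="synth01.*interictal"):
            pp.build_database_one(cohort, minutes_per_class=60.0)

    def test_four_class_build_is_balanced(self):
        ds = pp.build_database_two(self.small_cohort(n_patients=2),
                                   minutes_per_class=2.0)
        counts = ds.class_counts()
        assert set(counts) == {"interictal", "PreI", "PreII", "ictal"}
        assert len(set(counts.values())) == 1
        assert counts["PreI"] == 120  # 2 patients x 60 windows

    def test_early_preictal_half_strictly_precedes_late_half(self):
        ds = pp.build_database_two(self.small_cohort(n_patients=2),
                                   minutes_per_class=2.0)
        names = list(ds.class_names)
        for patient in np.unique(ds.patient):
            sel = ds.patient == patient
            t1 = ds.t_start[sel & (ds.labels == names.index("PreI"))]
            t2 = ds.t_start[sel & (ds.labels == names.index("PreII"))]
            assert t1.max() < t2.min()

    def test_hdf5_round_trip(self, tmp_path):
        ds = pp.build_database_one(self.small_cohort(n_patients=1),
                                   minutes_per_class=2.0)
        path = tmp_path / "imgs.h5"
        pp.save_images(path, ds)
        back = pp.load_images(path)
        assert np.allclose(back.pixels, ds.pixels)
        assert np.array_equal(back.labels, ds.labels)
        assert back.class_names == ds.class_names

    def test_streaming_build_reports_counts(self, tmp_path):
        out = tmp_path / "stream.h5"
        summary = pp.build_database_one(self.small_cohort(n_patients=1),
                                        minutes_per_class=2.0, out=str(out))
        assert summary["total"] == 120
        back = pp.load_images(out)
        assert len(back) == 120
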