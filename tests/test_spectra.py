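"""Spectral processing: baseline/noise estimators, peak picking, merging, alignment."""

import numpy as np
import pandas as pd
import pytest

from pmscreen.errors import FormatError, InputError
from pmscreen.pipeline import process_spectra
from pmscreen.config import ProcessingParams
from pmscreen.spectra import (
    FeatureMatrix,
    RawSpectrum,
    align_features,
    detect_peaks,
    estimate_baseline,
    estimate_noise,
    merge_spots,
    select_top_features,
    smooth,
)


def gaussian(mz, centre, height, sigma=0.8):
    return height * np.exp(-0.5 * ((mz - centre) / sigma) ** 2)


def brute_force_rolling_min(x: np.ndarray, w: int) -> np.ndarray:
    """Independent rolling-minimum oracle (edge-replicated window)."""
    half = w // 2
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    return np.array([padded[i : i + w].min() for i in range(x.size)])


class TestRawSpectrum:
    @pytest.mark.parametrize(
        "mz, intensity",
        [
            ([1.0, 2.0], [1.0]),  # length mismatch
            ([2.0, 1.0], [1.0, 1.0]),  # decreasing mz
            ([1.0], [1.0]),  # too short
            ([1.0, 2.0], [1.0, -1.0]),  # negative intensity
        ],
    )
    def test_invalid_arrays_rejected(self, mz, intensity):
        with pytest.raises(FormatError):
            RawSpectrum(np.array(mz), np.array(intensity))

    def test_text_round_trip(self, tmp_path):
        spec = RawSpectrum(np.linspace(700, 710, 101), np.random.default_rng(0).random(101))
        path = tmp_path / "s.txt"
        spec.to_text(path)
        back = RawSpectrum.from_text(path)
        np.testing.assert_array_equal(back.mz, spec.mz)
        np.testing.assert_array_equal(back.intensity, spec.intensity)


class TestBaseline:
    def test_constant_spectrum_gives_constant_baseline(self):
        mz = np.linspace(700, 900, 2001)
        spec = RawSpectrum(mz, np.full_like(mz, 17.0))
        baseline = estimate_baseline(spec, window=20.0)
        np.testing.assert_allclose(baseline, 17.0, rtol=1e-12)

    def test_zero_under_isolated_narrow_peak(self):
        mz = np.linspace(700, 900, 2001)
        spec = RawSpectrum(mz, gaussian(mz, 800.0, 100.0, sigma=0.8))
        baseline = estimate_baseline(spec, window=40.0)
        under_peak = np.abs(mz - 800.0) < 2.0
        assert np.all(np.abs(baseline[under_peak]) < 1.0)

    def test_linear_ramp_tracked_within_one_window(self):
        """Against the brute-force rolling minimum: the min-mean-recentre chain
        stays within one window span of a linear ramp."""
        mz = np.linspace(700, 900, 2001)
        slope = 0.5
        ramp = 10.0 + slope * (mz - 700.0)
        spec = RawSpectrum(mz, ramp)
        window = 20.0
        baseline = estimate_baseline(spec, window=window)
        w_pts = int(round(window / 0.1)) | 1
        oracle_min = brute_force_rolling_min(ramp, w_pts)
        assert np.all(baseline >= oracle_min - 1e-9)
        assert np.max(np.abs(baseline - ramp)) <= slope * window + 1e-6


class TestNoise:
    def test_mad_estimate_consistent_for_gaussian_noise(self, rng):
        sigma = 3.0
        mz = np.linspace(700, 1100, 4001)
        spec = RawSpectrum(mz, np.clip(100.0 + rng.normal(0, sigma, mz.size), 0, None))
        baseline = estimate_baseline(spec, window=30.0)
        noise = estimate_noise(spec, baseline, window=15.0)
        assert np.median(noise) == pytest.approx(sigma, rel=0.15)

    def test_zero_noise_floor_is_tiny_positive(self):
        mz = np.linspace(700, 900, 1001)
        spec = RawSpectrum(mz, np.full_like(mz, 5.0))
        noise = estimate_noise(spec, estimate_baseline(spec, 20.0), window=10.0)
        assert np.all(noise > 0)
        assert np.all(noise < 1e-9)

    def test_shift_invariance(self, rng):
        mz = np.linspace(700, 900, 2001)
        base = np.clip(50.0 + rng.normal(0, 2.0, mz.size), 0, None)
        s1 = RawSpectrum(mz, base)
        s2 = RawSpectrum(mz, base + 123.0)
        b1 = estimate_baseline(s1, 20.0)
        b2 = estimate_baseline(s2, 20.0)
        np.testing.assert_allclose(
            estimate_noise(s1, b1, 10.0), estimate_noise(s2, b2, 10.0), rtol=1e-9
        )


class TestDetectPeaks:
    def test_flat_zero_spectrum_yields_no_peaks(self):
        mz = np.linspace(700, 900, 1001)
        peaks = detect_peaks(RawSpectrum(mz, np.zeros_like(mz)), snr_threshold=2.0)
        assert peaks.empty

    def test_three_clean_gaussians_found_with_accurate_centroids(self):
        mz = np.arange(700.0, 3100.0, 0.1)
        intensity = sum(gaussian(mz, c, h) for c, h in [(1000.0, 50.0), (2000.0, 80.0), (3000.0, 30.0)])
        peaks = detect_peaks(RawSpectrum(mz, intensity), snr_threshold=2.0)
        assert len(peaks) == 3
        np.testing.assert_allclose(
            peaks["mz"].to_numpy(), [1000.0, 2000.0, 3000.0], atol=0.05
        )
        np.testing.assert_allclose(peaks["height"], [50.0, 80.0, 30.0], rtol=0.02)

    def test_peak_count_monotone_in_snr_threshold(self, tiny_experiment):
        spec = tiny_experiment.spectra[0]
        n2 = len(detect_peaks(spec, snr_threshold=2.0))
        n3 = len(detect_peaks(spec, snr_threshold=3.0))
        assert n2 > n3 > 0

    def test_matches_brute_force_enumeration(self, rng):
        """Peak apexes equal a naive enumeration of above-threshold local maxima."""
        for _ in range(20):
            n = int(rng.integers(200, 3000))
            mz = np.cumsum(rng.uniform(0.05, 0.2, n)) + 700.0
            intensity = np.clip(
                10.0 + rng.normal(0, 2.0, n)
                + gaussian(mz, float(rng.uniform(mz[0], mz[-1])), 50.0),
                0,
                None,
            )
            spec = RawSpectrum(mz, intensity)
            baseline = estimate_baseline(spec, 30.0)
            noise = estimate_noise(spec, baseline, 15.0)
            resid = spec.intensity - baseline
            expected = [
                i
                for i in range(1, n - 1)
                if resid[i] > resid[i - 1]
                and resid[i] > resid[i + 1]
                and resid[i] > 0
                and resid[i] / noise[i] >= 2.5
            ]
            got = detect_peaks(spec, 2.5, baseline=baseline, noise=noise)
            assert len(got) == len(expected)
            np.testing.assert_allclose(
                np.sort(got["height"].to_numpy()), np.sort(resid[expected]), rtol=1e-9
            )


class TestSelectTop:
    def test_undersized_input_returned_whole(self):
        peaks = pd.DataFrame({"mz": np.arange(10.0), "height": 1.0, "snr": 5.0})
        assert len(select_top_features(peaks, n=200, snr_floor=3.0)) == 10

    def test_ranking_and_floor(self):
        peaks = pd.DataFrame(
            {"mz": [10.0, 20.0, 30.0, 40.0], "height": 1.0, "snr": [5.0, 4.0, 3.0, 2.5]}
        )
        top = select_top_features(peaks, n=2, snr_floor=3.0)
        assert top["snr"].tolist() == [5.0, 4.0]

    def test_equal_snr_ties_break_by_ascending_mz_stably(self):
        peaks = pd.DataFrame({"mz": [30.0, 10.0, 20.0], "height": 1.0, "snr": 4.0})
        runs = [select_top_features(peaks, n=2, snr_floor=3.0) for _ in range(3)]
        for r in runs:
            assert r["mz"].tolist() == [10.0, 20.0]


class TestMergeSpots:
    def test_duplicated_spot_gives_zero_rsd(self):
        pl = pd.DataFrame({"mz": [800.0, 900.0], "height": [10.0, 20.0], "snr": [5.0, 8.0]})
        merged = merge_spots([pl, pl.copy()], min_spot_fraction=0.5)
        assert np.all(merged["rsd"] == 0.0)
        assert merged["height"].tolist() == [10.0, 20.0]

    def test_two_spot_hand_calculation(self):
        a = pd.DataFrame({"mz": [800.0], "height": [90.0], "snr": [5.0]})
        b = pd.DataFrame({"mz": [800.01], "height": [110.0], "snr": [5.0]})
        merged = merge_spots([a, b], min_spot_fraction=0.5)
        assert merged["height"].iloc[0] == pytest.approx(100.0)
        assert merged["rsd"].iloc[0] == pytest.approx(0.141421, abs=1e-5)

    def test_minority_features_dropped(self):
        a = pd.DataFrame({"mz": [800.0, 900.0], "height": [10.0, 5.0], "snr": [5.0, 3.0]})
        b = pd.DataFrame({"mz": [800.0], "height": [12.0], "snr": [5.0]})
        c = pd.DataFrame({"mz": [800.0], "height": [11.0], "snr": [5.0]})
        merged = merge_spots([a, b, c], min_spot_fraction=0.6)
        assert merged["mz"].tolist() == [800.0]
        assert merged["n_spots"].tolist() == [3]

    def test_no_spots_rejected(self):
        with pytest.raises(InputError):
            merge_spots([])


class TestAlignFeatures:
    def test_identical_peak_sets_square_and_complete(self):
        pl = pd.DataFrame({"mz": [800.0, 900.0, 1000.0], "height": [1.0, 2.0, 3.0], "snr": 5.0})
        fm = align_features({"s1": pl, "s2": pl.copy()})
        assert fm.intensities.shape == (3, 2)
        assert not fm.intensities.isna().any().any()

    def test_tolerance_arithmetic(self):
        a = pd.DataFrame({"mz": [1000.00], "height": [1.0], "snr": [5.0]})
        b = pd.DataFrame({"mz": [1000.10], "height": [1.0], "snr": [5.0]})
        wide = align_features({"a": a, "b": b}, tolerance_ppm=250.0)
        narrow = align_features({"a": a, "b": b}, tolerance_ppm=50.0)
        assert len(wide.mz) == 1
        assert len(narrow.mz) == 2

    def test_invariant_to_sample_order(self, rng):
        lists = {
            f"s{i}": pd.DataFrame(
                {
                    "mz": np.sort(rng.uniform(700, 1100, 20)),
                    "height": rng.uniform(1, 10, 20),
                    "snr": rng.uniform(3, 30, 20),
                }
            )
            for i in range(4)
        }
        forward = align_features(lists)
        reversed_ = align_features(dict(reversed(list(lists.items()))))
        pd.testing.assert_frame_equal(forward.intensities, reversed_.intensities)

    def test_requires_two_samples(self):
        with pytest.raises(InputError):
            align_features({"only": pd.DataFrame(columns=["mz", "height", "snr"])})


class TestNoiseFreeEndToEnd:
    def test_feature_matrix_recovers_ground_truth_heights(self, noise_free_experiment):
        """With no noise and no baseline the aligned matrix equals the true
        dose-scaled peak heights (up to the sub-grid apex offset)."""
        exp = noise_free_experiment
        params = ProcessingParams(smooth_window=0.0)
        matrices, rsd = process_spectra(exp.spectra, exp.design, params)
        fm = matrices["J774"]
        truth = exp.truth
        assert np.all(rsd["rsd"] < 1e-9)
        design = exp.design.drop_duplicates("sample_id").set_index("sample_id")
        for sid in fm.sample_ids:
            row = design.loc[sid]
            expected = truth.basal_height * truth.true_fold_change(
                row["particle"], float(row["dose"])
            )
            got = fm.intensities[sid]
            # match features to the registry by m/z
            idx = np.abs(
                truth.peptide_mz[None, :] - fm.mz[:, None]
            ).argmin(axis=1)
            valid = got.notna().to_numpy()
            # baseline recentring subtracts a tail-level offset where peak
            # tails overlap, so recovery is exact only to ~2%
            np.testing.assert_allclose(
                got.to_numpy()[valid], expected[idx][valid], rtol=2e-2, atol=0.5
            )


def test_smoothing_preserves_clean_peak_heights():
    mz = np.arange(700.0, 1500.0, 0.1)
    intensity = gaussian(mz, 1000.0, 50.0) + gaussian(mz, 1200.0, 20.0)
    sm = smooth(RawSpectrum(mz, intensity), window=1.5)
    peaks = detect_peaks(sm, snr_threshold=2.0)
    assert len(peaks) == 2
    np.testing.assert_allclose(peaks["height"], [50.0, 20.0], rtol=0.03)
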