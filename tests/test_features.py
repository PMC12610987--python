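import numpy as np
import pandas as pd
import pytest

from breathsig.features import (
    FeatureError, FeatureMatrix, NormalizationError, Peak, align_features,
    composite_spectrum, detect_peaks, filter_model_features, mass_tolerance,
    normalize_features,
)
from breathsig.preprocess import extract_eic, segment_breaths
from breathsig.raw_io import RawRecording, SampleSpectrum


def _gaussian_spectrum(mzs_amps, lo=10.0, hi=120.0, step=0.005, sigma_rel=1 / 2354.8):
    axis = np.arange(lo, hi, step)
    y = np.zeros_like(axis)
    for mz, amp in mzs_amps:
        y += amp * np.exp(-0.5 * ((axis - mz) / (mz * sigma_rel)) ** 2)
    return SampleSpectrum(axis, y, 1, np.array([0]))


class TestComposite:
    def _rec(self, n=4, scale=1.0):
        axis = np.arange(10.0, 50.0, 0.01)
        base = 100 * np.exp(-0.5 * ((axis - 30.0) / 0.02) ** 2)
        return RawRecording(axis, np.tile(base * scale, (n, 1)),
                            np.arange(float(n)), np.zeros(n))

    def test_identical_spectra_mean_equals_smoothed_member(self):
        rec = self._rec(4)
        comp = composite_spectrum(rec, [0, 1, 2, 3])
        single = composite_spectrum(rec, [0])
        np.testing.assert_allclose(comp.intensity, single.intensity, rtol=1e-9)
        assert comp.n_spectra_used == 4
        assert single.n_spectra_used == 1

    def test_empty_selection_raises(self):
        with pytest.raises(FeatureError, match="no exhalation spectra"):
            composite_spectrum(self._rec(), [])

    def test_bad_savgol_params_rejected(self):
        with pytest.raises(FeatureError):
            composite_spectrum(self._rec(), [0], sg_window=5, sg_order=5)

    def test_smoothing_moves_apex_by_less_than_one_grid_step(self):
        rec = self._rec()
        comp = composite_spectrum(rec, [0])
        apex_before = rec.mz_axis[np.argmax(rec.spectra[0])]
        apex_after = comp.mz_axis[np.argmax(comp.intensity)]
        assert abs(apex_after - apex_before) <= 0.01 + 1e-12


class TestDetectPeaks:
    def test_flat_spectrum_yields_no_peaks(self):
        spec = SampleSpectrum(np.arange(10.0, 20.0, 0.01),
                              np.zeros(1000), 1, np.array([0]))
        assert detect_peaks(spec) == []

    def test_two_gaussians_centroided_within_5_mda(self):
        spec = _gaussian_spectrum([(69.07, 1e4), (95.05, 5e3)])
        peaks = detect_peaks(spec)
        assert len(peaks) == 2
        assert abs(peaks[0].centroid_mz - 69.07) < 0.005
        assert abs(peaks[1].centroid_mz - 95.05) < 0.005

    def test_centroids_invariant_under_intensity_scaling(self):
        spec = _gaussian_spectrum([(69.07, 1e4), (95.05, 5e3)])
        doubled = SampleSpectrum(spec.mz_axis, spec.intensity * 2, 1, np.array([0]))
        c1 = [p.centroid_mz for p in detect_peaks(spec)]
        c2 = [p.centroid_mz for p in detect_peaks(doubled)]
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_simulated_channels_recovered(self, small_recording):
        rec, truth = small_recording
        water = extract_eic(rec, 37.038)
        tracers = [extract_eic(rec, m) for m in (69.07, 63.02, 55.03)]
        phase = segment_breaths(water, tracers)
        comp = composite_spectrum(rec, phase.selected_indices)
        centroids = np.array([p.centroid_mz for p in detect_peaks(comp)])
        for mz in truth.channel_amplitudes:
            assert np.min(np.abs(centroids - mz)) < 0.005


def _peak(mz, area=10.0):
    return Peak(mz, 100.0, area, (mz - 0.05, mz + 0.05))


class TestAlignment:
    def test_peaks_within_tolerance_merge(self):
        m = align_features({"a": [_peak(100.000), _peak(22.027)],
                            "b": [_peak(100.010), _peak(22.028)]})
        assert len(m.feature_mzs) == 2
        assert m.prevalence.tolist() == [1.0, 1.0]

    def test_minority_feature_dropped_by_prevalence_rule(self):
        lists = {f"s{i}": [_peak(50.0)] for i in range(5)}
        lists["s0"].append(_peak(80.0))
        lists["s1"].append(_peak(80.0))
        m = align_features(lists)  # 80.0 in 2/5 samples -> dropped
        assert len(m.feature_mzs) == 1
        assert abs(m.feature_mzs[0] - 50.0) < 1e-9

    def test_exactly_half_is_not_enough(self):
        lists = {f"s{i}": [_peak(50.0)] for i in range(4)}
        lists["s0"].append(_peak(80.0))
        lists["s1"].append(_peak(80.0))
        m = align_features(lists)  # prevalence 0.5 fails the strict > 0.5 rule
        assert len(m.feature_mzs) == 1

    def test_sample_order_invariance(self):
        lists = {"a": [_peak(50.0), _peak(60.0)], "b": [_peak(50.004)],
                 "c": [_peak(60.003), _peak(50.002)]}
        m1 = align_features(lists)
        m2 = align_features(dict(reversed(list(lists.items()))))
        np.testing.assert_allclose(m1.feature_mzs, m2.feature_mzs)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_consensus_is_median_of_members(self):
        m = align_features({"a": [_peak(100.000)], "b": [_peak(100.010)],
                            "c": [_peak(100.002)]})
        assert abs(m.feature_mzs[0] - 100.002) < 1e-9

    def test_missing_entries_imputed_zero(self):
        lists = {"a": [_peak(50.0), _peak(60.0)], "b": [_peak(50.0), _peak(60.0)],
                 "c": [_peak(50.0)]}
        m = align_features(lists)
        col60 = m.values[m.values.columns[1]]
        assert col60["c"] == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(FeatureError):
            align_features({})


def _matrix(values, mzs, normalized=False):
    df = pd.DataFrame(values, columns=mzs,
                      index=[f"s{i}" for i in range(len(values))])
    return FeatureMatrix(df, pd.Series(1.0, index=df.columns), normalized=normalized)


class TestNormalization:
    def test_arithmetic(self):
        m = _matrix([[4.0, 2.0]], [22.0274, 69.07])
        n = normalize_features(m)
        assert n.values.iloc[0, 1] == pytest.approx(0.5)
        assert n.values.iloc[0, 0] == pytest.approx(1.0)

    def test_scale_invariance_per_sample(self):
        m = _matrix([[4.0, 2.0, 8.0], [2.0, 5.0, 1.0]], [22.0274, 69.07, 95.05])
        scaled = _matrix([[8.0, 4.0, 16.0], [2.0, 5.0, 1.0]], [22.0274, 69.07, 95.05])
        pd.testing.assert_frame_equal(normalize_features(m).values,
                                      normalize_features(scaled).values)

    def test_zero_standard_reported_with_sample_ids(self):
        m = _matrix([[0.0, 2.0]], [22.0274, 69.07])
        with pytest.raises(NormalizationError, match="s0"):
            normalize_features(m)

    def test_absent_standard_raises(self):
        m = _matrix([[2.0, 3.0]], [50.0, 69.07])
        with pytest.raises(NormalizationError, match="not found"):
            normalize_features(m)


class TestModelFeatureFilter:
    def test_exclusion_rules(self):
        m = _matrix([[1.0] * 5], [21.022, 44.991, 95.054, 203.943, 330.85],
                    normalized=True)
        kept = filter_model_features(m).feature_mzs
        assert list(kept) == [44.991, 95.054]  # calibrants and m/z < 42 removed

    def test_prevalence_metadata_follows_columns(self):
        m = _matrix([[1.0, 1.0]], [21.022, 95.054], normalized=True)
        out = filter_model_features(m)
        assert list(out.prevalence.index) == [95.054]


def test_tolerance_schedule_anchors_and_monotonicity():
    assert mass_tolerance(42.0) == pytest.approx(0.015)
    assert mass_tolerance(685.0) == pytest.approx(0.4)
    grid = np.linspace(10, 700, 200)
    assert np.all(np.diff(mass_tolerance(grid)) >= 0)


def test_feature_matrix_csv_round_trip(tmp_path, small_cohort):
    _, mats = small_cohort
    m = mats["tidal"]
    m.write(tmp_path / "fm")
    back = FeatureMatrix.read(tmp_path / "fm")
    np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy(), rtol=1e-5)
    assert back.normalized == m.normalized
    assert list(back.sample_meta["group"]) == list(m.sample_meta["group"])
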