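"""Build a normalized feature matrix from a handful of recordings.

Each recording is segmented, its end-tidal spectra averaged and smoothed
(Savitzky-Golay), peaks centroided, and the per-sample peak lists aligned with
the mass-dependent tolerance. Features present in more than half the samples
survive; intensities are normalized to the heavy-water internal standard at
m/z 22.0274 and calibration ions plus everything below m/z 42 are removed
before modeling.
"""

from breathsig import (
    align_features, composite_spectrum, detect_peaks, extract_eic,
    filter_model_features, normalize_features, segment_breaths,
)
from breathsig.synthetic import RecordingSimConfig, simulate_recording

peaklists = {}
for i, seed in enumerate((1, 2, 3, 4)):
    cfg = RecordingSimConfig(seed=seed, mz_range=(10.0, 120.0),
                             calibrant_mzs=(21.0220,), calibrant_cps=(5e4,),
                             extra_channels=((95.05, 2e4), (79.054, 1.5e4)))
    rec, _ = simulate_recording(cfg)
    water = extract_eic(rec, 37.038)
    tracers = [extract_eic(rec, mz) for mz in (69.07, 63.02, 55.03)]
    phase = segment_breaths(water, tracers)
    comp = composite_spectrum(rec, phase.selected_indices)
    peaklists[f"sample{i}"] = detect_peaks(comp)
    print(f"sample{i}: {len(phase.selected_indices)} end-tidal spectra, "
          f"{len(peaklists[f'sample{i}'])} peaks")

matrix = align_features(peaklists)
matrix = normalize_features(matrix)
model_matrix = filter_model_features(matrix, calibrant_mzs=(21.0220,))
print(f"\naligned features: {[f'{m:.3f}' for m in matrix.feature_mzs]}")
print(f"model features (m/z >= 42, calibrants dropped): "
      f"{[f'{m:.3f}' for m in model_matrix.feature_mzs]}")
print("\nnormalized intensities (ratio to internal standard):")
print(model_matrix.values.round(3))
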