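"""Composite spectra, peak detection, cross-sample alignment and normalization.

Per-sample exhalation spectra are averaged into a composite, Savitzky-Golay
smoothed along the m/z axis, and reduced to centroided peaks. Peaks are aligned
across samples with a mass-dependent tolerance, kept when present in more than
half of all samples, normalized to the heavy-water internal standard
([D2O+H3O]+ at m/z 22.0274), and filtered of calibration ions and everything
below m/z 42 before modeling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .raw_io import RawRecording, SampleSpectrum

#: mass-dependent alignment tolerance: +/-0.015 Da at m/z 42 rising linearly to
#: +/-0.4 Da at m/z 685 (approximately constant relative resolution); clamped
#: outside that range.
TOL_ANCHORS = ((42.0, 0.015), (685.0, 0.4))

INTERNAL_STANDARD_MZ = 22.0274
CALIBRANT_MZS = (21.0220, 203.94299, 330.85)


class FeatureError(ValueError):
    pass


class NormalizationError(FeatureError):
    pass


def mass_tolerance(mz) -> np.ndarray | float:
    """Alignment half-window (Da) at mass ``mz``; linear between the anchors."""
    (m0, t0), (m1, t1) = TOL_ANCHORS
    return np.interp(mz, [m0, m1], [t0, t1])


@dataclass
class Peak:
    """One centroided peak in a composite spectrum."""

    centroid_mz: float
    apex_intensity: float
    integrated_area: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < self.centroid_mz < hi:
            raise FeatureError(f"centroid {self.centroid_mz} outside window {self.window}")
        if self.apex_intensity <= 0:
            raise FeatureError("apex intensity must be positive")


@dataclass
class FeatureMatrix:
    """Samples x aligned-feature intensity matrix with provenance.

    ``values`` is a DataFrame whose columns are consensus m/z (Da, float) and
    whose rows are sample ids; ``prevalence`` the fraction of samples in which
    each feature was detected; ``sample_meta`` per-sample annotations (subject,
    maneuver, group, bdr). After :func:`normalize_features` the values are
    dimensionless ratios to the internal standard.
    """

    values: pd.DataFrame
    prevalence: pd.Series
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalized: bool = False

    @property
    def feature_mzs(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def write(self, prefix) -> tuple[Path, Path]:
        """Write values as CSV (columns = m/z to 3 decimals) + JSON sidecar."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        out = self.values.copy()
        out.columns = [f"{mz:.3f}" for mz in self.feature_mzs]
        out.index.name = "sample_id"
        out.to_csv(csv_path, float_format="%.6g")
        sidecar = {
            "feature_mzs": [float(m) for m in self.feature_mzs],
            "prevalence": [float(p) for p in self.prevalence],
            "normalized": self.normalized,
            "sample_meta": json.loads(self.sample_meta.to_json(orient="index"))
            if not self.sample_meta.empty else {},
        }
        json_path = prefix.with_suffix(".json")
        json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return csv_path, json_path

    @classmethod
    def read(cls, prefix) -> "FeatureMatrix":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        values = pd.read_csv(prefix.with_suffix(".csv"), index_col="sample_id")
        values.columns = sidecar["feature_mzs"]
        meta = pd.DataFrame.from_dict(sidecar["sample_meta"], orient="index")
        return cls(
            values=values,
            prevalence=pd.Series(sidecar["prevalence"], index=values.columns),
            sample_meta=meta,
            normalized=sidecar["normalized"],
        )


def composite_spectrum(rec: RawRecording, selected_indices, sg_window: int = 7,
                       sg_order: int = 3) -> SampleSpectrum:
    """Average the selected (end-tidal) spectra and smooth along m/z.

    Summing and averaging differ only by the constant count of spectra, which
    the internal-standard normalization cancels; the arithmetic mean is used.
    """
    idx = np.asarray(selected_indices, dtype=int)
    if idx.size == 0:
        raise FeatureError("no exhalation spectra selected for composite")
    if sg_order >= sg_window:
        raise FeatureError("sg_order must be smaller than sg_window")
    if sg_window % 2 == 0:
        raise FeatureError("sg_window must be odd")
    mean = np.asarray(rec.spectra[idx], dtype=float).mean(axis=0)
    smoothed = savgol_filter(mean, sg_window, sg_order)
    np.clip(smoothed, 0.0, None, out=smoothed)
    return SampleSpectrum(
        mz_axis=rec.mz_axis,
        intensity=smoothed,
        n_spectra_used=int(idx.size),
        provenance=idx,
    )


def detect_peaks(spec: SampleSpectrum, min_prominence_rel: float = 1e-3,
                 min_intensity_cps: float = 50.0) -> list[Peak]:
    """Centroided peak list from a composite spectrum.

    Prominence is relative to the most intense signal in the spectrum; the
    centroid is the intensity-weighted mean m/z over the peak window (taken at
    95% of the prominence drop), which is scale-invariant by construction.
    """
    y = spec.intensity
    if y.max(initial=0.0) <= 0:
        return []
    apex_idx, props = find_peaks(
        y, height=min_intensity_cps, prominence=min_prominence_rel * y.max())
    if apex_idx.size == 0:
        return []
    _, _, left_ips, right_ips = peak_widths(y, apex_idx, rel_height=0.95)
    peaks = []
    for apex, li, ri in zip(apex_idx, left_ips, right_ips):
        lo = int(np.floor(li))
        hi = int(np.ceil(ri)) + 1
        seg_mz = spec.mz_axis[lo:hi]
        seg_y = y[lo:hi]
        total = seg_y.sum()
        if total <= 0:
            continue
        centroid = float(np.dot(seg_mz, seg_y) / total)
        area = float(np.trapezoid(seg_y, seg_mz))
        win = (float(spec.mz_axis[lo]), float(spec.mz_axis[hi - 1]))
        if not win[0] < centroid < win[1]:
            continue
        peaks.append(Peak(centroid, float(y[apex]), area, win))
    peaks.sort(key=lambda p: p.centroid_mz)
    return peaks


def align_features(peaklists: dict[str, list[Peak]], sample_meta: pd.DataFrame | None = None,
                   min_prevalence: float = 0.5, value_kind: str = "area") -> FeatureMatrix:
    """Cluster per-sample peak lists into consensus features.

    Single-linkage on the pooled, sorted centroids: a new cluster starts whenever
    the gap to the previous centroid exceeds the mass-dependent tolerance. The
    procedure is deterministic and independent of sample order. Clusters are
    kept iff detected in strictly more than ``min_prevalence`` of samples;
    missing entries are imputed as 0 (absence = below detection).
    """
    if not peaklists or all(len(v) == 0 for v in peaklists.values()):
        raise FeatureError("no peaks to align")
    sample_ids = sorted(peaklists)
    pooled = sorted(
        ((p.centroid_mz, sid, p) for sid in sample_ids for p in peaklists[sid]),
        key=lambda t: (t[0], t[1]),
    )
    clusters: list[list[tuple[float, str, Peak]]] = [[pooled[0]]]
    for item in pooled[1:]:
        prev_mz = clusters[-1][-1][0]
        if item[0] - prev_mz > mass_tolerance(0.5 * (item[0] + prev_mz)):
            clusters.append([item])
        else:
            clusters[-1].append(item)

    n = len(sample_ids)
    cols, prevs, col_values = [], [], []
    for members in clusters:
        present = {sid for _, sid, _ in members}
        prevalence = len(present) / n
        if prevalence <= min_prevalence:
            continue
        consensus = float(np.median([mz for mz, _, _ in members]))
        vals = dict.fromkeys(sample_ids, 0.0)
        for _, sid, p in members:
            vals[sid] += p.integrated_area if value_kind == "area" else p.apex_intensity
        cols.append(consensus)
        prevs.append(prevalence)
        col_values.append([vals[sid] for sid in sample_ids])

    if not cols:
        raise FeatureError("no feature passed the prevalence filter")
    values = pd.DataFrame(np.array(col_values).T, index=sample_ids, columns=cols)
    values = values.sort_index(axis=1)
    prevalence = pd.Series(prevs, index=cols).sort_index()
    meta = sample_meta.loc[sample_ids] if sample_meta is not None else pd.DataFrame(index=sample_ids)
    return FeatureMatrix(values=values, prevalence=prevalence, sample_meta=meta,
                         normalized=False)


def normalize_features(m: FeatureMatrix,
                       internal_standard_mz: float = INTERNAL_STANDARD_MZ) -> FeatureMatrix:
    """Divide each sample by its internal-standard feature value.

    Makes the matrix invariant to per-sample global intensity scaling (humidity,
    instrument sensitivity). The internal-standard feature itself becomes 1.
    """
    mzs = m.feature_mzs
    dist = np.abs(mzs - internal_standard_mz)
    j = int(np.argmin(dist))
    if dist[j] > mass_tolerance(internal_standard_mz):
        raise NormalizationError(
            f"internal standard m/z {internal_standard_mz} not found among features")
    std = m.values.iloc[:, j]
    bad = std.index[~(std > 0)].tolist()
    if bad:
        raise NormalizationError(
            f"internal standard missing or zero in samples: {bad}")
    values = m.values.div(std, axis=0)
    return FeatureMatrix(values=values, prevalence=m.prevalence.copy(),
                         sample_meta=m.sample_meta, normalized=True)


def filter_model_features(m: FeatureMatrix, calibrant_mzs=CALIBRANT_MZS,
                          min_mz: float = 42.0) -> FeatureMatrix:
    """Drop calibration ions and everything below m/z 42 before modeling."""
    if not m.normalized:
        warnings.warn("filter_model_features called on an un-normalized matrix")
    mzs = m.feature_mzs
    keep = mzs >= min_mz
    for cal in calibrant_mzs:
        keep &= np.abs(mzs - cal) > mass_tolerance(cal)
    values = m.values.loc[:, m.values.columns[keep]]
    return FeatureMatrix(values=values, prevalence=m.prevalence[m.prevalence.index[keep]],
                         sample_meta=m.sample_meta, normalized=m.normalized)
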