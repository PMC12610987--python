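"""Mass recalibration, ion-trace extraction, breath delineation and QC.

Every recording is recalibrated against the three PerMaSCal reference masses
(m/z 21.0220, 203.94299, 330.85) with a quadratic correction in sqrt(m/z) space
— the natural coordinate for a TOF analyser, where flight time scales with the
square root of mass. Breath phases are delineated from the water-adduct ion
trace (m/z 37.038): spectra are kept only when the water adduct exceeds 2e5 cps
and at least two of the three tracer VOCs (isoprene m/z 69.07, dimethyl sulfide
63.02, 1,2-butadiene 55.03) show a coincident local maximum. The capnostat
channel is used solely for quality control (its response lags the water ion),
never for phase delineation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .raw_io import RawRecording

PERMASCAL_MZS = (21.0220, 203.94299, 330.85)
WATER_ADDUCT_MZ = 37.038
TRACER_MZS = (69.07, 63.02, 55.03)
WATER_THRESHOLD_CPS = 2e5
CAPNOSTAT_MAX_UNITS = 3.5
CALIBRANT_MAX_PPM = 100.0
MIN_CYCLES = 3


class CalibrationError(RuntimeError):
    pass


class RangeError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class CalibrationModel:
    """Quadratic axis correction fitted in sqrt(m/z) space.

    ``coeffs`` are the polynomial coefficients p such that
    sqrt(m_corrected) = p0 * m_obs + p1 * sqrt(m_obs) + p2 (numpy polyval
    order); with three references the fit is exact and residuals measure
    centroid re-detection error only.
    """

    reference_mzs: tuple[float, ...]
    coeffs: np.ndarray
    residual_ppm: np.ndarray
    detected_mzs: np.ndarray

    @property
    def max_residual_ppm(self) -> float:
        return float(np.max(np.abs(self.residual_ppm)))

    def apply(self, mz_axis: np.ndarray) -> np.ndarray:
        corrected = np.polyval(self.coeffs, np.sqrt(mz_axis)) ** 2
        if not np.all(np.diff(corrected) > 0):
            raise CalibrationError("correction is not invertible over the mass range")
        return corrected


@dataclass
class IonTrace:
    """Extracted ion current: per-spectrum intensity summed over a m/z window."""

    target_mz: float
    window: float
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise RangeError("EIC window must be positive")
        self.intensity = np.asarray(self.intensity, dtype=float)


@dataclass
class BreathPhaseResult:
    """Outcome of breath-phase delineation on one recording."""

    selected_indices: np.ndarray     # end-tidal spectra retained for the composite
    cycle_count: int                 # maximal runs of water-above-threshold spectra
    water_ok: np.ndarray             # per-spectrum flags
    tracer_coincidence: np.ndarray


@dataclass
class QCReport:
    capnostat_pass: bool
    calibrant_pass: bool
    cycles_pass: bool
    details: dict = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return self.capnostat_pass and self.calibrant_pass and self.cycles_pass


def _detect_centroid(mz_axis: np.ndarray, spectrum: np.ndarray, target: float,
                     search_window: float = 0.3, min_apex_cps: float = 500.0) -> float:
    """Centroid of the strongest peak near ``target`` in a mean spectrum.

    Uses three-point log-parabolic (Gaussian) interpolation around the apex,
    which is exact for a noise-free Gaussian peak, falling back to an
    intensity-weighted mean when the interpolation is ill-conditioned. The apex
    must clear ``min_apex_cps`` (well above averaged counting noise, well below
    any real calibrant) or the peak is declared absent.
    """
    lo = np.searchsorted(mz_axis, target - search_window)
    hi = np.searchsorted(mz_axis, target + search_window)
    if hi - lo < 3:
        raise CalibrationError(f"reference mass {target} outside the recorded axis")
    seg = spectrum[lo:hi]
    apex = int(np.argmax(seg))
    if seg[apex] < min_apex_cps:
        raise CalibrationError(f"reference peak at m/z {target} not detected")
    i = lo + apex
    if 0 < i < len(spectrum) - 1:
        y0, y1, y2 = spectrum[i - 1], spectrum[i], spectrum[i + 1]
        if y0 > 0 and y2 > 0 and y1 > y0 and y1 > y2:
            l0, l1, l2 = np.log(y0), np.log(y1), np.log(y2)
            denom = l0 - 2 * l1 + l2
            if denom < 0:
                delta = 0.5 * (l0 - l2) / denom
                step = 0.5 * (mz_axis[i + 1] - mz_axis[i - 1])
                return float(mz_axis[i] + delta * step)
    # weighted-mean fallback over +/- 3 grid points
    w0, w1 = max(i - 3, 0), min(i + 4, len(spectrum))
    weights = spectrum[w0:w1]
    return float(np.dot(mz_axis[w0:w1], weights) / weights.sum())


def recalibrate(rec: RawRecording, reference_mzs=PERMASCAL_MZS
                ) -> tuple[RawRecording, CalibrationModel]:
    """Recalibrate the mass axis against the reference peaks.

    The summed spectrum is centroided at each reference, an exact three-point
    quadratic is fitted in sqrt(m/z) space, the axis is corrected, and residual
    ppm errors are measured by re-detecting the centroids on the corrected axis.
    """
    if len(reference_mzs) < 3:
        raise CalibrationError("three reference masses are required")
    summed = np.asarray(rec.spectra, dtype=float).mean(axis=0)
    detected = np.array([_detect_centroid(rec.mz_axis, summed, m) for m in reference_mzs])
    coeffs = np.polyfit(np.sqrt(detected), np.sqrt(np.asarray(reference_mzs)), 2)
    model = CalibrationModel(tuple(reference_mzs), coeffs, np.zeros(len(reference_mzs)),
                             detected)
    corrected_axis = model.apply(rec.mz_axis)
    out = RawRecording(
        mz_axis=corrected_axis,
        spectra=rec.spectra,
        times=rec.times,
        capnostat=rec.capnostat,
        metadata=dict(rec.metadata),
    )
    redetected = np.array([_detect_centroid(corrected_axis, summed, m) for m in reference_mzs])
    model.residual_ppm = (redetected - np.asarray(reference_mzs)) / np.asarray(reference_mzs) * 1e6
    return out, model


def extract_eic(rec: RawRecording, target_mz: float, window: float = 0.05) -> IonTrace:
    """Per-spectrum intensity summed over ``target_mz`` +/- ``window``."""
    if window <= 0:
        raise RangeError("EIC window must be positive")
    lo_mz, hi_mz = target_mz - window, target_mz + window
    if lo_mz < rec.mz_axis[0] or hi_mz > rec.mz_axis[-1]:
        raise RangeError(
            f"EIC window [{lo_mz:.3f}, {hi_mz:.3f}] outside recorded axis "
            f"[{rec.mz_axis[0]:.3f}, {rec.mz_axis[-1]:.3f}]")
    lo = np.searchsorted(rec.mz_axis, lo_mz)
    hi = np.searchsorted(rec.mz_axis, hi_mz, side="right")
    trace = np.asarray(rec.spectra[:, lo:hi], dtype=float).sum(axis=1)
    return IonTrace(target_mz, window, trace)


def _local_maxima(trace: np.ndarray, half_width: int = 2) -> np.ndarray:
    """Boolean mask of strict local maxima over a +/-``half_width`` neighborhood.

    The trace is lightly smoothed first (1 s cadence against a ~4 s breath
    period; wider smoothing would merge cycles). The first index of a plateau
    counts as the maximum.
    """
    n = len(trace)
    if n >= 5:
        s = savgol_filter(trace, 5, 2)
    else:
        s = trace.astype(float)
    out = np.zeros(n, dtype=bool)
    for t in range(n):
        lo, hi = max(0, t - half_width), min(n, t + half_width + 1)
        window = s[lo:hi]
        if s[t] < window.max():
            continue
        if np.any(s[lo:t] >= s[t]):
            continue  # not the first index of the plateau
        if np.all(window == s[t]):
            continue  # locally flat, not a maximum
        out[t] = True
    return out


def segment_breaths(water_trace: IonTrace, tracer_traces: list[IonTrace],
                    water_threshold: float = WATER_THRESHOLD_CPS,
                    coincidence_halfwidth: int = 1) -> BreathPhaseResult:
    """Delineate breath cycles and select end-tidal spectra.

    A spectrum is selected iff the water adduct exceeds ``water_threshold``
    there AND at least two of the tracer traces have a local maximum within
    ``coincidence_halfwidth`` spectra. The cycle count is the number of maximal
    runs of water-above-threshold spectra.
    """
    n = len(water_trace.intensity)
    for tr in tracer_traces:
        if len(tr.intensity) != n:
            raise ContractError("water and tracer traces must share the time base")
    above = water_trace.intensity > water_threshold
    # count maximal runs of True
    padded = np.concatenate([[False], above, [False]])
    cycle_count = int(np.sum(np.diff(padded.astype(int)) == 1))

    tracer_max = np.array([_local_maxima(tr.intensity) for tr in tracer_traces])
    k = coincidence_halfwidth
    near_max = np.zeros((len(tracer_traces), n), dtype=bool)
    for j in range(tracer_max.shape[0]):
        idx = np.flatnonzero(tracer_max[j])
        for i in idx:
            near_max[j, max(0, i - k):i + k + 1] = True
    coincidence = near_max.sum(axis=0) >= 2

    selected = np.flatnonzero(above & coincidence)
    return BreathPhaseResult(
        selected_indices=selected,
        cycle_count=cycle_count,
        water_ok=above,
        tracer_coincidence=coincidence,
    )


def qc_recording(rec: RawRecording, phase: BreathPhaseResult,
                 calib: CalibrationModel | None = None,
                 capnostat_max: float = CAPNOSTAT_MAX_UNITS,
                 calibrant_max_ppm: float = CALIBRANT_MAX_PPM,
                 min_cycles: int = MIN_CYCLES,
                 capnostat_stat: str = "max") -> QCReport:
    """Apply the sample-level QC cascade; always returns a report.

    Criteria: capnostat max <= 3.5 units; worst calibrant residual < 100 ppm;
    at least three full respiratory cycles. The overall verdict is their
    conjunction.
    """
    stat_fn = {"max": np.max, "mean": np.mean}[capnostat_stat]
    cap_value = float(stat_fn(rec.capnostat))
    cap_pass = cap_value <= capnostat_max
    if calib is not None:
        worst_ppm = calib.max_residual_ppm
        cal_pass = worst_ppm < calibrant_max_ppm
    else:
        worst_ppm = float("nan")
        cal_pass = True
    cyc_pass = phase.cycle_count >= min_cycles
    return QCReport(
        capnostat_pass=bool(cap_pass),
        calibrant_pass=bool(cal_pass),
        cycles_pass=bool(cyc_pass),
        details={
            "capnostat_" + capnostat_stat: cap_value,
            "capnostat_limit": capnostat_max,
            "worst_calibrant_ppm": worst_ppm,
            "calibrant_limit_ppm": calibrant_max_ppm,
            "cycle_count": phase.cycle_count,
            "min_cycles": min_cycles,
            "n_selected_spectra": int(len(phase.selected_indices)),
        },
    )
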