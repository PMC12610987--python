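"""Synthetic breath recordings and cohorts with known ground truth.

The recording simulator emulates a one-minute real-time PTR-TOF-MS acquisition:
one full spectrum per second over m/z 10-685, 12-16 breath cycles, a water-adduct
ion and tracer VOCs (isoprene, dimethyl sulfide, 1,2-butadiene) that rise with
each exhalation, constant calibrant and internal-standard peaks, optional
mass-axis drift, counting-style noise, and a capnostat channel that co-varies
with exhalation but lags the water signal.

The cohort simulator produces the statistical structure the downstream modeling
assumes: an asthma / COPD / control clinical table with a bronchodilator-response
(BDR) endpoint, and paired tidal/forced feature matrices in which designated m/z
channels carry group- and BDR-linked mean shifts on top of noise features.

Exhalation is modeled as a raised-cosine bump occupying a fixed fraction of each
breath cycle; peaks on the m/z axis are Gaussian with constant resolving power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .raw_io import RawRecording

PERMASCAL_MZS = (21.0220, 203.94299, 330.85)
WATER_ADDUCT_MZ = 37.038
INTERNAL_STANDARD_MZ = 22.0274
# isoprene [M+H]+, dimethyl sulfide, 1,2-butadiene — the breath-phase tracers
DEFAULT_TRACERS = ((69.07, 4.0e4), (63.02, 2.0e4), (55.03, 1.5e4))


class InvalidConfigError(ValueError):
    """Simulation config violates an invariant."""


@dataclass
class RecordingSimConfig:
    """Parameters of one simulated sampling session.

    Intensities are apex amplitudes in cps. ``tracer_channels`` and
    ``extra_channels`` are (m/z, exhalation amplitude) pairs; extra channels model
    subject VOCs and co-modulate with exhalation like the tracers.
    """

    duration_s: float = 60.0
    spectra_per_s: float = 1.0
    breath_rate: float = 14.0           # cycles / min; physiological 12-16
    mz_range: tuple[float, float] = (10.0, 685.0)
    mz_step: float = 0.005              # Da, dense-grid spacing
    resolution: float = 1000.0          # m / FWHM of the TOF peak shape
    drift_ppm: float = 0.0              # mass-proportional axis drift
    noise_floor_cps: float = 20.0       # Gaussian floor s.d.
    noise_shot_scale: float = 1.0       # s.d. contribution ~ sqrt(intensity)
    tracer_channels: tuple = DEFAULT_TRACERS
    extra_channels: tuple = ()
    water_adduct_mz: float = WATER_ADDUCT_MZ
    water_baseline_cps: float = 5.0e3
    water_exhale_cps: float = 6.0e5
    internal_standard_mz: float = INTERNAL_STANDARD_MZ
    internal_standard_cps: float = 1.0e4
    calibrant_mzs: tuple[float, ...] = PERMASCAL_MZS
    calibrant_cps: tuple[float, ...] = (5.0e4, 2.0e4, 1.0e4)
    exhale_duty: float = 0.5            # fraction of the cycle spent exhaling
    capnostat_baseline: float = 0.2     # instrument units
    capnostat_excursion: float = 2.6
    capnostat_lag_s: float = 1.0        # CO2 sensor is slower than the water ion
    subject_id: str = "SIM"
    maneuver: str = "tidal"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        if self.breath_rate <= 0:
            raise InvalidConfigError("breath_rate must be positive")
        if self.breath_rate * self.duration_s / 60.0 < 1:
            raise InvalidConfigError("config must contain at least one breath cycle")
        if not 0 < self.exhale_duty < 1:
            raise InvalidConfigError("exhale_duty must be in (0, 1)")
        lo, hi = self.mz_range
        for mz in self.all_channel_mzs():
            if not lo <= mz <= hi:
                raise InvalidConfigError(f"channel m/z {mz} outside mz_range {self.mz_range}")

    def all_channel_mzs(self) -> list[float]:
        return (
            [self.water_adduct_mz, self.internal_standard_mz]
            + [m for m, _ in self.tracer_channels]
            + [m for m, _ in self.extra_channels]
            + list(self.calibrant_mzs)
        )


@dataclass
class GroundTruth:
    """What the simulator actually put into a recording."""

    cycle_spans: list[tuple[int, int]]      # [start, end) time-index span per cycle
    exhalation_midpoints: np.ndarray        # time index of peak exhalation per cycle
    exhalation_envelope: np.ndarray         # [0, 1] per time point
    channel_amplitudes: dict[float, float]  # m/z -> exhalation apex amplitude, cps

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_spans)


def _gaussian_deposit(spectra: np.ndarray, mz_axis: np.ndarray, mz: float,
                      amp_t: np.ndarray, sigma: float) -> None:
    """Add a Gaussian peak at ``mz`` with per-time apex amplitudes ``amp_t``."""
    lo = np.searchsorted(mz_axis, mz - 5 * sigma)
    hi = np.searchsorted(mz_axis, mz + 5 * sigma)
    if hi <= lo:
        return
    profile = np.exp(-0.5 * ((mz_axis[lo:hi] - mz) / sigma) ** 2)
    spectra[:, lo:hi] += np.outer(amp_t, profile).astype(spectra.dtype)


def simulate_recording(cfg: RecordingSimConfig) -> tuple[RawRecording, GroundTruth]:
    """Generate one recording plus its ground truth; fully determined by cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    times = np.arange(0, cfg.duration_s, 1.0 / cfg.spectra_per_s)
    n_t = len(times)
    mz_axis = np.arange(cfg.mz_range[0], cfg.mz_range[1] + cfg.mz_step / 2, cfg.mz_step)

    period = 60.0 / cfg.breath_rate
    n_cycles = int(np.floor(cfg.duration_s / period + 1e-9))
    phase = np.mod(times, period) / period
    env = np.where(
        phase < cfg.exhale_duty,
        0.5 * (1.0 - np.cos(2.0 * np.pi * phase / cfg.exhale_duty)),
        0.0,
    )

    cycle_spans = []
    midpoints = []
    cycle_idx = np.floor(times / period + 1e-9).astype(int)
    for k in range(n_cycles):
        members = np.flatnonzero(cycle_idx == k)
        if members.size == 0:
            continue
        cycle_spans.append((int(members[0]), int(members[-1]) + 1))
        in_cycle = env[members]
        midpoints.append(int(members[np.argmax(in_cycle)]))
    midpoints = np.asarray(midpoints, dtype=int)

    spectra = np.zeros((n_t, len(mz_axis)), dtype=np.float32)
    drift = 1.0 + cfg.drift_ppm * 1e-6  # mass-proportional (linear-in-m/z) shift
    amplitudes: dict[float, float] = {}

    def deposit(mz, amp_t, apex):
        mz_obs = mz * drift
        sigma = mz_obs / cfg.resolution / 2.3548
        _gaussian_deposit(spectra, mz_axis, mz_obs, amp_t, sigma)
        amplitudes[mz] = apex

    deposit(cfg.water_adduct_mz,
            cfg.water_baseline_cps + cfg.water_exhale_cps * env,
            cfg.water_exhale_cps)
    deposit(cfg.internal_standard_mz,
            np.full(n_t, cfg.internal_standard_cps), cfg.internal_standard_cps)
    for mz, amp in list(cfg.tracer_channels) + list(cfg.extra_channels):
        deposit(mz, 0.02 * amp + amp * env, amp)
    for mz, amp in zip(cfg.calibrant_mzs, cfg.calibrant_cps):
        deposit(mz, np.full(n_t, amp), amp)

    if cfg.noise_floor_cps > 0 or cfg.noise_shot_scale > 0:
        sd = cfg.noise_floor_cps + cfg.noise_shot_scale * np.sqrt(spectra)
        spectra = spectra + (rng.standard_normal(spectra.shape) * sd).astype(np.float32)
        np.clip(spectra, 0.0, None, out=spectra)

    lag = cfg.capnostat_lag_s
    env_lag = np.where(
        np.mod(times - lag, period) / period < cfg.exhale_duty,
        0.5 * (1 - np.cos(2 * np.pi * (np.mod(times - lag, period) / period) / cfg.exhale_duty)),
        0.0,
    )
    capnostat = cfg.capnostat_baseline + cfg.capnostat_excursion * env_lag
    if cfg.noise_floor_cps > 0:
        capnostat = capnostat + 0.01 * rng.standard_normal(n_t)

    rec = RawRecording(
        mz_axis=mz_axis,
        spectra=spectra,
        times=times,
        capnostat=capnostat,
        metadata={
            "subject_id": cfg.subject_id,
            "maneuver": cfg.maneuver,
            "acquired_at": "1970-01-01T00:00:00Z",
        },
    )
    truth = GroundTruth(
        cycle_spans=cycle_spans,
        exhalation_midpoints=midpoints,
        exhalation_envelope=env,
        channel_amplitudes=amplitudes,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class InformativeChannel:
    """A feature m/z whose mean depends on group and/or BDR status.

    ``group_means`` maps each diagnosis group to the channel's mean (normalized,
    dimensionless units); ``bdr_shift`` is added for BDR-positive subjects.
    """

    mz: float
    group_means: dict[str, float]
    sd: float
    bdr_shift: float = 0.0


# Defaults mirror the reported disease/BDR associations: m/z 79.054 elevated in
# asthma and in BDR-positive subjects, 95.054 elevated in asthma vs COPD,
# 118.071 depressed in COPD, 101.039 tracking BDR, 53/71/77 elevated in COPD.
DEFAULT_INFORMATIVE = (
    InformativeChannel(79.054, {"asthma": 0.020, "copd": 0.028, "control": 0.015}, 0.008, 0.010),
    InformativeChannel(95.054, {"asthma": 0.189, "copd": 0.138, "control": 0.150}, 0.045),
    InformativeChannel(118.071, {"asthma": 0.034, "copd": 0.022, "control": 0.034}, 0.010),
    InformativeChannel(101.039, {"asthma": 0.015, "copd": 0.015, "control": 0.012}, 0.006, 0.009),
    InformativeChannel(53.037, {"asthma": 0.040, "copd": 0.055, "control": 0.045}, 0.012),
    InformativeChannel(71.055, {"asthma": 0.030, "copd": 0.045, "control": 0.033}, 0.010),
    InformativeChannel(77.059, {"asthma": 0.025, "copd": 0.035, "control": 0.027}, 0.009),
)


@dataclass
class CohortSimConfig:
    """Cohort sizes, planted effects and nuisance structure.

    Group sizes default to the study scale (160 asthma / 128 COPD / 254
    controls). ``bdr_effect`` gives the additive mean shifts applied to clinical
    biomarkers of BDR-positive subjects (FeNO ppb, eosinophils x10^9/L, IgE
    IU/mL, post-BD FEV1 %predicted).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"asthma": 160, "copd": 128, "control": 254})
    informative_channels: tuple = DEFAULT_INFORMATIVE
    n_noise_features: int = 500
    noise_feature_scale: float = 0.02
    bdr_effect: dict[str, float] = field(
        default_factory=lambda: {"feno_ppb": 20.0, "eos_10e9_l": 0.20,
                                 "ige_iu_ml": 150.0, "fev1_pct_pred": -8.0})
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.n_per_group.values()) <= 0:
            raise InvalidConfigError("at least one group must be non-empty")
        if any(n < 0 for n in self.n_per_group.values()):
            raise InvalidConfigError("group sizes must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        for ch in self.informative_channels:
            if not all(np.isfinite(list(ch.group_means.values()))):
                raise InvalidConfigError(f"non-finite group mean for channel {ch.mz}")


# Post-bronchodilator change in FEV1 (% predicted): reported means/sds by group.
_DELTA_FEV1 = {"asthma": (16.570, 14.040), "copd": (10.583, 10.852), "control": (2.0, 3.0)}
_DELTA_FVC = {"asthma": (4.0, 6.0), "copd": (2.0, 5.0), "control": (1.0, 3.0)}
_FEV1_PCT = {"asthma": (75.0, 18.0), "copd": (55.0, 18.0), "control": (98.0, 10.0)}
_GROUP_PREFIX = {"asthma": "AS", "copd": "CP", "control": "CT"}
_SMOKING_P = {  # never / former / current
    "asthma": (0.7, 0.2, 0.1), "copd": (0.15, 0.45, 0.4), "control": (0.7, 0.2, 0.1)}


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, dict[str, FeatureMatrix]]:
    """Generate a clinical table and paired tidal/forced feature matrices.

    Returns
    -------
    cohort : DataFrame indexed by subject_id with the documented clinical header
        (group, spirometry, FeNO, eosinophils, IgE, smoking, BMI, bdr label).
    matrices : dict with 'tidal' and 'forced' :class:`FeatureMatrix`; both carry
        the same planted per-subject signal with independent measurement noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for group, n in cfg.n_per_group.items():
        for i in range(n):
            d_fev1 = rng.normal(*_DELTA_FEV1[group])
            d_fvc = rng.normal(*_DELTA_FVC[group])
            bdr = bool(d_fev1 > 10.0 or d_fvc > 10.0)
            feno = max(1.0, rng.normal(25.0 if group == "asthma" else 15.0, 10.0))
            eos = max(0.0, rng.normal(0.20 if group == "asthma" else 0.15, 0.10))
            ige = max(2.0, rng.lognormal(np.log(80.0), 0.8))
            fev1 = rng.normal(*_FEV1_PCT[group])
            if bdr:
                feno += cfg.bdr_effect.get("feno_ppb", 0.0)
                eos += cfg.bdr_effect.get("eos_10e9_l", 0.0)
                ige += cfg.bdr_effect.get("ige_iu_ml", 0.0)
                fev1 += cfg.bdr_effect.get("fev1_pct_pred", 0.0)
            rows.append({
                "subject_id": f"{_GROUP_PREFIX.get(group, group[:2].upper() + '_')}{i:04d}",
                "group": group,
                "fev1_pct_pred": fev1,
                "fvc_pct_pred": fev1 + rng.normal(8.0, 6.0),
                "delta_fev1_pct_pred": d_fev1,
                "delta_fvc_pct_pred": d_fvc,
                "feno_ppb": feno,
                "eos_10e9_l": eos,
                "ige_iu_ml": ige,
                "smoking": rng.choice(["never", "former", "current"], p=_SMOKING_P[group]),
                "bmi": rng.normal(26.0, 4.0),
                "bdr": "positive" if bdr else "negative",
            })
    cohort = pd.DataFrame(rows).set_index("subject_id")

    info_mzs = [ch.mz for ch in cfg.informative_channels]
    noise_mzs = np.sort(rng.uniform(42.0, 300.0, size=cfg.n_noise_features))
    feature_mzs = np.sort(np.concatenate([info_mzs, noise_mzs]))
    n_sub = len(cohort)

    # per-subject latent channel levels, shared between the two maneuvers;
    # maneuver-level measurement noise (half the subject s.d.) comes on top
    latent = np.zeros((n_sub, len(feature_mzs)))
    col_of = {mz: j for j, mz in enumerate(feature_mzs)}
    for ch in cfg.informative_channels:
        means = cohort["group"].map(ch.group_means).to_numpy(dtype=float)
        means = means + np.where(cohort["bdr"].to_numpy() == "positive", ch.bdr_shift, 0.0)
        latent[:, col_of[ch.mz]] = means + rng.normal(0.0, ch.sd, size=n_sub)
    for mz in noise_mzs:
        latent[:, col_of[mz]] = cfg.noise_feature_scale + rng.normal(
            0.0, cfg.noise_feature_scale / 2.0, size=n_sub)

    matrices = {}
    for maneuver in ("tidal", "forced"):
        noise = np.zeros_like(latent)
        for ch in cfg.informative_channels:
            noise[:, col_of[ch.mz]] = rng.normal(0.0, ch.sd / 2.0, size=n_sub)
        for mz in noise_mzs:
            noise[:, col_of[mz]] = rng.normal(0.0, cfg.noise_feature_scale / 4.0, size=n_sub)
        values = np.clip(latent + noise, 1e-4, None)
        df = pd.DataFrame(values, index=cohort.index, columns=feature_mzs)
        meta = pd.DataFrame({
            "subject": cohort.index,
            "maneuver": maneuver,
            "group": cohort["group"].to_numpy(),
            "bdr": cohort["bdr"].to_numpy(),
        }, index=cohort.index)
        matrices[maneuver] = FeatureMatrix(
            values=df,
            prevalence=pd.Series(1.0, index=df.columns),
            sample_meta=meta,
            normalized=True,
        )

    if cfg.missing_rate > 0:
        for col in ("feno_ppb", "eos_10e9_l", "ige_iu_ml", "bmi"):
            mask = rng.random(n_sub) < cfg.missing_rate
            cohort.loc[mask, col] = np.nan

    return cohort, matrices


def simulate_recording_cohort(out_dir, n_per_group: dict[str, int],
                              channel_amps_cps: dict[float, dict[str, float]] | None = None,
                              duration_s: float = 30.0, mz_range=(10.0, 340.0),
                              mz_step: float = 0.01, seed: int = 0,
                              recording_kwargs: dict | None = None
                              ) -> tuple[list[dict], pd.DataFrame]:
    """Write per-subject raw recordings (tidal + forced) with group-dependent
    VOC channel amplitudes, for exercising the pipeline end to end.

    ``channel_amps_cps`` maps a planted m/z to per-group mean exhalation
    amplitudes (cps); subject levels vary lognormally around the group mean and
    are shared between the two maneuvers of a subject. Returns the recordings
    manifest (path / sample_id / subject_id / maneuver dicts, pipeline-ready)
    and a matching clinical cohort table.
    """
    from pathlib import Path

    from .raw_io import write_recording

    if channel_amps_cps is None:
        channel_amps_cps = {
            79.054: {"asthma": 4.0e4, "copd": 3.0e4, "control": 1.5e4},
            95.054: {"asthma": 6.0e4, "copd": 3.0e4, "control": 3.5e4},
            118.071: {"asthma": 3.0e4, "copd": 1.2e4, "control": 3.0e4},
        }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cohort, _ = simulate_cohort(CohortSimConfig(n_per_group=dict(n_per_group),
                                                n_noise_features=0, seed=seed))
    recordings = []
    for subject_id, row in cohort.iterrows():
        amps = {mz: by_group[row["group"]] * rng.lognormal(0.0, 0.25)
                for mz, by_group in channel_amps_cps.items()}
        for maneuver in ("tidal", "forced"):
            cfg = RecordingSimConfig(
                duration_s=duration_s, mz_range=mz_range, mz_step=mz_step,
                extra_channels=tuple(sorted(amps.items())),
                subject_id=subject_id, maneuver=maneuver,
                seed=int(rng.integers(2**31 - 1)),
                **(recording_kwargs or {}))
            rec, _ = simulate_recording(cfg)
            sample_id = f"{subject_id}_{maneuver}"
            path = out_dir / f"{sample_id}.h5"
            write_recording(rec, path, overwrite=True)
            recordings.append({"path": str(path), "sample_id": sample_id,
                               "subject_id": subject_id, "maneuver": maneuver})
    return recordings, cohort
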