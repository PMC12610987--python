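"""Raw recording data model and HDF5 container I/O.

A recording is one ~60 s real-time PTR-TOF-MS sampling session: full spectra on a
shared dense m/z axis acquired once per second, plus an auxiliary capnostat (CO2)
channel sampled on the same time base.

Container layout (HDF5)::

    /mz_axis          float64[n_mz]      shared m/z grid, Da, strictly increasing
    /spectra          float32[n_t, n_mz] intensities, counts per second
    /times            float64[n_t]       seconds from acquisition start
    /aux/capnostat    float64[n_t]       capnostat reading, instrument units
    /meta             attrs: subject_id, maneuver, acquired_at

Unknown optional groups are ignored (with a logged warning) so that vendor-side
extensions do not break readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

_KNOWN_ROOT = {"mz_axis", "spectra", "times", "aux", "meta"}


class FormatError(ValueError):
    """Container does not conform to the documented layout."""


class ValidationError(ValueError):
    """In-memory recording violates a structural invariant."""


@dataclass
class RawRecording:
    """Time-resolved spectra for one sampling session.

    Attributes
    ----------
    mz_axis : ndarray, Da, strictly increasing, shared by all spectra.
    spectra : ndarray (n_times, n_mz), intensities in cps, nonnegative.
    times : ndarray, seconds from start.
    capnostat : ndarray, per-time CO2 channel in instrument units.
    metadata : dict with at least subject_id, maneuver ('tidal'|'forced'),
        acquired_at (ISO string).
    """

    mz_axis: np.ndarray
    spectra: np.ndarray
    times: np.ndarray
    capnostat: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.spectra = np.asarray(self.spectra)
        self.times = np.asarray(self.times, dtype=float)
        self.capnostat = np.asarray(self.capnostat, dtype=float)

    @property
    def n_spectra(self) -> int:
        return self.spectra.shape[0]

    def validate(self) -> None:
        if self.spectra.ndim != 2 or self.spectra.shape[0] == 0:
            raise ValidationError("recording must contain at least one spectrum")
        n_t = self.spectra.shape[0]
        if len(self.times) != n_t or len(self.capnostat) != n_t:
            raise ValidationError(
                "spectra, times and capnostat must share the time base "
                f"(got {n_t}, {len(self.times)}, {len(self.capnostat)})"
            )
        if self.spectra.shape[1] != len(self.mz_axis):
            raise ValidationError("spectra second axis must match mz_axis length")
        if len(self.mz_axis) < 2 or not np.all(np.diff(self.mz_axis) > 0):
            raise ValidationError("mz_axis must be strictly increasing")
        if np.any(self.spectra < 0):
            raise ValidationError("intensities must be nonnegative")


@dataclass
class SampleSpectrum:
    """Composite (exhalation-averaged) spectrum for one sample.

    ``provenance`` records which time indices of the source recording were
    averaged, so the end-tidal selection is auditable.
    """

    mz_axis: np.ndarray
    intensity: np.ndarray
    n_spectra_used: int
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=int)
        if self.n_spectra_used < 1:
            raise ValidationError("composite requires at least one source spectrum")
        if len(self.intensity) != len(self.mz_axis):
            raise ValidationError("intensity must match mz_axis length")


def write_recording(rec: RawRecording, path, *, overwrite: bool = False) -> Path:
    """Write a recording to the documented HDF5 layout; round-trip lossless."""
    rec.validate()
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("mz_axis", data=rec.mz_axis.astype(np.float64))
        f.create_dataset("spectra", data=rec.spectra)
        f.create_dataset("times", data=rec.times.astype(np.float64))
        aux = f.create_group("aux")
        aux.create_dataset("capnostat", data=rec.capnostat.astype(np.float64))
        meta = f.create_group("meta")
        for k, v in rec.metadata.items():
            meta.attrs[k] = v
    return path


def read_recording(path) -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If a mandatory dataset is absent (the message names it).
    ValidationError
        If the stored axis is not strictly increasing.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("mz_axis", "spectra", "times"):
            if name not in f:
                raise FormatError(f"mandatory dataset '{name}' missing from {path}")
        if "aux" not in f or "capnostat" not in f["aux"]:
            raise FormatError(f"mandatory dataset 'aux/capnostat' missing from {path}")
        for name in f:
            if name not in _KNOWN_ROOT:
                logger.warning("ignoring unknown group %r in %s", name, path)
        metadata = {}
        if "meta" in f:
            metadata = {k: _native(v) for k, v in f["meta"].attrs.items()}
        rec = RawRecording(
            mz_axis=f["mz_axis"][:],
            spectra=f["spectra"][:],
            times=f["times"][:],
            capnostat=f["aux"]["capnostat"][:],
            metadata=metadata,
        )
    rec.validate()
    return rec


def _native(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v
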