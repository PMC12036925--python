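"""Core in-memory containers shared by all processing stages.

The pipeline moves data between stages as plain numpy arrays wrapped in
lightweight dataclasses that carry acquisition metadata (echo times,
readout shifts, b-vectors, mixing times), voxel spacing, and — for derived
parameter maps — a validity mask plus per-voxel exclusion reason codes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeMeta",
    "AcquisitionSeries",
    "QuantitativeMap",
    "MuscleInfo",
    "MuscleLabelMap",
    "Spectrum",
    "EXCLUSION_CODES",
    "EXCLUSION_NAMES",
]

# Per-voxel / per-muscle exclusion reason codes shared across modalities.
EXCLUSION_CODES = {
    "none": 0,
    "t2_low": 1,          # water T2 < 15 ms
    "t2_high": 2,         # water T2 > 70 ms
    "b1_low": 3,          # B1+ < 80 % of prescribed flip angle
    "b1_high": 4,         # B1+ > 120 % of prescribed flip angle
    "ff_high": 5,         # FF > 60 % (water T1)
    "snr_low": 6,         # SNR < 15 (DTI)
    "olefinic_high": 7,   # olefinic FF > 10 % (DTI)
    "muscle_ff_high": 8,  # muscle mean FF > 50 % (DTI, muscle level)
    "too_few_voxels": 9,  # < 50 voxels in the muscle ROI
    "no_signal": 10,      # zero-signal voxel, fit undefined
    "no_convergence": 11,
    "corrupted": 12,      # generic manual/QC exclusion
}
EXCLUSION_NAMES = {v: k for k, v in EXCLUSION_CODES.items()}


@dataclass(frozen=True)
class VolumeMeta:
    """Acquisition metadata for one volume of a series.

    Only the fields relevant to the given modality are set: echo time for
    Dixon/MSE, readout shift and mixing time for the diffusion scans,
    b-value/b-vector for diffusion weighting, pulse index for fingerprints.
    """

    echo_time_ms: Optional[float] = None
    readout_shift_ms: Optional[float] = None
    mixing_time_ms: Optional[float] = None
    bvalue: Optional[float] = None              # s/mm^2
    bvec: Optional[tuple[float, float, float]] = None
    bmatrix: Optional[tuple[float, ...]] = None  # row-major 3x3, s/mm^2
    pulse_index: Optional[int] = None


@dataclass
class AcquisitionSeries:
    """A stack of image volumes with per-volume acquisition metadata.

    ``data`` has shape (nx, ny, nz, nvol); complex for chemical-shift
    encoded acquisitions, real magnitude otherwise.  ``spacing`` is the
    voxel size in mm.  Extra acquisition constants (fat-water frequency
    offset, transmitter frequency, ...) live in ``constants``.
    """

    data: np.ndarray
    meta: list[VolumeMeta]
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4-D (x, y, z, volume)")
        if self.data.shape[-1] != len(self.meta):
            raise ValueError(
                f"{self.data.shape[-1]} volumes but {len(self.meta)} metadata entries"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def echo_times(self) -> np.ndarray:
        return np.array([m.echo_time_ms for m in self.meta], dtype=float)

    def affine(self) -> np.ndarray:
        return np.diag([*self.spacing, 1.0])

    def to_nifti(self, path: str | Path) -> None:
        """Write magnitude (and, for complex data, phase) NIfTI volumes."""
        path = Path(path)
        if np.iscomplexobj(self.data):
            nib.save(nib.Nifti1Image(np.abs(self.data), self.affine()), str(path))
            phase_path = path.with_name(path.name.replace(".nii", "_phase.nii"))
            nib.save(nib.Nifti1Image(np.angle(self.data), self.affine()), str(phase_path))
        else:
            nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine()), str(path))


@dataclass
class QuantitativeMap:
    """One scalar parameter per voxel plus validity mask and reason codes.

    ``values`` is float (NaN where undefined); ``valid`` marks voxels that
    carry a usable estimate; ``reason`` holds an ``EXCLUSION_CODES`` entry
    for every invalid voxel (0 elsewhere).
    """

    name: str
    units: str
    values: np.ndarray
    valid: np.ndarray
    reason: np.ndarray = None  # type: ignore[assignment]
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.reason is None:
            self.reason = np.zeros(self.values.shape, dtype=np.int8)
        self.reason = np.asarray(self.reason, dtype=np.int8)
        if not (self.values.shape == self.valid.shape == self.reason.shape):
            raise ValueError("values, valid and reason must share one shape")

    def exclude(self, where: np.ndarray, reason: str) -> None:
        """Mask ``where`` voxels, recording ``reason``; idempotent on
        voxels that are already invalid (first reason wins)."""
        where = np.asarray(where, dtype=bool) & self.valid
        self.valid[where] = False
        self.reason[where] = EXCLUSION_CODES[reason]

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.masked().astype(np.float32), affine), str(path))
        rpath = Path(path)
        rpath = rpath.with_name(rpath.name.replace(".nii", "_reason.nii"))
        nib.save(nib.Nifti1Image(self.reason.astype(np.int16), affine), str(rpath))


@dataclass(frozen=True)
class MuscleInfo:
    """Dictionary entry for one muscle ROI label."""

    label: int
    code: str          # e.g. "VL"
    name: str          # e.g. "vastus lateralis"
    side: str          # "L" or "R"
    compartment: str   # "thigh" or "leg"
    group: Optional[str] = None  # QUAD / HSTR / ANT / FIB / TRIC


@dataclass
class MuscleLabelMap:
    """Integer-labelled ROI volume with a muscle dictionary."""

    labels: np.ndarray
    muscles: dict[int, MuscleInfo]
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def present_labels(self) -> list[int]:
        found = set(np.unique(self.labels).tolist()) - {0}
        return sorted(found)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))

    def dictionary_json(self) -> str:
        return json.dumps(
            {str(k): dataclasses.asdict(v) for k, v in self.muscles.items()}, indent=2
        )


@dataclass
class Spectrum:
    """A single-voxel proton spectrum on a ppm axis referenced to water.

    ``ppm`` is monotone; ``signal`` may be complex or magnitude.
    """

    ppm: np.ndarray
    signal: np.ndarray
    transmitter_mhz: float = 123.2

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.signal = np.asarray(self.signal)
        if self.ppm.ndim != 1 or self.ppm.shape != self.signal.shape:
            raise ValueError("ppm and signal must be matching 1-D arrays")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    @property
    def resolution_ppm(self) -> float:
        return float(abs(np.median(np.diff(self.ppm))))

    def magnitude(self) -> np.ndarray:
        return np.abs(self.signal)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ppm": self.ppm.tolist(),
            "real": np.real(self.signal).tolist(),
            "imag": np.imag(self.signal).tolist(),
            "transmitter_mhz": self.transmitter_mhz,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Spectrum":
        payload = json.loads(Path(path).read_text())
        signal = np.array(payload["real"], dtype=float)
        imag = np.array(payload.get("imag", np.zeros_like(signal)), dtype=float)
        if np.any(imag != 0):
            signal = signal + 1j * imag
        return cls(
            ppm=np.array(payload["ppm"], dtype=float),
            signal=signal,
            transmitter_mhz=float(payload.get("transmitter_mhz", 123.2)),
        )
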