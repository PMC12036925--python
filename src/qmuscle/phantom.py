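"""Synthetic lower-limb phantom with per-muscle ground truth.

Every downstream stage of the pipeline (Dixon fat-water separation,
tri-exponential water T2, fingerprint T1 matching, fat-suppressed DTI,
MRS pH) is exercised against acquisitions generated here from known
per-muscle parameter values, so recovery accuracy can be measured
voxel-by-voxel without patient data.

Muscles are non-overlapping elliptical cylinders on a regular grid.  Each
carries a true fat fraction, water T2, water T1, T2*, a diffusion tensor
(eigenvalues + principal axis), an olefinic fat fraction and a pH.  Smooth
multiplicative B1+ and additive off-resonance (psi) fields model hardware
imperfections; Rician noise is realized by adding i.i.d. complex Gaussian
noise before any magnitude operation.

Forward models
--------------
Dixon (3 echoes)        S(TE) = (W + F e^{i 2 pi df_fat TE}) e^{i 2 pi psi TE} e^{-TE/T2*}
Multi-echo spin echo    s(TE) = A_w e^{-TE/T2w} + A_f (p1 e^{-TE/T2f1} + p2 e^{-TE/T2f2})
Diffusion + DOFS        S(ts; b, g) = (W e^{-b g^T D g} + F_ol e^{i 2 pi df_ol ts} e^{-b d_f}) e^{i 2 pi psi ts}
Fingerprint             inversion-prepared spoiled-gradient-echo recursion (variable flip angles)
Spectrum                water + carnosine-C2H Lorentzians; the C2H shift encodes pH
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import AcquisitionSeries, MuscleInfo, MuscleLabelMap, Spectrum, VolumeMeta

__all__ = [
    "MuscleSpec",
    "FingerprintSchedule",
    "PhantomConfig",
    "PhantomGroundTruth",
    "realize_phantom",
    "generate_dixon_series",
    "generate_mse_series",
    "generate_dti_series",
    "generate_fingerprint_series",
    "generate_spectrum",
    "fingerprint_signal",
    "default_config",
    "write_phantom",
    "add_complex_noise",
    "sigma_for_snr",
    "DEFAULT_DIRECTIONS",
]

# 3 T proton frequency and chemical-shift constants (configurable below).
LARMOR_MHZ = 123.2
FAT_SHIFT_PPM = -3.4          # main aliphatic peak relative to water
OLEFINIC_SHIFT_PPM = +0.6     # olefinic peak (~5.3 ppm) relative to water (4.7 ppm)
FAT_T1_MS = 371.0
# Two-component fat T2 model used by both the generator and the water-T2
# fit.  Both fat T2s sit above the 15-70 ms muscle-water window so the
# water component stays identifiable from 17 magnitude echoes.
FAT_T2_COMPONENTS = ((0.56, 231.0), (0.44, 83.0))  # (weight, T2 ms)
FAT_DIFFUSIVITY = 0.05        # um^2/ms, quasi-restricted fat diffusion

# Non-coplanar 6-direction diffusion-encoding set (icosahedral style).
DEFAULT_DIRECTIONS = np.array(
    [
        [1, 0, 1], [-1, 0, 1], [0, 1, 1],
        [0, 1, -1], [1, 1, 0], [-1, 1, 0],
    ],
    dtype=float,
) / np.sqrt(2.0)


class MuscleSpec(BaseModel):
    """Ground-truth parameters of one elliptical-cylinder muscle."""

    label: int
    code: str
    name: str = ""
    side: str = "R"
    compartment: str = "thigh"
    group: Optional[str] = None
    center: tuple[float, float]      # fraction of FOV, (x, y) in [0, 1]
    semiaxes: tuple[float, float]    # fraction of FOV
    ff: float = 5.0                  # %
    t2w_ms: float = 32.0
    t1w_ms: float = 1200.0
    t2star_ms: float = 25.0
    eigenvalues: tuple[float, float, float] = (2.0, 1.5, 1.3)  # um^2/ms, descending
    axis_tilt_deg: float = 0.0       # principal-axis tilt away from z
    ph: float = 7.05
    olefinic_fraction: float = 0.0   # residual olefinic fat in the DTI scan

    @field_validator("ff")
    @classmethod
    def _ff_range(cls, v: float) -> float:
        if not 0.0 <= v <= 100.0:
            raise ValueError("FF must lie in [0, 100] %")
        return v

    @field_validator("eigenvalues")
    @classmethod
    def _eig_sorted_positive(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("tensor eigenvalues must be positive")
        if not (v[0] >= v[1] >= v[2]):
            raise ValueError("eigenvalues must be sorted descending")
        return v


class FingerprintSchedule(BaseModel):
    """Flip-angle/TR pattern of the inversion-prepared fingerprint scan."""

    flip_deg: list[float]
    tr_ms: list[float]
    invert: bool = True

    @model_validator(mode="after")
    def _lengths(self):
        if len(self.flip_deg) == 0:
            raise ValueError("fingerprint schedule must contain at least one pulse")
        if len(self.flip_deg) != len(self.tr_ms):
            raise ValueError("flip_deg and tr_ms must have equal length")
        return self

    @classmethod
    def default(cls, n_pulses: int = 400, tr_ms: float = 12.0) -> "FingerprintSchedule":
        i = np.arange(n_pulses)
        flips = 10.0 + 50.0 * np.sin(np.pi * (i + 1) / n_pulses)
        return cls(flip_deg=flips.tolist(), tr_ms=[tr_ms] * n_pulses)


class PhantomConfig(BaseModel):
    """Full description of the synthetic acquisition session."""

    nx: int = 64
    ny: int = 64
    nz: int = 5
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    muscles: list[MuscleSpec]
    # acquisition timings
    dixon_te_ms: tuple[float, float, float] = (2.75, 3.95, 5.15)
    mse_echo_spacing_ms: float = 9.5
    mse_n_echoes: int = 17
    dti_bvalue: float = 400.0                       # s/mm^2
    dti_readout_shifts_ms: tuple[float, ...] = (1.1, 3.3, 5.5, 7.8, 10.0, 12.2)
    dti_mixing_times_ms: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0)
    fingerprint: FingerprintSchedule = Field(default_factory=FingerprintSchedule.default)
    # physics constants
    larmor_mhz: float = LARMOR_MHZ
    fat_shift_ppm: float = FAT_SHIFT_PPM
    olefinic_shift_ppm: float = OLEFINIC_SHIFT_PPM
    fat_t1_ms: float = FAT_T1_MS
    # field models
    b1_range: tuple[float, float] = (0.85, 1.15)    # fraction of nominal
    psi_amplitude_hz: float = 30.0                  # off-resonance amplitude
    noise_sigma: float = 0.0                        # absolute signal units (S0 = 1)
    seed: int = 0

    @field_validator("b1_range")
    @classmethod
    def _b1_positive(cls, v):
        if v[0] <= 0 or v[1] <= v[0]:
            raise ValueError("B1 range must be positive and increasing")
        return v

    @field_validator("noise_sigma")
    @classmethod
    def _sigma_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise sigma must be >= 0")
        return v

    @model_validator(mode="after")
    def _check(self):
        labels = [m.label for m in self.muscles]
        if len(labels) != len(set(labels)):
            raise ValueError("muscle labels must be unique")
        te = self.dixon_te_ms
        if not (te[0] < te[1] < te[2]):
            raise ValueError("Dixon echo times must be strictly increasing")
        return self

    @property
    def fat_shift_hz(self) -> float:
        return self.fat_shift_ppm * self.larmor_mhz

    @property
    def olefinic_shift_hz(self) -> float:
        return self.olefinic_shift_ppm * self.larmor_mhz

    def grid_shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)


# --------------------------------------------------------------------------
# realization


@dataclass
class PhantomGroundTruth:
    """Realized per-voxel truth maps plus the muscle truth table."""

    config: PhantomConfig
    label_map: MuscleLabelMap
    ff: np.ndarray            # %, 0 outside muscle
    t2w_ms: np.ndarray
    t1w_ms: np.ndarray
    t2star_ms: np.ndarray
    tensor: np.ndarray        # (nx, ny, nz, 3, 3) um^2/ms
    olefinic: np.ndarray      # fraction
    b1: np.ndarray            # fraction of nominal
    psi_hz: np.ndarray
    truth_table: pd.DataFrame

    @property
    def muscle_mask(self) -> np.ndarray:
        return self.label_map.labels > 0


def _rotation_from_z(tilt_deg: float) -> np.ndarray:
    """Rotation taking the z axis to a fibre direction tilted in the x-z plane."""
    t = np.deg2rad(tilt_deg)
    return np.array(
        [[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]]
    )


def _smooth_fields(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic smooth B1+ (multiplicative) and psi (Hz) fields."""
    nx, ny, nz = config.grid_shape()
    x = (np.arange(nx) + 0.5) / nx - 0.5
    y = (np.arange(ny) + 0.5) / ny - 0.5
    xx, yy = np.meshgrid(x, y, indexing="ij")
    # radially falling transmit field, scaled exactly into the configured range
    g = 1.0 - 2.0 * (xx**2 + yy**2) / 0.5
    g = (g - g.min()) / (g.max() - g.min())  # [0, 1]
    lo, hi = config.b1_range
    b1_2d = lo + (hi - lo) * g
    # smooth off-resonance: tilted plane plus a central bump
    psi_2d = config.psi_amplitude_hz * (
        0.6 * (xx + yy) + 0.4 * np.exp(-((xx**2 + yy**2) / 0.08))
    )
    b1 = np.repeat(b1_2d[:, :, None], nz, axis=2)
    psi = np.repeat(psi_2d[:, :, None], nz, axis=2)
    return b1, psi


def realize_phantom(config: PhantomConfig) -> PhantomGroundTruth:
    """Rasterize the muscle layout and assemble all per-voxel truth maps."""
    nx, ny, nz = config.grid_shape()
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    ff = np.zeros((nx, ny, nz))
    t2w = np.zeros_like(ff)
    t1w = np.zeros_like(ff)
    t2star = np.zeros_like(ff)
    olefinic = np.zeros_like(ff)
    tensor = np.zeros((nx, ny, nz, 3, 3))

    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    xx, yy = np.meshgrid(x, y, indexing="ij")

    muscles: dict[int, MuscleInfo] = {}
    rows = []
    for m in config.muscles:
        cx, cy = m.center
        ax, ay = m.semiaxes
        inside = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        if np.any(labels[inside, :] != 0):
            raise ValueError(f"muscle {m.code} ({m.label}) overlaps an earlier muscle")
        labels[inside, :] = m.label
        ff[inside, :] = m.ff
        t2w[inside, :] = m.t2w_ms
        t1w[inside, :] = m.t1w_ms
        t2star[inside, :] = m.t2star_ms
        olefinic[inside, :] = m.olefinic_fraction
        R = _rotation_from_z(m.axis_tilt_deg)
        D = R @ np.diag(m.eigenvalues) @ R.T
        tensor[inside, :, :, :] = D
        muscles[m.label] = MuscleInfo(
            label=m.label, code=m.code, name=m.name or m.code,
            side=m.side, compartment=m.compartment, group=m.group,
        )
        lam = m.eigenvalues
        md = sum(lam) / 3.0
        rows.append(
            dict(
                label=m.label, code=m.code, side=m.side, compartment=m.compartment,
                ff=m.ff, t2w_ms=m.t2w_ms, t1w_ms=m.t1w_ms, t2star_ms=m.t2star_ms,
                lambda1=lam[0], lambda2=lam[1], lambda3=lam[2], md=md,
                fa=_fa_from_eigenvalues(lam), ph=m.ph,
                olefinic_fraction=m.olefinic_fraction,
                n_voxels=int(np.count_nonzero(labels == m.label)),
            )
        )

    b1, psi = _smooth_fields(config)
    return PhantomGroundTruth(
        config=config,
        label_map=MuscleLabelMap(labels=labels, muscles=muscles, spacing=config.spacing),
        ff=ff, t2w_ms=t2w, t1w_ms=t1w, t2star_ms=t2star,
        tensor=tensor, olefinic=olefinic, b1=b1, psi_hz=psi,
        truth_table=pd.DataFrame(rows),
    )


def _fa_from_eigenvalues(lam: Sequence[float]) -> float:
    lam = np.asarray(lam, dtype=float)
    md = lam.mean()
    num = np.sqrt(((lam - md) ** 2).sum())
    den = np.sqrt((lam**2).sum())
    return float(np.sqrt(1.5) * num / den) if den > 0 else 0.0


def _rng(config: PhantomConfig, stream: int) -> np.random.Generator:
    # one independent, reproducible stream per modality
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _complex_noise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    if sigma == 0:
        return np.zeros(shape, dtype=complex)
    return rng.normal(0.0, sigma, shape) + 1j * rng.normal(0.0, sigma, shape)


# --------------------------------------------------------------------------
# forward models


def generate_dixon_series(
    config: PhantomConfig, truth: Optional[PhantomGroundTruth] = None
) -> AcquisitionSeries:
    """Three-echo chemical-shift-encoded gradient-echo series (complex)."""
    truth = truth or realize_phantom(config)
    te = np.asarray(config.dixon_te_ms) * 1e-3  # s
    w = np.where(truth.muscle_mask, 1.0 - truth.ff / 100.0, 0.0)
    f = np.where(truth.muscle_mask, truth.ff / 100.0, 0.0)
    r2star = np.zeros_like(truth.t2star_ms)
    np.divide(1.0, truth.t2star_ms * 1e-3, out=r2star, where=truth.t2star_ms > 0)
    rng = _rng(config, 1)
    vols = []
    for t in te:
        s = (w + f * np.exp(2j * np.pi * config.fat_shift_hz * t)) * np.exp(
            2j * np.pi * truth.psi_hz * t - r2star * t
        )
        vols.append(s + _complex_noise(rng, config.noise_sigma, s.shape))
    data = np.stack(vols, axis=-1)
    meta = [VolumeMeta(echo_time_ms=float(t * 1e3)) for t in te]
    return AcquisitionSeries(
        data=data, meta=meta, spacing=config.spacing,
        constants={"fat_shift_hz": config.fat_shift_hz, "larmor_mhz": config.larmor_mhz},
    )


def mse_echo_times(config: PhantomConfig) -> np.ndarray:
    n = config.mse_n_echoes
    return config.mse_echo_spacing_ms * np.arange(1, n + 1)


def generate_mse_series(
    config: PhantomConfig, truth: Optional[PhantomGroundTruth] = None
) -> AcquisitionSeries:
    """17-echo multi-echo spin-echo magnitude series for water-T2 mapping."""
    truth = truth or realize_phantom(config)
    te = mse_echo_times(config)  # ms
    aw = np.where(truth.muscle_mask, 1.0 - truth.ff / 100.0, 0.0)
    af = np.where(truth.muscle_mask, truth.ff / 100.0, 0.0)
    # excitation-amplitude weighting by the local transmit field (nominal 90 deg)
    b1w = np.sin(np.pi / 2.0 * truth.b1)
    inv_t2w = np.zeros_like(truth.t2w_ms)
    np.divide(1.0, truth.t2w_ms, out=inv_t2w, where=truth.t2w_ms > 0)
    rng = _rng(config, 2)
    vols = []
    for t in te:
        fat = sum(p * np.exp(-t / t2f) for p, t2f in FAT_T2_COMPONENTS)
        s = b1w * (aw * np.exp(-t * inv_t2w) + af * fat)
        noisy = np.abs(s + _complex_noise(rng, config.noise_sigma, s.shape))
        vols.append(noisy)
    data = np.stack(vols, axis=-1)
    meta = [VolumeMeta(echo_time_ms=float(t)) for t in te]
    return AcquisitionSeries(data=data, meta=meta, spacing=config.spacing)


def generate_dti_series(
    config: PhantomConfig,
    truth: Optional[PhantomGroundTruth] = None,
    mixing_time_ms: float = 100.0,
    directions: Optional[np.ndarray] = None,
) -> AcquisitionSeries:
    """Stimulated-echo diffusion series with olefinic contamination.

    Volumes are ordered shift-major: for each readout shift, one b = 0
    volume followed by the diffusion-weighted directions.  The complex
    signal keeps the chemical-shift phase evolution of the olefinic fat
    across readout shifts so the fat-water decomposition stage is testable.
    """
    truth = truth or realize_phantom(config)
    directions = DEFAULT_DIRECTIONS if directions is None else np.asarray(directions, float)
    if directions.shape[0] < 6:
        raise ValueError("at least 6 non-coplanar diffusion directions are required")
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    b = config.dti_bvalue  # s/mm^2
    # b * g^T D g with D in um^2/ms = 1e-3 mm^2/s
    att = np.empty(truth.tensor.shape[:3] + (len(directions),))
    for k, g in enumerate(directions):
        att[..., k] = np.einsum("...ij,i,j->...", truth.tensor, g, g) * 1e-3 * b
    w_amp = np.where(truth.muscle_mask, 1.0 - truth.olefinic, 0.0)
    f_amp = np.where(truth.muscle_mask, truth.olefinic, 0.0)
    rng = _rng(config, 3)
    vols, meta = [], []
    for ts in config.dti_readout_shifts_ms:
        phase = np.exp(2j * np.pi * truth.psi_hz * ts * 1e-3)
        fat_phase = np.exp(2j * np.pi * config.olefinic_shift_hz * ts * 1e-3)
        bset = [(0.0, None)] + [(b, k) for k in range(len(directions))]
        for bval, k in bset:
            if k is None:
                water = w_amp
            else:
                water = w_amp * np.exp(-att[..., k])
            fat = f_amp * np.exp(-bval * FAT_DIFFUSIVITY * 1e-3) * fat_phase
            s = (water + fat) * phase
            vols.append(s + _complex_noise(rng, config.noise_sigma, s.shape))
            gvec = (0.0, 0.0, 0.0) if k is None else tuple(directions[k])
            bmat = np.zeros((3, 3)) if k is None else bval * np.outer(directions[k], directions[k])
            meta.append(
                VolumeMeta(
                    readout_shift_ms=float(ts),
                    mixing_time_ms=float(mixing_time_ms),
                    bvalue=float(bval),
                    bvec=gvec,
                    bmatrix=tuple(bmat.ravel()),
                )
            )
    data = np.stack(vols, axis=-1)
    return AcquisitionSeries(
        data=data, meta=meta, spacing=config.spacing,
        constants={
            "olefinic_shift_hz": config.olefinic_shift_hz,
            "mixing_time_ms": float(mixing_time_ms),
        },
    )


def fingerprint_signal(
    t1_ms: np.ndarray | float,
    schedule: FingerprintSchedule,
    b1: np.ndarray | float = 1.0,
    m0: float = 1.0,
) -> np.ndarray:
    """Signal time-course of the inversion-prepared spoiled-GRE recursion.

    Longitudinal magnetization starts at -m0 after (perfect) inversion; each
    pulse with actual flip ``b1 * alpha_i`` reads out ``Mz sin`` and tips the
    remainder, which then relaxes toward m0 over TR_i.  Broadcasts over
    arrays of T1 and B1 (returned shape ``broadcast(t1, b1) + (n_pulses,)``).
    """
    t1 = np.asarray(t1_ms, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    shape = np.broadcast_shapes(t1.shape, b1.shape)
    t1 = np.broadcast_to(t1, shape).copy()
    b1 = np.broadcast_to(b1, shape)
    mz = np.full(shape, -m0 if schedule.invert else m0, dtype=float)
    out = np.empty(shape + (len(schedule.flip_deg),), dtype=float)
    with np.errstate(divide="ignore"):
        inv_t1 = np.where(t1 > 0, 1.0 / t1, np.inf)
    for i, (flip, tr) in enumerate(zip(schedule.flip_deg, schedule.tr_ms)):
        a = np.deg2rad(flip) * b1
        out[..., i] = mz * np.sin(a)
        mz = mz * np.cos(a)
        e1 = np.exp(-tr * inv_t1)
        mz = m0 + (mz - m0) * e1
    return out


def generate_fingerprint_series(
    config: PhantomConfig, truth: Optional[PhantomGroundTruth] = None
) -> AcquisitionSeries:
    """Per-voxel fingerprint time-courses from the two-compartment model."""
    truth = truth or realize_phantom(config)
    sched = config.fingerprint
    mask = truth.muscle_mask
    t1w = truth.t1w_ms[mask]
    b1 = truth.b1[mask]
    frac = truth.ff[mask] / 100.0
    water = fingerprint_signal(t1w, sched, b1)
    fat = fingerprint_signal(np.full_like(t1w, config.fat_t1_ms), sched, b1)
    courses = (1.0 - frac)[:, None] * water + frac[:, None] * fat
    n_pulse = len(sched.flip_deg)
    data = np.zeros(truth.ff.shape + (n_pulse,))
    data[mask] = courses
    rng = _rng(config, 4)
    if config.noise_sigma > 0:
        data = np.abs(data + _complex_noise(rng, config.noise_sigma, data.shape)).real
    meta = [VolumeMeta(pulse_index=i) for i in range(n_pulse)]
    return AcquisitionSeries(
        data=data, meta=meta, spacing=config.spacing,
        constants={"fat_t1_ms": config.fat_t1_ms},
    )


def generate_spectrum(
    config: PhantomConfig,
    ph: float = 7.05,
    muscle_ff: float = 5.0,
    n_points: int = 4096,
    ppm_range: tuple[float, float] = (0.0, 10.0),
    water_ppm: float = 4.70,
    carnosine_amplitude: float = 0.06,
    linewidth_ppm: float = 0.03,
) -> Spectrum:
    """Single-voxel spectrum with a pH-encoding carnosine C2H resonance.

    The C2H chemical shift follows the Henderson-Hasselbalch titration
    curve of the imidazole C2 proton; its amplitude falls with the muscle
    fat fraction, emulating the SNR loss in fat-replaced muscle.
    """
    from .mrs import DEFAULT_CALIBRATION, shift_for_ph

    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    delta = shift_for_ph(ph, DEFAULT_CALIBRATION)

    def lorentz(center: float, amp: float, width: float) -> np.ndarray:
        return amp * (width / 2) ** 2 / ((ppm - center) ** 2 + (width / 2) ** 2)

    signal = lorentz(water_ppm, 1.0, 2 * linewidth_ppm).astype(complex)
    amp = carnosine_amplitude * max(1.0 - muscle_ff / 100.0, 0.0)
    signal += lorentz(delta, amp, linewidth_ppm)
    rng = _rng(config, 5)
    signal += _complex_noise(rng, config.noise_sigma, signal.shape)
    return Spectrum(ppm=ppm, signal=signal, transmitter_mhz=config.larmor_mhz)


# --------------------------------------------------------------------------
# default layout and serialization


def default_config(
    nx: int = 64, ny: int = 64, nz: int = 5,
    noise_sigma: float = 0.0, seed: int = 0, bilateral: bool = False,
    olefinic_fraction: float = 0.0,
) -> PhantomConfig:
    """A lower-leg layout spanning the disease range of the parameters.

    Six muscles per side cover FF from near-normal (2 %) to strongly
    fat-replaced (60 %), water T2 from normal (~28 ms) to pathologically
    elevated (45 ms), water T1 1.0-1.5 s, and tensors with MD 1.4-1.8
    um^2/ms and FA 0.2-0.35.
    """
    base = [
        # code, compartment, group, ff, t2w, t1w, t2*, eigenvalues, ph
        ("TA", "leg", "ANT", 2.0, 28.0, 1400.0, 28.0, (2.10, 1.55, 1.35), 7.00),
        ("TP", "leg", "ANT", 10.0, 32.0, 1300.0, 26.0, (2.00, 1.50, 1.30), 7.02),
        ("PER", "leg", "FIB", 20.0, 35.0, 1250.0, 24.0, (1.95, 1.45, 1.25), 7.05),
        ("SOL", "leg", "TRIC", 30.0, 38.0, 1200.0, 22.0, (1.90, 1.40, 1.20), 7.08),
        ("GM", "leg", "TRIC", 45.0, 42.0, 1100.0, 20.0, (1.85, 1.35, 1.15), 7.10),
        ("GL", "leg", "TRIC", 60.0, 45.0, 1000.0, 18.0, (1.80, 1.30, 1.10), 7.12),
    ]
    centers = [(0.22, 0.25), (0.22, 0.58), (0.5, 0.22), (0.5, 0.62), (0.78, 0.3), (0.78, 0.65)]
    sides = ["R", "L"] if bilateral else ["R"]
    muscles = []
    for iside, side in enumerate(sides):
        for k, ((code, comp, grp, ff, t2w, t1w, t2s, lam, ph), (cx, cy)) in enumerate(
            zip(base, centers)
        ):
            cy = cy / 2 + 0.5 * iside if bilateral else cy
            ay = 0.055 if bilateral else 0.11
            muscles.append(
                MuscleSpec(
                    label=iside * len(base) + k + 1, code=code, side=side,
                    compartment=comp, group=grp, center=(cx, cy),
                    semiaxes=(0.09, ay), ff=ff, t2w_ms=t2w, t1w_ms=t1w,
                    t2star_ms=t2s, eigenvalues=lam, axis_tilt_deg=8.0, ph=ph,
                    olefinic_fraction=olefinic_fraction,
                )
            )
    return PhantomConfig(
        nx=nx, ny=ny, nz=nz, muscles=muscles, noise_sigma=noise_sigma, seed=seed
    )


def sigma_for_snr(series: AcquisitionSeries, mask: np.ndarray, snr: float) -> float:
    """Noise SD giving SNR = mean first-volume tissue signal / sigma."""
    if snr <= 0:
        raise ValueError("SNR must be positive")
    return float(np.mean(np.abs(series.data[..., 0])[np.asarray(mask, bool)])) / snr


def add_complex_noise(
    series: AcquisitionSeries, sigma: float, seed: int
) -> AcquisitionSeries:
    """Add circular complex Gaussian noise of SD ``sigma`` per channel in
    place (magnitude data become Rician once the caller takes ``abs``)."""
    rng = np.random.default_rng(seed)
    noise = sigma * (rng.normal(size=series.data.shape)
                     + 1j * rng.normal(size=series.data.shape))
    series.data[:] = series.data + noise
    return series


def write_phantom(config: PhantomConfig, out_dir: str | Path) -> PhantomGroundTruth:
    """Generate all modalities and write them (NIfTI + JSON + CSV) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = realize_phantom(config)
    generate_dixon_series(config, truth).to_nifti(out / "dixon.nii.gz")
    generate_mse_series(config, truth).to_nifti(out / "mse.nii.gz")
    generate_dti_series(config, truth).to_nifti(out / "dti_tm100.nii.gz")
    generate_fingerprint_series(config, truth).to_nifti(out / "fingerprint.nii.gz")
    truth.label_map.to_nifti(out / "labels.nii.gz")
    import nibabel as nib

    affine = np.diag([*config.spacing, 1.0])
    nib.save(nib.Nifti1Image((truth.b1 * 100).astype(np.float32), affine), str(out / "b1_percent.nii.gz"))
    generate_spectrum(config).to_json(out / "spectrum.json")
    truth.truth_table.to_csv(out / "truth.csv", index=False)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    (out / "muscles.json").write_text(truth.label_map.dictionary_json())
    return truth
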