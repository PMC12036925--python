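"""Muscle diffusion processing: noise/SNR, olefinic fat-water
decomposition, b-matrix handling, tensor fitting and exclusion rules.

The diffusion scan suppresses the main aliphatic fat peak spectrally, but
the olefinic fat resonance (~0.6 ppm from water) survives and biases the
tensor because fat barely diffuses.  Each diffusion-weighted image is
therefore acquired at several readout shifts; across shifts the olefinic
signal accrues a known chemical-shift phase while water does not,

    S(t_s) = (W + F e^{i 2 pi df_ol t_s}) e^{i (phi0 + 2 pi psi t_s)},

so a per-voxel complex least-squares fit over the shift dimension separates
the water magnitude W from the olefinic fat F (Dixon-based olefinic fat
suppression, DOFS).  The tensor is then fit to the water signal by
nonlinear least squares on S = S0 exp(-B:D) with per-volume 3x3 b-matrices
(imaging-gradient cross terms enter through the b-matrix).

Noise is estimated by local-patch principal component analysis with a
Marchenko-Pastur cut, giving SNR = mean(b=0 signal)/sigma.  Exclusions use
strict inequalities: voxel SNR < 15 or olefinic FF > 10 %; muscle-level
rules (overall FF > 50 %, fewer than 50 voxels) dominate voxel rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import AcquisitionSeries, EXCLUSION_CODES, QuantitativeMap

__all__ = [
    "TensorFit",
    "DofsResult",
    "estimate_noise_and_snr",
    "dofs_decompose",
    "compute_diffusion_time",
    "bmatrix_from_bvec",
    "bmatrix_from_waveform",
    "fit_tensor",
    "fit_tensor_map",
    "apply_dti_exclusions",
    "process_dti_series",
    "SNR_THRESHOLD",
    "OLEFINIC_FF_THRESHOLD",
    "MUSCLE_FF_THRESHOLD",
    "MIN_VOXELS",
    "DIFFUSION_TIME_OFFSET_MS",
]

SNR_THRESHOLD = 15.0
OLEFINIC_FF_THRESHOLD = 10.0   # %
MUSCLE_FF_THRESHOLD = 50.0     # %
MIN_VOXELS = 50
DIFFUSION_TIME_OFFSET_MS = 16.3
SNR_CAP = 1e6
GAMMA_RAD_PER_S_PER_T = 2.0 * np.pi * 42.577478518e6


# --------------------------------------------------------------------------
# noise and SNR


def estimate_noise_and_snr(
    volumes: np.ndarray, patch: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Patch-wise PCA noise level and SNR map from b = 0 volumes.

    ``volumes``: (nx, ny, nz, nvol) magnitude (or complex; magnitude is
    taken).  Within each in-plane patch the voxels-by-volumes matrix is
    eigen-decomposed and the noise variance read off the Marchenko-Pastur
    bulk of the spectrum.  With a single volume the estimator falls back to
    the standard deviation of the local-mean-removed patch.  Returns
    (sigma map, SNR map); SNR is capped where sigma vanishes.
    """
    data = np.abs(np.asarray(volumes, dtype=float))
    if data.ndim == 3:
        data = data[..., None]
    nx, ny, nz, nvol = data.shape
    if patch > nx or patch > ny:
        raise ValueError("patch size exceeds image extent")
    sigma = np.zeros((nx, ny, nz))
    for z in range(nz):
        for x0 in range(0, nx, patch):
            for y0 in range(0, ny, patch):
                block = data[x0:x0 + patch, y0:y0 + patch, z, :]
                X = block.reshape(-1, nvol)
                if nvol == 1:
                    s = float(np.std(X - X.mean()))
                else:
                    s = _mp_sigma(X)
                sigma[x0:x0 + patch, y0:y0 + patch, z] = s
    mean_sig = data.mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sigma > 0, mean_sig / sigma, SNR_CAP)
    return sigma, np.minimum(snr, SNR_CAP)


def _mp_sigma(X: np.ndarray) -> float:
    """Marchenko-Pastur noise sigma of an (M voxels, N volumes) matrix."""
    M, N = X.shape
    lam = np.linalg.eigvalsh(X.T @ X / M)[::-1]  # descending
    lam = np.clip(lam, 0.0, None)
    for p in range(N):
        tail = lam[p:]
        sig2 = tail.mean()
        gamma = (N - p) / M
        if tail[0] - tail[-1] < 4.0 * sig2 * np.sqrt(gamma):
            return float(np.sqrt(sig2))
    return float(np.sqrt(max(lam[-1], 0.0)))


# --------------------------------------------------------------------------
# DOFS decomposition


@dataclass
class DofsResult:
    """Per-voxel output of the olefinic fat-water decomposition."""

    water: np.ndarray          # magnitude, a.u.
    olefinic: np.ndarray       # magnitude, a.u.
    olefinic_ff: QuantitativeMap  # %
    psi_hz: np.ndarray


def _dofs_residual(S: np.ndarray, t_s: np.ndarray, omega: float, psi: np.ndarray):
    """Inner complex solve of the DOFS model at per-voxel psi.

    ``S``: (nshift, N); ``psi``: (N,).  Returns (residual, coeffs (N, 2)).
    """
    demod = S * np.exp(-2j * np.pi * psi[None, :] * t_s[:, None])
    ones = np.ones_like(t_s, dtype=complex)
    fat = np.exp(1j * omega * t_s)
    A = np.stack([ones, fat], axis=1)  # (nshift, 2), shared
    pinv = np.linalg.pinv(A)
    coef = (pinv @ demod).T            # (N, 2)
    resid = A @ coef.T - demod
    return np.sum(np.abs(resid) ** 2, axis=0), coef


def dofs_decompose(
    shifted_images: np.ndarray,
    shifts_ms: Sequence[float],
    olefinic_shift_hz: float,
    psi_window_hz: float = 60.0,
    n_psi: int = 41,
    refine_iters: int = 10,
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0),
) -> DofsResult:
    """Separate water and olefinic fat across readout shifts.

    ``shifted_images``: complex array (..., nshift).  The field rate psi is
    grid-searched in a window and refined per voxel; among residual local
    minima the water-dominant solution is preferred (the olefinic fraction
    is small by construction after spectral fat suppression), which
    resolves the swap ambiguity psi -> psi + df_ol.
    """
    t_s = np.asarray(shifts_ms, dtype=float) * 1e-3
    if len(t_s) < 3:
        raise ValueError("at least 3 readout shifts are required")
    data = np.asarray(shifted_images)
    if data.shape[-1] != len(t_s):
        raise ValueError("last axis must index the readout shifts")
    shape = data.shape[:-1]
    flat = data.reshape(-1, len(t_s)).T  # (nshift, N)
    present = np.max(np.abs(flat), axis=0) > 1e-12
    idx = np.nonzero(present)[0]
    S = flat[:, idx].astype(complex)
    n = S.shape[1]
    omega = 2.0 * np.pi * olefinic_shift_hz

    water = np.zeros(int(np.prod(shape)))
    fatm = np.zeros_like(water)
    psi_map = np.zeros_like(water)
    if n:
        psi_grid = np.linspace(-psi_window_hz, psi_window_hz, n_psi)
        res_all = np.empty((n_psi, n))
        w_all = np.empty((n_psi, n))
        for j, psi in enumerate(psi_grid):
            res, coef = _dofs_residual(S, t_s, omega, np.full(n, psi))
            res_all[j] = res
            w_all[j] = np.abs(coef[:, 0])
        # local minima of the residual profile; prefer water-dominant branch
        interior = np.zeros_like(res_all, dtype=bool)
        interior[1:-1] = (res_all[1:-1] <= res_all[:-2]) & (res_all[1:-1] <= res_all[2:])
        interior[0] = res_all[0] <= res_all[1]
        interior[-1] = res_all[-1] <= res_all[-2]
        score = np.where(interior, w_all, -np.inf)
        jpick = np.argmax(score, axis=0)
        psi_cur = psi_grid[jpick]
        step = np.full(n, psi_grid[1] - psi_grid[0])
        for _ in range(refine_iters):
            trials = [psi_cur - step, psi_cur, psi_cur + step]
            res3 = [_dofs_residual(S, t_s, omega, t)[0] for t in trials]
            k = np.argmin(np.stack(res3), axis=0)
            psi_cur = np.stack(trials)[k, np.arange(n)]
            step = np.where(k == 1, step * 0.5, step)
        _, coef = _dofs_residual(S, t_s, omega, psi_cur)
        water[idx] = np.abs(coef[:, 0])
        fatm[idx] = np.abs(coef[:, 1])
        psi_map[idx] = psi_cur

    water = water.reshape(shape)
    fatm = fatm.reshape(shape)
    denom = water + fatm
    valid = denom > 0
    off = np.full(shape, np.nan)
    np.divide(fatm * 100.0, denom, out=off, where=valid)
    ff_map = QuantitativeMap("olefinic_FF", "%", off, valid, spacing=spacing)
    ff_map.reason[~valid] = EXCLUSION_CODES["no_signal"]
    return DofsResult(water=water, olefinic=fatm, olefinic_ff=ff_map,
                      psi_hz=psi_map.reshape(shape))


# --------------------------------------------------------------------------
# timings and b-matrices


def compute_diffusion_time(mixing_time_ms: float) -> float:
    """Diffusion time of the stimulated-echo scan: TM + 16.3 ms."""
    if mixing_time_ms < 0:
        raise ValueError("mixing time must be nonnegative")
    return float(mixing_time_ms) + DIFFUSION_TIME_OFFSET_MS


def bmatrix_from_bvec(bvalue: float, bvec: Sequence[float]) -> np.ndarray:
    """b-matrix of a single diffusion gradient: b * g g^T (s/mm^2)."""
    g = np.asarray(bvec, dtype=float)
    nrm = np.linalg.norm(g)
    if nrm == 0:
        return np.zeros((3, 3))
    g = g / nrm
    return bvalue * np.outer(g, g)


def bmatrix_from_waveform(times_s: np.ndarray, gradients_t_per_m: np.ndarray) -> np.ndarray:
    """Full b-matrix of an arbitrary sampled gradient waveform (s/mm^2).

    Integrates q(t) = gamma * int g dt and B = int q q^T dt numerically,
    which captures the cross terms between diffusion and imaging gradients
    exactly for the sampled waveform.  ``gradients_t_per_m``: (nt, 3).
    """
    t = np.asarray(times_s, dtype=float)
    g = np.asarray(gradients_t_per_m, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3 or g.shape[0] != t.shape[0]:
        raise ValueError("gradients must be (nt, 3) matching the time axis")
    q = GAMMA_RAD_PER_S_PER_T * np.concatenate(
        [np.zeros((1, 3)), np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(t)[:, None], axis=0)]
    )
    outer = q[:, :, None] * q[:, None, :]
    B = np.trapezoid(outer, t, axis=0)  # rad^2 s / m^2 ... SI: s/m^2
    return B * 1e-6  # s/m^2 -> s/mm^2


# --------------------------------------------------------------------------
# tensor fitting


@dataclass
class TensorFit:
    """Diffusion tensor of one voxel (um^2/ms)."""

    tensor: np.ndarray
    eigenvalues: np.ndarray  # descending
    md: float
    fa: float
    s0: float
    residual: float
    clamped: bool = False    # negative eigenvalue clamped to zero


def _design_matrix(bmats: np.ndarray) -> np.ndarray:
    """(nvol, 7) design for [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    B = np.asarray(bmats, dtype=float)
    return np.column_stack(
        [
            np.ones(len(B)),
            -B[:, 0, 0], -B[:, 1, 1], -B[:, 2, 2],
            -2 * B[:, 0, 1], -2 * B[:, 0, 2], -2 * B[:, 1, 2],
        ]
    )


def _params_to_tensor(p: np.ndarray) -> np.ndarray:
    """(..., 7) parameters -> (..., 3, 3) symmetric tensors."""
    D = np.empty(p.shape[:-1] + (3, 3))
    D[..., 0, 0] = p[..., 1]
    D[..., 1, 1] = p[..., 2]
    D[..., 2, 2] = p[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = p[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = p[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = p[..., 6]
    return D


def _fit_tensor_arrays(signals: np.ndarray, bmats: np.ndarray,
                       n_gn: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Tensor fit for (nvol, N) signals: WLLS init + Gauss-Newton refinement
    of S = S0 exp(-B:D).  Returns (params (N, 7), residual (N,))."""
    X = _design_matrix(bmats)  # (nvol, 7)
    S = np.asarray(signals, dtype=float)
    eps = np.max(S, axis=0, keepdims=True) * 1e-12 + 1e-300
    logS = np.log(np.maximum(S, eps))
    # weighted linear init (weights ~ signal, the standard WLLS choice)
    W = S
    p = np.empty((S.shape[1], 7))
    XtW = X.T[None, :, :] * (W.T[:, None, :] ** 2)     # (N, 7, nvol)
    G = XtW @ X                                        # (N, 7, 7)
    b = XtW @ logS.T[:, :, None]                       # (N, 7, 1)
    p = np.linalg.solve(G, b)[..., 0]                  # (N, 7)
    # Gauss-Newton on the exponential model
    for _ in range(n_gn):
        pred = np.exp(p @ X.T)                         # (N, nvol)
        r = S.T - pred
        J = pred[:, :, None] * X[None, :, :]           # (N, nvol, 7)
        Jt = np.swapaxes(J, 1, 2)
        H = Jt @ J + 1e-12 * np.eye(7)
        step = np.linalg.solve(H, Jt @ r[:, :, None])[..., 0]
        p = p + step
    pred = np.exp(p @ X.T)
    resid = np.sum((S.T - pred) ** 2, axis=1)
    return p, resid


def _metrics(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues (descending), MD, FA and clamp flags for (..., 3, 3)."""
    lam = np.linalg.eigvalsh(D)[..., ::-1]
    clamped = lam[..., -1] < 0
    lam_c = np.clip(lam, 0.0, None)
    md = lam_c.mean(axis=-1)
    num = np.sqrt(np.sum((lam_c - md[..., None]) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam_c**2, axis=-1))
    fa = np.zeros_like(md)
    np.divide(np.sqrt(1.5) * num, den, out=fa, where=den > 0)
    return lam_c, md, fa, clamped


def fit_tensor(signals: np.ndarray, bmatrices: np.ndarray) -> TensorFit:
    """Nonlinear least-squares tensor fit of one voxel.

    ``signals``: (nvol,) magnitudes; ``bmatrices``: (nvol, 3, 3) in s/mm^2
    (the b-matrices are applied exactly, so upstream cross-term corrections
    propagate).  Output tensor in um^2/ms.
    """
    signals = np.asarray(signals, dtype=float)
    bmats = np.asarray(bmatrices, dtype=float)
    if signals.ndim != 1 or bmats.shape != (len(signals), 3, 3):
        raise ValueError("need (nvol,) signals and (nvol, 3, 3) b-matrices")
    X = _design_matrix(bmats)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient diffusion design: need >=6 "
                         "independent b-matrices plus b=0")
    p, resid = _fit_tensor_arrays(signals[:, None], bmats)
    D = _params_to_tensor(p[0]) * 1e3  # mm^2/s -> um^2/ms
    lam, md, fa, clamped = _metrics(D)
    return TensorFit(
        tensor=D, eigenvalues=lam, md=float(md), fa=float(fa),
        s0=float(np.exp(p[0, 0])), residual=float(resid[0]),
        clamped=bool(clamped),
    )


def fit_tensor_map(
    volumes: np.ndarray, bmatrices: np.ndarray,
    mask: Optional[np.ndarray] = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0),
) -> dict[str, QuantitativeMap]:
    """Voxel-wise tensor fit of a (nx, ny, nz, nvol) magnitude stack.

    Returns maps for MD, FA, lambda1-3 (um^2/ms) sharing one validity mask.
    """
    data = np.abs(np.asarray(volumes, dtype=float))
    shape = data.shape[:3]
    flat = data.reshape(-1, data.shape[-1]).T
    ok = np.min(flat, axis=0) > 0
    if mask is not None:
        ok &= np.asarray(mask, bool).ravel()
    nvox = flat.shape[1]
    md = np.full(nvox, np.nan)
    fa = np.full(nvox, np.nan)
    lams = np.full((nvox, 3), np.nan)
    if np.any(ok):
        p, _ = _fit_tensor_arrays(flat[:, ok], np.asarray(bmatrices, float))
        D = _params_to_tensor(p) * 1e3
        lam, mdv, fav, _ = _metrics(D)
        md[ok], fa[ok], lams[ok] = mdv, fav, lam
    okv = ok.reshape(shape)
    out = {}
    for name, units, vals in (
        ("MD", "um^2/ms", md), ("FA", "", fa),
        ("lambda1", "um^2/ms", lams[:, 0]),
        ("lambda2", "um^2/ms", lams[:, 1]),
        ("lambda3", "um^2/ms", lams[:, 2]),
    ):
        m = QuantitativeMap(name, units, vals.reshape(shape), okv.copy(), spacing=spacing)
        m.reason[~okv] = EXCLUSION_CODES["no_signal"]
        out[name] = m
    return out


# --------------------------------------------------------------------------
# exclusions and pipeline


def apply_dti_exclusions(snr, olefinic_ff, muscle_ff, n_voxels) -> np.ndarray:
    """Exclusion codes from the four gate quantities (strict inequalities).

    Muscle-level rules (overall muscle FF > 50 %, fewer than 50 voxels)
    dominate the voxel-level rules (SNR < 15, olefinic FF > 10 %); boundary
    values are retained.  Broadcasts; returns ``EXCLUSION_CODES`` values.
    """
    snr, olef, mff, nvox = np.broadcast_arrays(
        np.asarray(snr, float), np.asarray(olefinic_ff, float),
        np.asarray(muscle_ff, float), np.asarray(n_voxels, float),
    )
    code = np.zeros(snr.shape, dtype=np.int8)
    code[snr < SNR_THRESHOLD] = EXCLUSION_CODES["snr_low"]
    code[olef > OLEFINIC_FF_THRESHOLD] = EXCLUSION_CODES["olefinic_high"]
    code[nvox < MIN_VOXELS] = EXCLUSION_CODES["too_few_voxels"]
    code[mff > MUSCLE_FF_THRESHOLD] = EXCLUSION_CODES["muscle_ff_high"]
    return code


def process_dti_series(
    series: AcquisitionSeries,
    apply_dofs: bool = True,
    mask: Optional[np.ndarray] = None,
) -> dict:
    """Full diffusion pipeline on one mixing-time acquisition.

    Groups the volumes of a shift-major complex series by diffusion
    encoding, runs the olefinic decomposition across readout shifts for
    each encoding (or plain magnitude averaging when ``apply_dofs`` is
    off), estimates noise/SNR from the b = 0 data, and fits the tensor.
    Returns the tensor maps plus SNR, sigma, olefinic-FF maps and the
    diffusion time.
    """
    shifts = sorted({m.readout_shift_ms for m in series.meta})
    encodings: dict[tuple, list[int]] = {}
    for i, m in enumerate(series.meta):
        key = (m.bvalue, m.bvec)
        encodings.setdefault(key, []).append(i)
    olef_hz = series.constants.get("olefinic_shift_hz", 0.6 * 123.2)

    water_vols, bmats = [], []
    olef_ff_b0 = None
    for (bval, bvec), vol_idx in encodings.items():
        stack = np.stack([series.data[..., i] for i in sorted(
            vol_idx, key=lambda i: series.meta[i].readout_shift_ms)], axis=-1)
        if apply_dofs:
            res = dofs_decompose(stack, shifts, olef_hz, spacing=series.spacing)
            water_vols.append(res.water)
            if bval == 0:
                olef_ff_b0 = res.olefinic_ff
        else:
            water_vols.append(np.mean(np.abs(stack), axis=-1))
        meta = series.meta[vol_idx[0]]
        bmats.append(
            np.array(meta.bmatrix, float).reshape(3, 3)
            if meta.bmatrix is not None
            else bmatrix_from_bvec(bval, bvec)
        )
    volumes = np.stack(water_vols, axis=-1)
    b0_idx = [k for k, (bval, _) in enumerate(encodings) if bval == 0]
    b0_cols = [i for (bval, _), ids in encodings.items() if bval == 0 for i in ids]
    sigma, snr = estimate_noise_and_snr(np.abs(series.data[..., b0_cols]))
    tensors = fit_tensor_map(volumes, np.stack(bmats), mask=mask, spacing=series.spacing)
    tm = series.constants.get("mixing_time_ms", series.meta[0].mixing_time_ms)
    return {
        "tensors": tensors,
        "snr": snr,
        "sigma": sigma,
        "olefinic_ff": olef_ff_b0,
        "water_volumes": volumes,
        "diffusion_time_ms": compute_diffusion_time(tm) if tm is not None else None,
    }
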