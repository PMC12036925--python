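"""Water T2 from 17-echo multi-echo spin-echo decays.

The magnitude decay is modelled as a tri-exponential sum: one water
component with free amplitude and T2, plus a fat contribution with two
components of fixed T2 and fixed relative weights,

    s(TE) = A_w e^{-TE/T2w} + A_f (p1 e^{-TE/T2f1} + p2 e^{-TE/T2f2}).

Only (A_w, T2w, A_f) are free: seventeen magnitude points cannot stably
support free fat T2s, and the fixed constants are shared with the phantom
generator.  The nonlinear T2w is found by variable projection over a
coarse logarithmic grid followed by per-voxel parabolic refinement; the
amplitudes come from the inner linear solve with a nonnegativity fallback.

Voxel exclusion follows the study rules with strict inequalities: water
T2 below 15 ms or above 70 ms, and transmit field (B1+) below 80 % or
above 120 % of the prescribed flip angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .phantom import FAT_T2_COMPONENTS
from .types import AcquisitionSeries, QuantitativeMap

__all__ = [
    "T2FitResult",
    "fit_triexponential",
    "fit_t2_map",
    "apply_t2_exclusions",
    "apply_t2_map_exclusions",
    "T2_BOUNDS_MS",
    "B1_BOUNDS_PERCENT",
]

T2_BOUNDS_MS = (15.0, 70.0)       # retained range, strict inequalities
B1_BOUNDS_PERCENT = (80.0, 120.0)


@dataclass(frozen=True)
class T2FitResult:
    """Tri-exponential fit of one voxel."""

    t2w_ms: float
    water_amp: float
    fat_amp: float
    residual: float
    exclusion: str = "none"   # none / t2_low / t2_high / b1_low / b1_high
    valid: bool = True


def _fat_basis(te_ms: np.ndarray) -> np.ndarray:
    return sum(p * np.exp(-te_ms / t2f) for p, t2f in FAT_T2_COMPONENTS)


def _inner_solve(signals: np.ndarray, water_col: np.ndarray, fat_col: np.ndarray):
    """Nonnegative 2-column linear solve, vectorized over voxels.

    ``signals``: (E, N); columns: (E,) or (N, E).  Returns amplitudes
    (2, N) and residual sum of squares (N,).
    """
    if water_col.ndim == 1:
        B = np.stack([water_col, fat_col], axis=1)  # (E, 2)
        coef, *_ = np.linalg.lstsq(B, signals, rcond=None)
        resid = signals - B @ coef
    else:
        B = np.stack([water_col, fat_col], axis=2)           # (N, E, 2)
        Bt = np.swapaxes(B, 1, 2)                             # (N, 2, E)
        G = Bt @ B
        y = signals.T[:, :, None]
        coef = np.linalg.solve(G, Bt @ y)[..., 0].T           # (2, N)
        resid = signals - np.einsum("nek,kn->en", B, coef)
    # nonnegativity fallback: clamp a negative amplitude and refit the other
    for j, other in ((0, 1), (1, 0)):
        neg = coef[j] < 0
        if np.any(neg):
            col = (fat_col, water_col)[j]
            col_v = col if col.ndim == 1 else col[neg].T
            s = signals[:, neg]
            if col.ndim == 1:
                amp = np.maximum((col @ s) / (col @ col), 0.0)
                r = s - col[:, None] * amp
            else:
                amp = np.maximum(np.sum(col_v * s, axis=0) /
                                 np.sum(col_v * col_v, axis=0), 0.0)
                r = s - col_v * amp
            coef[j, neg] = 0.0
            coef[other, neg] = amp
            resid[:, neg] = r
    return coef, np.sum(resid**2, axis=0)


def _fit_many(signals: np.ndarray, te_ms: np.ndarray,
              coarse: int = 60, refine_iters: int = 25) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """VARPRO fit of (A_w, T2w, A_f) for (E, N) signals; returns
    (t2w, water_amp, fat_amp, residual)."""
    n = signals.shape[1]
    fat_col = _fat_basis(te_ms)
    grid = np.geomspace(3.0, 200.0, coarse)
    best_res = np.full(n, np.inf)
    best_t2 = np.full(n, grid[0])
    for t2 in grid:
        _, res = _inner_solve(signals, np.exp(-te_ms / t2), fat_col)
        better = res < best_res
        best_res[better] = res[better]
        best_t2[better] = t2

    # golden-style parabolic refinement in log T2 space, per voxel
    logt2 = np.log(best_t2)
    step = np.full(n, np.log(grid[1] / grid[0]))
    for _ in range(refine_iters):
        trials = [logt2 - step, logt2, logt2 + step]
        res3 = []
        for t in trials:
            wcol = np.exp(-te_ms[None, :] / np.exp(t)[:, None])  # (N, E)
            fcol = np.broadcast_to(fat_col, wcol.shape)
            _, res = _inner_solve(signals, wcol, fcol)
            res3.append(res)
        R = np.stack(res3)
        k = np.argmin(R, axis=0)
        logt2 = np.stack(trials)[k, np.arange(n)]
        step = np.where(k == 1, step * 0.5, step)
    t2w = np.exp(logt2)
    wcol = np.exp(-te_ms[None, :] / t2w[:, None])
    coef, res = _inner_solve(signals, wcol, np.broadcast_to(fat_col, wcol.shape))
    return t2w, coef[0], coef[1], res


def fit_triexponential(decay: np.ndarray, te_ms: np.ndarray) -> T2FitResult:
    """Fit one voxel's magnitude decay; see module docstring for the model."""
    decay = np.asarray(decay, dtype=float)
    te_ms = np.asarray(te_ms, dtype=float)
    if decay.ndim != 1 or decay.shape != te_ms.shape:
        raise ValueError("decay and te must be matching 1-D arrays")
    if len(te_ms) < 8:
        raise ValueError("at least 8 echoes are required")
    if not np.all(np.diff(te_ms) > 0):
        raise ValueError("echo times must be strictly increasing")
    if np.all(decay == 0):
        return T2FitResult(np.nan, 0.0, 0.0, 0.0, valid=False)
    t2w, aw, af, res = _fit_many(decay[:, None], te_ms)
    return T2FitResult(float(t2w[0]), float(aw[0]), float(af[0]), float(res[0]))


def fit_t2_map(
    series: AcquisitionSeries,
    mask: Optional[np.ndarray] = None,
    rician_correction: bool = True,
) -> tuple[QuantitativeMap, np.ndarray, np.ndarray]:
    """Voxel-wise tri-exponential fit of an MSE series.

    With ``rician_correction`` the noise floor of the magnitude data is
    removed by the second-moment identity E[|s|^2] = s^2 + 2 sigma^2, with
    sigma estimated from outside-mask background voxels (no-op when no
    mask is given or the background is silent).  Without it, the floor of
    the late echoes is absorbed by the long-T2 fat component and biases
    water T2 low.  Returns (water-T2 map [ms], water amp, fat amp).
    """
    te_ms = series.echo_times()
    data = np.abs(np.asarray(series.data, dtype=float))
    shape = data.shape[:3]
    if rician_correction and mask is not None:
        bg = data[~np.asarray(mask, bool)]
        if bg.size and np.median(bg) > 0:
            sigma = float(np.median(bg)) / np.sqrt(np.pi / 2.0)
            data = np.sqrt(np.clip(data**2 - 2.0 * sigma**2, 0.0, None))
    flat = data.reshape(-1, data.shape[-1]).T  # (E, N)
    ok = np.max(flat, axis=0) > 0
    if mask is not None:
        ok &= np.asarray(mask, bool).ravel()
    t2w = np.full(flat.shape[1], np.nan)
    aw = np.zeros(flat.shape[1])
    af = np.zeros(flat.shape[1])
    if np.any(ok):
        t2w[ok], aw[ok], af[ok], _ = _fit_many(flat[:, ok], te_ms)
    qmap = QuantitativeMap(
        name="water_T2", units="ms",
        values=t2w.reshape(shape), valid=ok.reshape(shape),
        spacing=series.spacing,
    )
    qmap.reason[~ok.reshape(shape)] = 10  # no_signal
    return qmap, aw.reshape(shape), af.reshape(shape)


def _b1_percent(b1) -> np.ndarray:
    """Accept B1+ either as fraction of nominal or as percent."""
    b1 = np.asarray(b1, dtype=float)
    return b1 * 100.0 if np.nanmax(b1) <= 3.0 else b1


def apply_t2_exclusions(result: T2FitResult, b1) -> T2FitResult:
    """Flag one voxel per the strict T2/B1 retention windows.

    Boundary values (T2 exactly 15 or 70 ms, B1 exactly 80 or 120 %) are
    retained, matching the strict inequalities of the exclusion rules.
    """
    if not result.valid:
        return result
    b1p = float(_b1_percent(b1))
    code = "none"
    if result.t2w_ms < T2_BOUNDS_MS[0]:
        code = "t2_low"
    elif result.t2w_ms > T2_BOUNDS_MS[1]:
        code = "t2_high"
    elif b1p < B1_BOUNDS_PERCENT[0]:
        code = "b1_low"
    elif b1p > B1_BOUNDS_PERCENT[1]:
        code = "b1_high"
    return replace(result, exclusion=code, valid=code == "none")


def apply_t2_map_exclusions(t2_map: QuantitativeMap, b1_map) -> QuantitativeMap:
    """Apply the strict T2/B1 windows to a whole map (in place; returned)."""
    b1p = _b1_percent(b1_map)
    v = t2_map.values
    t2_map.exclude(v < T2_BOUNDS_MS[0], "t2_low")
    t2_map.exclude(v > T2_BOUNDS_MS[1], "t2_high")
    t2_map.exclude(b1p < B1_BOUNDS_PERCENT[0], "b1_low")
    t2_map.exclude(b1p > B1_BOUNDS_PERCENT[1], "b1_high")
    return t2_map
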