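"""Three-point Dixon fat-water separation and derived area measures.

The three complex gradient-echo images are fit per voxel to

    S(TE) = (W + F e^{i 2 pi df_fat TE}) e^{i 2 pi psi TE} e^{-TE/T2*}

with a single-peak fat spectrum and a single T2* decay: complex amplitudes
(W, F) enter linearly, the field map psi and R2* = 1/T2* nonlinearly.  The
nonlinear pair is found by variable projection: for candidate (psi, R2*)
the best (W, F) is a linear least-squares solve, and the residual landscape
is searched on a grid.  Because a three-echo fit is bimodal in psi (the
fat-water-swapped solution is a second, equally deep minimum at shifted
psi), the voxel-wise choice between residual minima is made by region
growing from the most reliable voxel under a smooth-field-map assumption,
followed by per-voxel coordinate refinement.

Fat-fraction maps, cross-sectional area (CSA) and contractile CSA follow:
FF = fat/(water+fat)*100 and cCSA = (1 - 0.01*FF)*CSA.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import AcquisitionSeries, MuscleLabelMap, QuantitativeMap

__all__ = [
    "FatWaterResult",
    "separate_fat_water",
    "compute_ff",
    "compute_ccsa",
    "compute_csa",
]

T2STAR_BOUNDS_MS = (5.0, 100.0)


@dataclass
class FatWaterResult:
    """Per-voxel output of the three-point Dixon fit."""

    water: np.ndarray      # magnitude, a.u.
    fat: np.ndarray        # magnitude, a.u.
    ff: QuantitativeMap    # %
    psi_hz: np.ndarray
    t2star_ms: np.ndarray
    converged: np.ndarray  # bool


def _residual_grid(signals: np.ndarray, te_s: np.ndarray, c: np.ndarray,
                   psi: float, r2s: float) -> tuple[np.ndarray, np.ndarray]:
    """Residual of the VARPRO inner solve at one (psi, R2*) for all voxels.

    ``signals``: (3, N) complex.  Returns (residual (N,), coeffs (2, N)).
    """
    phase = np.exp((2j * np.pi * psi - r2s) * te_s)
    A = np.stack([phase, c * phase], axis=1)  # (3, 2)
    pinv = np.linalg.pinv(A)
    coef = pinv @ signals
    resid = A @ coef - signals
    return np.sum(np.abs(resid) ** 2, axis=0), coef


def _residual_pervoxel(signals: np.ndarray, te_s: np.ndarray, c: np.ndarray,
                       psi: np.ndarray, r2s: np.ndarray):
    """Same inner solve with per-voxel (psi, R2*); fully vectorized.

    ``signals``: (3, N); ``psi``, ``r2s``: (N,).  Returns (residual (N,),
    coeffs (N, 2)).
    """
    phase = np.exp((2j * np.pi * psi[None, :] - r2s[None, :]) * te_s[:, None])  # (3, N)
    A = np.stack([phase, c[:, None] * phase], axis=2)        # (3, N, 2)
    A = np.moveaxis(A, 1, 0)                                  # (N, 3, 2)
    Ah = np.conj(np.swapaxes(A, 1, 2))                        # (N, 2, 3)
    G = Ah @ A                                                # (N, 2, 2)
    y = signals.T[:, :, None]                                 # (N, 3, 1)
    b = Ah @ y                                                # (N, 2, 1)
    coef = np.linalg.solve(G, b)                              # (N, 2, 1)
    resid = A @ coef - y
    return np.sum(np.abs(resid[..., 0]) ** 2, axis=1), coef[..., 0]


def _local_minima(profile: np.ndarray) -> np.ndarray:
    """Boolean mask of strict-or-plateau local minima along axis 0."""
    lower_left = np.empty_like(profile, dtype=bool)
    lower_right = np.empty_like(profile, dtype=bool)
    lower_left[0] = True
    lower_left[1:] = profile[1:] <= profile[:-1]
    lower_right[-1] = True
    lower_right[:-1] = profile[:-1] <= profile[1:]
    return lower_left & lower_right


def separate_fat_water(
    series: AcquisitionSeries,
    fat_shift_hz: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
    n_psi: int = 65,
    n_r2s: int = 10,
    refine_iters: int = 12,
) -> FatWaterResult:
    """Fit (W, F, psi, T2*) per voxel from a three-echo complex series."""
    if series.n_volumes != 3:
        raise ValueError("three-point Dixon requires exactly 3 echoes")
    te_ms = series.echo_times()
    if not np.all(np.diff(te_ms) > 0):
        raise ValueError("echo times must be strictly increasing")
    if fat_shift_hz is None:
        fat_shift_hz = series.constants.get("fat_shift_hz")
    if fat_shift_hz is None:
        raise ValueError("fat_shift_hz must be given or present in series constants")

    te_s = te_ms * 1e-3
    data = np.asarray(series.data, dtype=complex)
    shape = data.shape[:3]
    flat = data.reshape(-1, 3).T  # (3, Nvox)
    signal_present = np.max(np.abs(flat), axis=0) > 1e-12
    if mask is not None:
        signal_present &= np.asarray(mask, bool).ravel()
    idx = np.nonzero(signal_present)[0]
    S = flat[:, idx]
    n = S.shape[1]

    water = np.zeros(shape).ravel()
    fatm = np.zeros(shape).ravel()
    psi_map = np.zeros(shape).ravel()
    t2s_map = np.full(shape, np.nan).ravel()
    converged = np.zeros(shape, bool).ravel()

    if n > 0:
        c = np.exp(2j * np.pi * fat_shift_hz * te_s)
        dte = np.diff(te_s).mean()
        psi_max = 1.0 / (2.0 * dte)
        psi_grid = np.linspace(-psi_max, psi_max, n_psi)
        r2s_grid = 1.0 / (np.geomspace(T2STAR_BOUNDS_MS[0], T2STAR_BOUNDS_MS[1], n_r2s) * 1e-3)

        # coarse VARPRO landscape, minimized over R2* at each psi
        prof = np.full((n_psi, n), np.inf)
        best_r2s = np.zeros((n_psi, n))
        for j, psi in enumerate(psi_grid):
            for r2s in r2s_grid:
                res, _ = _residual_grid(S, te_s, c, psi, r2s)
                better = res < prof[j]
                prof[j][better] = res[better]
                best_r2s[j][better] = r2s

        # region-grow the field map only across voxels with real signal;
        # pure-noise background would otherwise bridge separate muscles
        # and propagate garbage psi into them
        amp = np.max(np.abs(S), axis=0)
        reliable = amp >= 0.15 * np.percentile(amp, 99)
        psi_sel = _choose_field_map(prof, psi_grid, idx, shape, reliable)
        jsel = np.array([int(np.argmin(np.abs(psi_grid - p))) for p in psi_sel])
        r2s_sel = best_r2s[jsel, np.arange(n)]

        # coordinate refinement: parabolic steps in psi and R2*, shrinking
        dpsi = np.full(n, psi_grid[1] - psi_grid[0])
        dr2s = r2s_sel * 0.4
        psi_cur, r2s_cur = psi_sel.copy(), r2s_sel
        r2s_lo, r2s_hi = 1.0 / (T2STAR_BOUNDS_MS[1] * 1e-3), 1.0 / (T2STAR_BOUNDS_MS[0] * 1e-3)
        for _ in range(refine_iters):
            for which in ("psi", "r2s"):
                if which == "psi":
                    trials = [
                        np.clip(psi_cur - dpsi, -psi_max, psi_max),
                        psi_cur,
                        np.clip(psi_cur + dpsi, -psi_max, psi_max),
                    ]
                    res3 = [
                        _residual_pervoxel(S, te_s, c, t, r2s_cur)[0] for t in trials
                    ]
                else:
                    trials = [
                        np.clip(r2s_cur - dr2s, r2s_lo, r2s_hi),
                        r2s_cur,
                        np.clip(r2s_cur + dr2s, r2s_lo, r2s_hi),
                    ]
                    res3 = [
                        _residual_pervoxel(S, te_s, c, psi_cur, t)[0] for t in trials
                    ]
                R = np.stack(res3)          # (3, N)
                k = np.argmin(R, axis=0)
                pick = np.stack(trials)[k, np.arange(n)]
                if which == "psi":
                    psi_cur = pick
                    dpsi = np.where(k == 1, dpsi * 0.5, dpsi)
                else:
                    r2s_cur = pick
                    dr2s = np.where(k == 1, dr2s * 0.5, dr2s)
        res_final, coef = _residual_pervoxel(S, te_s, c, psi_cur, r2s_cur)
        W = np.abs(coef[:, 0])
        F = np.abs(coef[:, 1])

        water[idx] = W
        fatm[idx] = F
        psi_map[idx] = psi_cur
        t2s_map[idx] = 1e3 / r2s_cur
        scale = np.maximum(np.sum(np.abs(S) ** 2, axis=0), 1e-30)
        converged[idx] = res_final / scale < 1e-2

    water = water.reshape(shape)
    fatm = fatm.reshape(shape)
    ff = compute_ff(water, fatm, spacing=series.spacing)
    ff.valid &= signal_present.reshape(shape)
    return FatWaterResult(
        water=water, fat=fatm, ff=ff,
        psi_hz=psi_map.reshape(shape),
        t2star_ms=t2s_map.reshape(shape),
        converged=converged.reshape(shape),
    )


def _choose_field_map(prof: np.ndarray, psi_grid: np.ndarray,
                      idx: np.ndarray, shape: tuple[int, int, int],
                      reliable: Optional[np.ndarray] = None) -> np.ndarray:
    """Pick one psi per voxel among residual local minima by region growing.

    Seeds at the voxel whose best minimum is most clearly separated from
    its runner-up, then grows outward (6-connected), assigning each voxel
    the candidate minimum closest to the mean psi of its already-assigned
    neighbours.  This resolves the global fat-water swap ambiguity under a
    smooth-field-map assumption.  Growth is restricted to ``reliable``
    voxels (real signal); the rest get the small-|psi| prior directly.
    """
    n_psi, n = prof.shape
    if reliable is None:
        reliable = np.ones(n, dtype=bool)
    minima = _local_minima(prof)
    # candidate list per voxel: indices of local minima sorted by residual
    candidates: list[np.ndarray] = []
    seed_pick: list[int] = []
    margins = np.zeros(n)
    min_sep = max(1, n_psi // 12)  # one candidate per residual valley
    for v in range(n):
        cand = np.nonzero(minima[:, v])[0]
        order = np.argsort(prof[cand, v])
        cand = cand[order]
        kept: list[int] = []
        for j in cand:  # non-maximum suppression across the psi axis
            if all(abs(j - k) >= min_sep for k in kept):
                kept.append(int(j))
            if len(kept) == 4:
                break
        cand = np.array(kept)
        candidates.append(cand)
        if len(cand) > 1:
            margins[v] = prof[cand[1], v] - prof[cand[0], v]
        else:
            margins[v] = np.inf
        # seed prior: among near-degenerate minima (the fat-water swap is an
        # exact second solution) prefer the one with the smallest |psi| —
        # true off-resonance is far smaller than the fat chemical shift
        best = prof[cand[0], v]
        span = prof[:, v].max() - best
        near = cand[prof[cand, v] <= best + 0.25 * span]
        seed_pick.append(int(near[np.argmin(np.abs(psi_grid[near]))]))

    # voxel adjacency in the full grid restricted to fitted voxels
    pos = -np.ones(int(np.prod(shape)), dtype=np.int64)
    pos[idx] = np.arange(n)
    coords = np.stack(np.unravel_index(idx, shape), axis=1)
    nbrs: list[list[int]] = [[] for _ in range(n)]
    strides = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for v in range(n):
        if not reliable[v]:
            continue
        x, y, z = coords[v]
        for dx, dy, dz in strides:
            q = (x + dx, y + dy, z + dz)
            if all(0 <= qi < si for qi, si in zip(q, shape)):
                p = pos[np.ravel_multi_index(q, shape)]
                if p >= 0 and reliable[p]:
                    nbrs[v].append(int(p))

    psi_sel = np.full(n, np.nan)
    assigned = np.zeros(n, bool)
    finite_margin = np.where(np.isfinite(margins), margins, np.max(prof))
    # weak voxels are not grown through: they take the small-|psi| prior
    weak = np.nonzero(~reliable)[0]
    psi_sel[weak] = psi_grid[np.array(seed_pick, dtype=int)[weak]] if len(weak) else psi_sel[weak]
    assigned[weak] = True
    if not np.any(reliable):
        return psi_sel
    masked_margin = np.where(reliable, finite_margin, -np.inf)
    order_seed = int(np.argmax(masked_margin))
    # multiple connected components: loop until everything is assigned
    heap: list[tuple[float, int]] = []
    remaining = set(np.nonzero(reliable)[0].tolist())
    seed = order_seed
    while remaining:
        psi_sel[seed] = psi_grid[seed_pick[seed]]
        assigned[seed] = True
        remaining.discard(seed)
        for q in nbrs[seed]:
            if not assigned[q]:
                heapq.heappush(heap, (-finite_margin[q], q))
        while heap:
            _, v = heapq.heappop(heap)
            if assigned[v]:
                continue
            ref = [psi_sel[q] for q in nbrs[v] if assigned[q]]
            ref_psi = float(np.mean(ref)) if ref else psi_grid[seed_pick[v]]
            cand = candidates[v]
            pick = cand[int(np.argmin(np.abs(psi_grid[cand] - ref_psi)))]
            psi_sel[v] = psi_grid[pick]
            assigned[v] = True
            remaining.discard(v)
            for q in nbrs[v]:
                if not assigned[q]:
                    heapq.heappush(heap, (-finite_margin[q], q))
        if remaining:  # next component
            seed = max(remaining, key=lambda v: finite_margin[v])
    return psi_sel


def compute_ff(
    water: np.ndarray, fat: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0),
) -> QuantitativeMap:
    """Fat-fraction map, FF = fat/(water + fat) * 100 (percent).

    Voxels with zero total signal are masked (undefined), not set to zero.
    """
    water = np.asarray(water, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if np.any(water < 0) or np.any(fat < 0):
        raise ValueError("water and fat magnitudes must be nonnegative")
    denom = water + fat
    valid = denom > 0
    ff = np.full(water.shape, np.nan)
    np.divide(fat * 100.0, denom, out=ff, where=valid)
    qmap = QuantitativeMap(name="FF", units="%", values=ff, valid=valid, spacing=spacing)
    qmap.reason[~valid] = 10  # no_signal
    return qmap


def compute_ccsa(csa_mm2: float, ff_percent: float) -> float:
    """Contractile cross-sectional area, cCSA = (1 - 0.01*FF) * CSA."""
    if not 0.0 <= ff_percent <= 100.0:
        raise ValueError("FF must lie in [0, 100] %")
    if csa_mm2 < 0:
        raise ValueError("CSA must be nonnegative")
    return (1.0 - 0.01 * ff_percent) * csa_mm2


def compute_csa(
    labels: MuscleLabelMap,
    slice_indices: Optional[Sequence[int]] = None,
) -> dict[int, float]:
    """Per-muscle cross-sectional area in mm^2.

    CSA of a slice is the in-slice voxel count times the in-plane voxel
    area; per muscle the mean over the selected slices is returned.  A
    muscle absent from every selected slice gets CSA 0.
    """
    import warnings

    dx, dy, _ = labels.spacing
    area = dx * dy
    nz = labels.labels.shape[2]
    if slice_indices is None:
        slice_indices = range(nz)
    out: dict[int, float] = {}
    for label in labels.muscles:
        per_slice = [
            np.count_nonzero(labels.labels[:, :, z] == label) * area
            for z in slice_indices
        ]
        if not any(per_slice):
            warnings.warn(f"label {label} absent from selected slices", stacklevel=2)
        out[label] = float(np.mean(per_slice)) if per_slice else 0.0
    return out
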