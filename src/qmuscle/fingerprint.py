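"""Water T1 by dictionary matching of fingerprint time-courses.

A dictionary of simulated signal evolutions is built on a grid of
(water T1, fat fraction, B1+) from the same inversion-prepared
spoiled-gradient-echo forward model the phantom uses.  Acquisitions are
magnitude images, so each entry is stored as the magnitude of the signed
simulated course, unit normalized; a measured time-course is likewise
reduced to its magnitude and assigned the grid node maximizing the inner
product with the unit-normalized signal — making the estimate invariant
to overall signal scale and consistent with Rician data.  Ties are
broken deterministically toward the lowest T1, then lowest FF, then lowest
B1.  Voxels with FF above 60 % are excluded from further analysis
(strict inequality; FF of exactly 60 % is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import FAT_T1_MS, FingerprintSchedule, fingerprint_signal
from .types import AcquisitionSeries, QuantitativeMap

__all__ = [
    "FingerprintDictionary",
    "default_grid",
    "build_dictionary",
    "match_fingerprint",
    "match_series",
    "apply_t1_exclusion",
    "T1_FF_EXCLUSION_PERCENT",
]

T1_FF_EXCLUSION_PERCENT = 60.0


def default_grid() -> dict[str, np.ndarray]:
    """Desk-scale dictionary axes: T1w 600-2000 ms / 25 ms, FF 0-100 % /
    2.5 %, B1 0.7-1.3 / 0.05."""
    return {
        "t1_ms": np.arange(600.0, 2000.0 + 1e-9, 25.0),
        "ff_percent": np.arange(0.0, 100.0 + 1e-9, 2.5),
        "b1": np.arange(0.70, 1.30 + 1e-9, 0.05),
    }


@dataclass
class FingerprintDictionary:
    """Unit-normalized fingerprints on a (T1w, FF, B1) grid."""

    schedule: FingerprintSchedule
    t1_ms: np.ndarray
    ff_percent: np.ndarray
    b1: np.ndarray
    entries: np.ndarray = field(repr=False)  # (n_nodes, n_pulses), unit rows
    nodes: np.ndarray = field(repr=False)    # (n_nodes, 3): t1, ff, b1
    fat_t1_ms: float = FAT_T1_MS

    def node_index(self, t1: float, ff: float, b1: float) -> int:
        i = int(np.argmin(np.abs(self.t1_ms - t1)))
        j = int(np.argmin(np.abs(self.ff_percent - ff)))
        k = int(np.argmin(np.abs(self.b1 - b1)))
        return (i * len(self.ff_percent) + j) * len(self.b1) + k


def build_dictionary(
    schedule: FingerprintSchedule,
    grid: Optional[dict[str, np.ndarray]] = None,
    fat_t1_ms: float = FAT_T1_MS,
) -> FingerprintDictionary:
    """Simulate and normalize one fingerprint per grid node.

    Node order is C-order over (T1, FF, B1) with every axis ascending, so
    the first-maximum tie-break of the matcher resolves toward the lowest
    T1, then FF, then B1.
    """
    grid = grid or default_grid()
    t1 = np.asarray(grid["t1_ms"], dtype=float)
    ff = np.asarray(grid["ff_percent"], dtype=float)
    b1 = np.asarray(grid["b1"], dtype=float)
    for name, ax in (("t1_ms", t1), ("ff_percent", ff), ("b1", b1)):
        if ax.size == 0:
            raise ValueError(f"empty dictionary axis {name}")
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise ValueError(f"dictionary axis {name} must be strictly increasing")

    # water and fat courses depend on (T1|fat_T1, B1) only; FF mixes them
    water = fingerprint_signal(t1[:, None], schedule, b1[None, :])      # (nt1, nb1, P)
    fat = fingerprint_signal(np.full((1, 1), fat_t1_ms), schedule, b1[None, :])  # (1, nb1, P)
    frac = ff / 100.0
    # entries[i, j, k] = (1-f_j) water[i, k] + f_j fat[k]
    entries = (
        (1.0 - frac)[None, :, None, None] * water[:, None, :, :]
        + frac[None, :, None, None] * fat[None, None, 0][..., :, :]
    )  # (nt1, nff, nb1, P)
    # magnitude acquisition: the sign of the post-inversion course is lost
    flat = np.abs(entries.reshape(-1, entries.shape[-1]))
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    flat = flat / norms
    nodes = np.stack(
        np.meshgrid(t1, ff, b1, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return FingerprintDictionary(
        schedule=schedule, t1_ms=t1, ff_percent=ff, b1=b1,
        entries=flat, nodes=nodes, fat_t1_ms=fat_t1_ms,
    )


def match_fingerprint(signal: np.ndarray, dictionary: FingerprintDictionary):
    """Match one time-course; returns (T1w ms, FF %, B1) or None for zero signal."""
    signal = np.asarray(signal)
    if signal.ndim != 1 or signal.shape[0] != dictionary.entries.shape[1]:
        raise ValueError("signal length must equal the fingerprint length")
    signal = np.abs(signal)
    norm = np.linalg.norm(signal)
    if norm == 0:
        return None
    scores = (dictionary.entries @ signal) / norm
    best = int(np.argmax(scores))  # first max -> lowest T1/FF/B1 on ties
    t1, ff, b1 = dictionary.nodes[best]
    return float(t1), float(ff), float(b1)


def match_series(
    series: AcquisitionSeries,
    dictionary: FingerprintDictionary,
    mask: Optional[np.ndarray] = None,
    chunk: int = 4096,
) -> tuple[QuantitativeMap, QuantitativeMap, np.ndarray]:
    """Voxel-wise matching of a fingerprint series.

    Returns (water-T1 map [ms], FF map [%], B1 map [fraction of nominal]).
    """
    data = np.abs(np.asarray(series.data))
    shape = data.shape[:3]
    flat = data.reshape(-1, data.shape[-1])
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    if mask is not None:
        ok &= np.asarray(mask, bool).ravel()
    t1 = np.full(flat.shape[0], np.nan)
    ff = np.full(flat.shape[0], np.nan)
    b1 = np.full(flat.shape[0], np.nan)
    idx = np.nonzero(ok)[0]
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        block = flat[sel] / norms[sel, None]
        scores = block @ dictionary.entries.T
        best = np.argmax(scores, axis=1)
        t1[sel] = dictionary.nodes[best, 0]
        ff[sel] = dictionary.nodes[best, 1]
        b1[sel] = dictionary.nodes[best, 2]
    okv = ok.reshape(shape)
    t1_map = QuantitativeMap("water_T1", "ms", t1.reshape(shape), okv.copy(),
                             spacing=series.spacing)
    ff_map = QuantitativeMap("FF_mrf", "%", ff.reshape(shape), okv.copy(),
                             spacing=series.spacing)
    for m in (t1_map, ff_map):
        m.reason[~okv] = 10  # no_signal
    return t1_map, ff_map, b1.reshape(shape)


def apply_t1_exclusion(t1_map: QuantitativeMap, ff_map) -> QuantitativeMap:
    """Mask water-T1 voxels with FF above 60 % (strict; 60 % retained)."""
    ff = ff_map.values if isinstance(ff_map, QuantitativeMap) else np.asarray(ff_map, float)
    if ff.shape != t1_map.values.shape:
        raise ValueError("FF and T1 maps must be co-registered (same shape)")
    with np.errstate(invalid="ignore"):
        t1_map.exclude(ff > T1_FF_EXCLUSION_PERCENT, "ff_high")
    return t1_map
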