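"""Intramuscular pH from the carnosine C2H resonance.

The imidazole C2 proton of carnosine titrates in the physiological range:
its chemical shift moves between a protonated (acid) and a deprotonated
(base) limit as a Henderson-Hasselbalch function of pH.  Measuring the C2H
offset from the water resonance in a single-voxel spectrum therefore reads
out intracellular pH:

    pH = pKa + log10((delta_acid - delta) / (delta - delta_base)),

strictly decreasing in the observed shift ``delta``.  Calibration constants
(pKa and the limiting shifts) are configuration with literature-derived
defaults.  In muscles whose fat fraction exceeds 30 % the carnosine SNR is
inadequate and the assessment is omitted (strict inequality: exactly 30 %
is still assessed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .types import Spectrum

__all__ = [
    "PhCalibration",
    "DEFAULT_CALIBRATION",
    "PeakLocation",
    "locate_peaks",
    "estimate_ph",
    "shift_for_ph",
    "apply_mrs_omission",
    "ph_from_spectrum",
    "MRS_FF_OMISSION_PERCENT",
]

MRS_FF_OMISSION_PERCENT = 30.0
WATER_WINDOW_PPM = (4.2, 5.2)
C2H_WINDOW_PPM = (7.5, 8.7)
MIN_PEAK_SNR = 2.0


@dataclass(frozen=True)
class PhCalibration:
    """Titration constants of the carnosine C2H proton."""

    pka: float = 6.87
    delta_acid_ppm: float = 8.52   # fully protonated limit
    delta_base_ppm: float = 7.63   # fully deprotonated limit

    def __post_init__(self) -> None:
        if not self.delta_acid_ppm > self.delta_base_ppm:
            raise ValueError("delta_acid must exceed delta_base")
        if not 6.0 < self.pka < 8.0:
            raise ValueError("pKa outside the plausible (6, 8) range")


DEFAULT_CALIBRATION = PhCalibration()


class PeakLocation(NamedTuple):
    water_ppm: float
    c2h_ppm: Optional[float]
    c2h_snr: float


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-bin vertex of a parabola through (i-1, i, i+1); falls back to x[i]."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[i] + delta * (x[min(i + 1, len(x) - 1)] - x[i - 1]) / 2.0)


def locate_peaks(spec: Spectrum) -> PeakLocation:
    """Find the water and carnosine C2H resonances.

    Water is the magnitude maximum in 4.2-5.2 ppm; C2H the maximum in
    7.5-8.7 ppm refined by three-point parabolic interpolation.  The C2H
    SNR is peak height over the baseline noise SD (estimated from the
    signal-poor upper end of the axis); below 2x noise the peak is deemed
    absent and ``c2h_ppm`` is None — pH is then unavailable, not an error.
    """
    ppm = spec.ppm
    mag = spec.magnitude()
    lo, hi = min(ppm[0], ppm[-1]), max(ppm[0], ppm[-1])
    if lo > WATER_WINDOW_PPM[0] or hi < C2H_WINDOW_PPM[1]:
        raise ValueError("spectral axis must cover the water and C2H windows")

    def window(bounds):
        sel = (ppm >= bounds[0]) & (ppm <= bounds[1])
        return np.nonzero(sel)[0]

    widx = window(WATER_WINDOW_PPM)
    wmax = widx[np.argmax(mag[widx])]
    water_ppm = _parabolic_refine(ppm, mag, int(wmax))

    # baseline noise from the far-downfield tail (beyond any resonance)
    noise_sel = ppm >= hi - 0.5
    noise_sd = float(np.std(mag[noise_sel])) if np.any(noise_sel) else 0.0
    baseline = float(np.median(mag[noise_sel])) if np.any(noise_sel) else 0.0

    cidx = window(C2H_WINDOW_PPM)
    cmax = cidx[np.argmax(mag[cidx])]
    height = mag[cmax] - baseline
    snr = height / noise_sd if noise_sd > 0 else np.inf
    if not np.isfinite(snr):
        snr = float(np.inf)
    if height <= 0 or snr < MIN_PEAK_SNR:
        return PeakLocation(water_ppm, None, float(max(snr, 0.0)) if np.isfinite(snr) else 0.0)
    c2h_ppm = _parabolic_refine(ppm, mag, int(cmax))
    return PeakLocation(water_ppm, c2h_ppm, float(snr) if np.isfinite(snr) else float("inf"))


def estimate_ph(delta_c2h_ppm: float, cal: PhCalibration = DEFAULT_CALIBRATION) -> float:
    """pH from the C2H chemical shift via the titration curve."""
    if not cal.delta_base_ppm < delta_c2h_ppm < cal.delta_acid_ppm:
        raise ValueError(
            f"C2H shift {delta_c2h_ppm:.3f} ppm outside the open calibration "
            f"interval ({cal.delta_base_ppm}, {cal.delta_acid_ppm})"
        )
    return cal.pka + np.log10(
        (cal.delta_acid_ppm - delta_c2h_ppm) / (delta_c2h_ppm - cal.delta_base_ppm)
    )


def shift_for_ph(ph: float, cal: PhCalibration = DEFAULT_CALIBRATION) -> float:
    """Inverse of :func:`estimate_ph`: the C2H shift at a given pH."""
    r = 10.0 ** (ph - cal.pka)
    return (cal.delta_acid_ppm + cal.delta_base_ppm * r) / (1.0 + r)


def apply_mrs_omission(muscle_ff_percent: float) -> bool:
    """True (omit the pH assessment) iff the muscle FF exceeds 30 % (strict)."""
    return muscle_ff_percent > MRS_FF_OMISSION_PERCENT


def ph_from_spectrum(
    spec: Spectrum,
    muscle_ff_percent: float = 0.0,
    cal: PhCalibration = DEFAULT_CALIBRATION,
) -> Optional[float]:
    """End-to-end pH estimate; None when omitted or the C2H peak is absent."""
    if apply_mrs_omission(muscle_ff_percent):
        return None
    peaks = locate_peaks(spec)
    if peaks.c2h_ppm is None:
        return None
    return float(estimate_ph(peaks.c2h_ppm, cal))
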