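"""Tri-exponential water-T2 fitting and exclusion rules."""

from __future__ import annotations

import numpy as np
import pytest

from qmuscle.phantom import FAT_T2_COMPONENTS
from qmuscle.water_t2 import (
    B1_BOUNDS_PERCENT,
    T2_BOUNDS_MS,
    apply_t2_exclusions,
    apply_t2_map_exclusions,
    fit_t2_map,
    fit_triexponential,
)
from qmuscle.types import QuantitativeMap

TE = 9.5 * np.arange(1, 18)


def _decay(aw, t2w, af):
    fat = sum(p * np.exp(-TE / t2f) for p, t2f in FAT_T2_COMPONENTS)
    return aw * np.exp(-TE / t2w) + af * fat


def test_monoexponential_nested_case():
    fit = fit_triexponential(_decay(1.0, 35.0, 0.0), TE)
    assert abs(fit.t2w_ms - 35.0) < 1e-3
    assert abs(fit.fat_amp) < 1e-6


def test_triexponential_exact_recovery():
    fit = fit_triexponential(_decay(0.7, 40.0, 0.3), TE)
    assert abs(fit.t2w_ms - 40.0) < 0.05
    assert abs(fit.water_amp - 0.7) < 1e-3
    assert abs(fit.fat_amp - 0.3) < 1e-3


def test_validation_errors():
    with pytest.raises(ValueError):
        fit_triexponential(np.ones(5), TE[:5])  # too few echoes
    with pytest.raises(ValueError):
        fit_triexponential(np.ones(17), TE[::-1])
    assert not fit_triexponential(np.zeros(17), TE).valid


def test_exclusion_windows_are_strict():
    base = fit_triexponential(_decay(1.0, 35.0, 0.0), TE)
    from dataclasses import replace

    lo, hi = T2_BOUNDS_MS
    # boundaries retained
    assert apply_t2_exclusions(replace(base, t2w_ms=lo), 100.0).valid
    assert apply_t2_exclusions(replace(base, t2w_ms=hi), 100.0).valid
    assert apply_t2_exclusions(base, B1_BOUNDS_PERCENT[0]).valid
    assert apply_t2_exclusions(base, B1_BOUNDS_PERCENT[1]).valid
    # beyond boundaries excluded with the right reason
    assert apply_t2_exclusions(replace(base, t2w_ms=lo - 0.01), 100.0).exclusion == "t2_low"
    assert apply_t2_exclusions(replace(base, t2w_ms=hi + 0.01), 100.0).exclusion == "t2_high"
    assert apply_t2_exclusions(base, 79.9).exclusion == "b1_low"
    assert apply_t2_exclusions(base, 120.1).exclusion == "b1_high"


def test_b1_accepts_fraction_or_percent():
    base = fit_triexponential(_decay(1.0, 35.0, 0.0), TE)
    assert apply_t2_exclusions(base, 0.79).exclusion == "b1_low"
    assert apply_t2_exclusions(base, 1.0).valid


def test_map_exclusions():
    vals = np.array([[[14.0, 35.0, 71.0, 35.0]]])
    q = QuantitativeMap("water_T2", "ms", vals, np.ones_like(vals, bool))
    b1 = np.array([[[100.0, 100.0, 100.0, 121.0]]])
    apply_t2_map_exclusions(q, b1)
    assert list(q.valid[0, 0]) == [False, True, False, False]


def test_rician_correction_reduces_bias(clean_config, clean_truth):
    from qmuscle.phantom import generate_mse_series, sigma_for_snr

    series = generate_mse_series(clean_config, clean_truth)
    m = clean_truth.muscle_mask
    sigma = sigma_for_snr(series, m, 50.0)
    rng = np.random.default_rng(17)
    noisy = np.abs(series.data + sigma * (rng.normal(size=series.data.shape)
                                          + 1j * rng.normal(size=series.data.shape)))
    series.data[:] = noisy
    sel = m & (clean_truth.ff <= 50.0)
    q_on, _, _ = fit_t2_map(series, mask=m, rician_correction=True)
    q_off, _, _ = fit_t2_map(series, mask=m, rician_correction=False)
    err_on = np.median(np.abs(q_on.values[sel] - clean_truth.t2w_ms[sel]))
    err_off = np.median(np.abs(q_off.values[sel] - clean_truth.t2w_ms[sel]))
    assert err_on < err_off


def test_phantom_noiseless_map(clean_config, clean_truth):
    from qmuscle.phantom import generate_mse_series

    series = generate_mse_series(clean_config, clean_truth)
    q, _, _ = fit_t2_map(series, mask=clean_truth.muscle_mask)
    m = clean_truth.muscle_mask & (clean_truth.ff <= 50.0)
    err = np.abs(q.values[m] - clean_truth.t2w_ms[m])
    assert np.median(err) < 0.1
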