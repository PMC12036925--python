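"""Diffusion: noise/SNR, DOFS, b-matrices, tensor fit, exclusions."""

from __future__ import annotations

import numpy as np
import pytest

from qmuscle.dti import (
    DIFFUSION_TIME_OFFSET_MS,
    apply_dti_exclusions,
    bmatrix_from_bvec,
    bmatrix_from_waveform,
    compute_diffusion_time,
    dofs_decompose,
    estimate_noise_and_snr,
    fit_tensor,
    fit_tensor_map,
    process_dti_series,
)
from qmuscle.types import EXCLUSION_CODES

DIRS = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                 [1, 1, 0], [1, 0, 1], [0, 1, 1]], float)
DIRS /= np.linalg.norm(DIRS, axis=1, keepdims=True)


def _bmats(b=400.0):
    return np.stack([np.zeros((3, 3))] + [bmatrix_from_bvec(b, g) for g in DIRS])


def _signals(D_mm2_s, bmats, s0=1.0):
    return s0 * np.exp(-np.einsum("vij,ij->v", bmats, D_mm2_s))


def test_tensor_noiseless_exact():
    rng = np.random.default_rng(0)
    R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    D = R @ np.diag([1.8e-3, 1.5e-3, 1.2e-3]) @ R.T
    fit = fit_tensor(_signals(D, _bmats()), _bmats())
    np.testing.assert_allclose(fit.tensor, D * 1e3, atol=1e-9)
    assert abs(fit.md - 1.5) < 1e-9


def test_isotropic_fa_below_1e6():
    D = np.eye(3) * 1.5e-3
    fit = fit_tensor(_signals(D, _bmats()), _bmats())
    assert fit.fa < 1e-6


def test_rank_deficient_design_raises():
    bm = np.stack([np.zeros((3, 3))] + [bmatrix_from_bvec(400.0, [1, 0, 0])] * 6)
    with pytest.raises(ValueError):
        fit_tensor(np.ones(7), bm)


def test_bmatrix_from_bvec_trace_is_b():
    B = bmatrix_from_bvec(400.0, [1.0, 1.0, 0.0])
    assert np.isclose(np.trace(B), 400.0)
    assert np.allclose(B, B.T)


def test_bmatrix_from_waveform_matches_pgse():
    t = np.linspace(0.0, 0.05, 20001)
    g = np.zeros((len(t), 3))
    delta, Delta, G0 = 0.005, 0.03, 0.03
    g[(t >= 0) & (t < delta), 0] = G0
    g[(t >= Delta) & (t < Delta + delta), 0] = -G0
    B = bmatrix_from_waveform(t, g)
    gamma = 2 * np.pi * 42.577478518e6
    b_analytic = (gamma * G0 * delta) ** 2 * (Delta - delta / 3.0) * 1e-6
    assert abs(B[0, 0] / b_analytic - 1.0) < 2e-3
    assert abs(B[1, 1]) < 1e-9


def test_bmatrix_waveform_cross_terms():
    """Simultaneous x and y lobes must produce an off-diagonal term."""
    t = np.linspace(0.0, 0.05, 20001)
    g = np.zeros((len(t), 3))
    sel1 = (t >= 0) & (t < 0.005)
    sel2 = (t >= 0.03) & (t < 0.035)
    g[sel1, 0] = g[sel1, 1] = 0.03
    g[sel2, 0] = g[sel2, 1] = -0.03
    B = bmatrix_from_waveform(t, g)
    assert B[0, 1] > 0
    assert np.isclose(B[0, 1], B[0, 0], rtol=1e-6)


def test_diffusion_time():
    assert compute_diffusion_time(100.0) == 100.0 + DIFFUSION_TIME_OFFSET_MS
    assert compute_diffusion_time(400.0) == 416.3
    with pytest.raises(ValueError):
        compute_diffusion_time(-1.0)


def test_dofs_single_voxel_exact():
    shifts = np.array([1.1, 3.3, 5.5, 7.8, 10.0, 12.2])
    olef_hz = 0.6 * 123.2
    ts = shifts * 1e-3
    S = (1.0 + 0.07 * np.exp(2j * np.pi * olef_hz * ts)) \
        * np.exp(1j * (0.4 + 2 * np.pi * 12.0 * ts))
    res = dofs_decompose(S.reshape(1, 1, 1, -1), shifts, olef_hz)
    assert abs(res.water[0, 0, 0] - 1.0) < 1e-6
    assert abs(res.olefinic[0, 0, 0] - 0.07) < 1e-6
    assert abs(res.psi_hz[0, 0, 0] - 12.0) < 1e-3
    assert abs(res.olefinic_ff.values[0, 0, 0] - 100 * 0.07 / 1.07) < 1e-3


def test_dofs_needs_three_shifts():
    with pytest.raises(ValueError):
        dofs_decompose(np.ones((1, 1, 1, 2), complex), [1.0, 2.0], 70.0)


def test_snr_estimator_on_known_noise():
    rng = np.random.default_rng(1)
    vols = 30.0 + rng.normal(0.0, 2.0, (20, 20, 3, 6))
    sigma, snr = estimate_noise_and_snr(vols)
    assert abs(np.median(sigma) - 2.0) / 2.0 < 0.15
    assert abs(np.median(snr) - 15.0) / 15.0 < 0.15


def test_snr_caps_on_noiseless_data():
    _, snr = estimate_noise_and_snr(np.full((10, 10, 1, 3), 5.0))
    assert np.all(np.isfinite(snr))


def test_exclusion_precedence():
    codes = apply_dti_exclusions(
        snr=[20, 10, 20, 20, 10],
        olefinic_ff=[5, 5, 12, 5, 12],
        muscle_ff=[30, 30, 30, 60, 60],
        n_voxels=[100, 100, 100, 100, 100],
    )
    assert codes[0] == 0
    assert codes[1] == EXCLUSION_CODES["snr_low"]
    assert codes[2] == EXCLUSION_CODES["olefinic_high"]
    # muscle-level rule dominates voxel rules
    assert codes[3] == EXCLUSION_CODES["muscle_ff_high"]
    assert codes[4] == EXCLUSION_CODES["muscle_ff_high"]


def test_exclusion_boundaries_retained():
    codes = apply_dti_exclusions(15.0, 10.0, 50.0, 50)
    assert codes == 0


def test_process_series_noiseless(clean_config, clean_truth):
    from qmuscle.phantom import generate_dti_series

    series = generate_dti_series(clean_config, clean_truth)
    out = process_dti_series(series, mask=clean_truth.muscle_mask)
    m = clean_truth.muscle_mask
    lam_t = np.linalg.eigvalsh(clean_truth.tensor)[..., ::-1]
    md_t = lam_t.mean(-1)
    err = np.abs(out["tensors"]["MD"].values - md_t)[m]
    assert np.median(err) < 1e-3
    assert out["diffusion_time_ms"] == pytest.approx(116.3)
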