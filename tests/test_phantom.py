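"""Phantom generator: determinism, geometry, field ranges, series layout."""

from __future__ import annotations

import numpy as np
import pytest

from qmuscle.phantom import (
    FAT_T2_COMPONENTS,
    FingerprintSchedule,
    MuscleSpec,
    PhantomConfig,
    default_config,
    fingerprint_signal,
    generate_dixon_series,
    generate_dti_series,
    generate_mse_series,
    generate_spectrum,
    realize_phantom,
)


def test_same_seed_bit_identical():
    a = generate_dixon_series(default_config(seed=3, noise_sigma=0.01))
    b = generate_dixon_series(default_config(seed=3, noise_sigma=0.01))
    np.testing.assert_array_equal(a.data, b.data)


def test_different_seed_differs():
    a = generate_dixon_series(default_config(seed=3, noise_sigma=0.01))
    b = generate_dixon_series(default_config(seed=4, noise_sigma=0.01))
    assert not np.array_equal(a.data, b.data)


def test_modalities_use_independent_streams():
    """MSE noise must not be correlated with Dixon noise for one seed."""
    cfg = default_config(seed=5, noise_sigma=0.02)
    d = generate_dixon_series(cfg)
    m = generate_mse_series(cfg)
    bg = ~realize_phantom(cfg).muscle_mask
    x = np.abs(d.data[..., 0])[bg].ravel()
    y = np.abs(m.data[..., 0])[bg].ravel()
    n = min(len(x), len(y))
    rho = np.corrcoef(x[:n], y[:n])[0, 1]
    assert abs(rho) < 0.05


def test_muscles_do_not_overlap(clean_truth):
    # labels are written muscle by muscle; overlap would have raised
    labels = clean_truth.label_map.labels
    assert set(np.unique(labels)) == {0} | {m.label for m in
                                           clean_truth.config.muscles}


def test_b1_spans_configured_range(clean_truth):
    lo, hi = clean_truth.config.b1_range
    assert np.isclose(clean_truth.b1.min(), lo)
    assert np.isclose(clean_truth.b1.max(), hi)


def test_truth_table_matches_config(clean_truth):
    tbl = clean_truth.truth_table
    assert len(tbl) == len(clean_truth.config.muscles)
    for spec in clean_truth.config.muscles:
        row = tbl[tbl["label"] == spec.label].iloc[0]
        assert row["ff"] == spec.ff
        assert row["t2w_ms"] == spec.t2w_ms
        assert row["n_voxels"] > 0


def test_voxelwise_truth_constant_inside_muscle(clean_truth):
    for spec in clean_truth.config.muscles:
        sel = clean_truth.label_map.labels == spec.label
        assert sel.sum() > 0
        assert np.all(clean_truth.ff[sel] == spec.ff)
        assert np.all(clean_truth.t1w_ms[sel] == spec.t1w_ms)


def test_fat_t2_components_normalized_and_outside_water_window():
    weights = [p for p, _ in FAT_T2_COMPONENTS]
    assert np.isclose(sum(weights), 1.0)
    for _, t2 in FAT_T2_COMPONENTS:
        assert t2 > 70.0  # outside the 15-70 ms water retention window


def test_dixon_series_layout(clean_config, clean_truth):
    s = generate_dixon_series(clean_config, clean_truth)
    assert s.data.shape == clean_config.grid_shape() + (3,)
    assert np.iscomplexobj(s.data)
    np.testing.assert_allclose(s.echo_times(), clean_config.dixon_te_ms)


def test_mse_series_is_magnitude(clean_config, clean_truth):
    s = generate_mse_series(clean_config, clean_truth)
    assert not np.iscomplexobj(s.data)
    assert np.all(s.data >= 0)
    assert len(s.meta) == clean_config.mse_n_echoes


def test_dti_series_has_bmatrices(clean_config, clean_truth):
    s = generate_dti_series(clean_config, clean_truth)
    for m in s.meta:
        assert m.bmatrix is not None
        B = np.asarray(m.bmatrix, float).reshape(3, 3)
        assert np.isclose(np.trace(B), m.bvalue, rtol=1e-6)


def test_fingerprint_signal_broadcasts():
    sched = FingerprintSchedule.default()
    out = fingerprint_signal(np.array([800.0, 1200.0])[:, None], sched,
                             np.array([0.9, 1.0, 1.1])[None, :])
    assert out.shape == (2, 3, len(sched.flip_deg))
    single = fingerprint_signal(1200.0, sched, 1.0)
    np.testing.assert_allclose(out[1, 1], single)


def test_spectrum_roundtrip_json(tmp_path, clean_config):
    spec = generate_spectrum(clean_config, ph=7.0, muscle_ff=5.0)
    p = tmp_path / "s.json"
    spec.to_json(p)
    from qmuscle.types import Spectrum

    back = Spectrum.from_json(p)
    np.testing.assert_allclose(back.ppm, spec.ppm)
    np.testing.assert_allclose(back.signal, spec.signal)


def test_overlapping_muscles_rejected():
    cfg = default_config(seed=0)
    m = cfg.muscles[0]
    dup = MuscleSpec(**{**m.model_dump(), "label": 99, "code": "DUP"})
    with pytest.raises(ValueError):
        realize_phantom(PhantomConfig(**{**cfg.model_dump(),
                                         "muscles": cfg.muscles + [dup]}))


def test_eigenvalues_must_descend():
    cfg = default_config(seed=0)
    m = cfg.muscles[0].model_dump()
    m["eigenvalues"] = (1.0, 1.5, 1.2)
    with pytest.raises(ValueError):
        MuscleSpec(**m)
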