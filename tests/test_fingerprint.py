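"""Fingerprint dictionary construction and matching."""

from __future__ import annotations

import numpy as np
import pytest

from qmuscle.fingerprint import (
    T1_FF_EXCLUSION_PERCENT,
    apply_t1_exclusion,
    build_dictionary,
    default_grid,
    match_fingerprint,
    match_series,
)
from qmuscle.phantom import FAT_T1_MS, FingerprintSchedule, fingerprint_signal
from qmuscle.types import QuantitativeMap


@pytest.fixture(scope="module")
def small_dict():
    grid = {
        "t1_ms": np.arange(800.0, 1601.0, 100.0),
        "ff_percent": np.arange(0.0, 61.0, 10.0),
        "b1": np.arange(0.9, 1.101, 0.05),
    }
    return build_dictionary(FingerprintSchedule.default(), grid)


def _signal(t1, ff, b1, sched):
    w = fingerprint_signal(t1, sched, b1)
    f = fingerprint_signal(FAT_T1_MS, sched, b1)
    return (1.0 - ff / 100.0) * w + (ff / 100.0) * f


def test_default_grid_axes():
    g = default_grid()
    assert g["t1_ms"][0] == 600.0 and g["t1_ms"][-1] == 2000.0
    assert np.allclose(np.diff(g["t1_ms"]), 25.0)
    assert np.allclose(np.diff(g["ff_percent"]), 2.5)
    assert np.allclose(np.diff(g["b1"]), 0.05)


def test_entries_are_unit_rows(small_dict):
    norms = np.linalg.norm(small_dict.entries, axis=1)
    np.testing.assert_allclose(norms, 1.0, rtol=1e-12)
    assert np.all(small_dict.entries >= 0)  # magnitude entries


def test_on_grid_self_match_exact(small_dict):
    sched = small_dict.schedule
    rng = np.random.default_rng(0)
    nodes = small_dict.nodes
    for i in rng.integers(0, len(nodes), 40):
        t1, ff, b1 = nodes[i]
        m = match_fingerprint(_signal(t1, ff, b1, sched), small_dict)
        assert m == (t1, ff, b1)


def test_scale_invariance(small_dict):
    sched = small_dict.schedule
    sig = _signal(1200.0, 20.0, 1.0, sched)
    assert match_fingerprint(sig, small_dict) == match_fingerprint(3.7e4 * sig, small_dict)


def test_zero_signal_returns_none(small_dict):
    assert match_fingerprint(np.zeros(small_dict.entries.shape[1]), small_dict) is None


def test_tie_break_toward_lowest_node(small_dict):
    # two identical entries -> argmax picks the first in C order
    d = small_dict
    e = d.entries.copy()
    e[5] = e[0]
    from dataclasses import replace as dc_replace

    d2 = type(d)(schedule=d.schedule, t1_ms=d.t1_ms, ff_percent=d.ff_percent,
                 b1=d.b1, entries=e, nodes=d.nodes, fat_t1_ms=d.fat_t1_ms)
    sig = e[0]
    m = match_fingerprint(sig, d2)
    assert m == tuple(d.nodes[0])


def test_node_index_consistent(small_dict):
    i = small_dict.node_index(1200.0, 20.0, 1.0)
    np.testing.assert_allclose(small_dict.nodes[i], (1200.0, 20.0, 1.0))


def test_exclusion_strict_above_60():
    vals = np.array([[[1200.0, 1200.0, 1200.0]]])
    t1 = QuantitativeMap("water_T1", "ms", vals, np.ones_like(vals, bool))
    ff = QuantitativeMap("FF_mrf", "%",
                         np.array([[[59.0, 60.0, 60.1]]]),
                         np.ones_like(vals, bool))
    apply_t1_exclusion(t1, ff)
    assert list(t1.valid[0, 0]) == [True, True, False]


def test_match_series_runs_on_small_stack(small_dict):
    sched = small_dict.schedule
    sig = _signal(1000.0, 10.0, 1.0, sched)
    data = np.broadcast_to(sig, (2, 2, 1, len(sig))).copy()
    from qmuscle.types import AcquisitionSeries, VolumeMeta

    series = AcquisitionSeries(
        data=data, meta=[VolumeMeta(pulse_index=i) for i in range(len(sig))],
    )
    t1, ff, b1 = match_series(series, small_dict)
    assert np.all(t1.values == 1000.0)
    assert np.all(ff.values == 10.0)
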