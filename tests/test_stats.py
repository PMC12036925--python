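"""ROI statistics: aggregation, ledger, longitudinal and rank tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from qmuscle import stats as S
from qmuscle.types import MuscleInfo, MuscleLabelMap, QuantitativeMap


def _rec(**kw):
    base = dict(subject="P1", group="patient", visit="BL", side="L",
                muscle="TA", parameter="FF", value=10.0, n_voxels=100)
    base.update(kw)
    return S.MuscleRecord(**base)


# ----------------------------------------------------------------- aggregation


def _label_setup():
    vals = np.zeros((12, 12, 2))
    labels = np.zeros((12, 12, 2), np.int16)
    vals[1:8, 1:8, :] = 1.5
    labels[1:8, 1:8, :] = 1        # 98 voxels
    vals[9:11, 1:4, :] = 2.0
    labels[9:11, 1:4, :] = 2       # 12 voxels
    info = {
        1: MuscleInfo(label=1, code="TA", name="tibialis anterior",
                      side="L", compartment="leg"),
        2: MuscleInfo(label=2, code="SOL", name="soleus",
                      side="L", compartment="leg"),
    }
    q = QuantitativeMap("MD", "um^2/ms", vals, labels > 0)
    return q, MuscleLabelMap(labels=labels, muscles=info)


def test_aggregate_min_voxel_rule_and_ledger():
    q, lm = _label_setup()
    led = S.ExclusionLedger()
    recs = S.aggregate_muscle(q, lm, parameter="MD", ledger=led)
    by = {r.muscle: r for r in recs}
    assert by["TA"].value == 1.5 and not by["TA"].excluded
    assert by["SOL"].excluded and by["SOL"].reason == "too_few_voxels"
    assert led.conserved("MD")
    summary = led.summary()["MD"]
    assert summary["total"] == summary["retained"] + sum(summary["excluded"].values())


def test_aggregate_absent_label_gives_zero_count_record():
    q, lm = _label_setup()
    lm.muscles[3] = MuscleInfo(label=3, code="GM", name="gastrocnemius medialis",
                               side="L", compartment="leg")
    recs = S.aggregate_muscle(q, lm, parameter="MD")
    gm = [r for r in recs if r.muscle == "GM"][0]
    assert gm.n_voxels == 0 and gm.excluded


def test_weighted_average_uses_voxel_counts():
    recs = [_rec(muscle="TA", value=10.0, n_voxels=100),
            _rec(muscle="SOL", value=20.0, n_voxels=300)]
    assert S.weighted_average(recs) == pytest.approx(17.5)


def test_weighted_average_scopes():
    recs = [_rec(muscle="TA", value=10.0, n_voxels=100),       # leg
            _rec(muscle="RF", value=30.0, n_voxels=100)]       # thigh
    assert S.weighted_average(recs, scope="global_leg") == pytest.approx(10.0)
    assert S.weighted_average(recs, scope="global_thigh") == pytest.approx(30.0)
    assert S.weighted_average([], scope="all") is None


def test_bilateral_average_weighted_merge():
    recs = [_rec(side="L", value=10.0, n_voxels=100),
            _rec(side="R", value=20.0, n_voxels=300)]
    out = S.bilateral_average(recs)
    assert len(out) == 1
    assert out[0].side == "LR"
    assert out[0].value == pytest.approx(17.5)
    assert out[0].n_voxels == 400


def test_bilateral_unilateral_flagged():
    out = S.bilateral_average([_rec(side="L", value=10.0)])
    assert out[0].reason == "unilateral"
    assert out[0].value == 10.0


# ------------------------------------------------------------------ bookkeeping


def test_cohort_tally_matches_study_numbers():
    t = S.tally_cohort()
    assert t == {"total": 2268, "patients": 1800, "controls": 468,
                 "dti_total": 441}


def test_significance_levels():
    assert S.significance_levels(9) == 0.0056
    assert S.significance_levels(20) == 0.0025
    with pytest.raises(ValueError):
        S.significance_levels(0)


# ---------------------------------------------------------------- longitudinal


def test_delta_completers_only():
    vals = {"P1": {"BL": 10.0, "2y": 13.0},
            "P2": {"BL": 20.0, "2y": 24.0},
            "P3": {"BL": 5.0}}
    with pytest.warns(UserWarning):
        d = S.delta_over_time(vals)
    assert d.deltas == {"P1": 3.0, "P2": 4.0}
    assert d.mean == pytest.approx(3.5)
    assert d.sd == pytest.approx(np.std([3.0, 4.0], ddof=1))


def test_srm_definition_and_edge_cases():
    assert S.standardized_response_mean([1.0, 2.0, 3.0]) == pytest.approx(2.0)
    assert S.standardized_response_mean([2.0, 2.0]) is None  # zero SD
    with pytest.raises(ValueError):
        S.standardized_response_mean([1.0])


def test_srm_simulation_recovers_point_eight():
    rng = np.random.default_rng(42)
    deltas = rng.normal(0.8, 1.0, 500)
    srm = S.standardized_response_mean(deltas)
    assert abs(srm - 0.8) < 0.1


# ------------------------------------------------------------------ rank tests


def test_spearman_matches_exhaustive_oracle():
    rng = np.random.default_rng(1)
    for n in (4, 5, 6, 7):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        rho, p, _ = S.spearman(x, y)
        rx = sps.rankdata(x) - (n + 1) / 2
        ry = sps.rankdata(y) - (n + 1) / 2
        obs = abs(rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        hits = total = 0
        for perm in itertools.permutations(ry):
            pv = np.asarray(perm)
            hits += abs(rx @ pv) / np.sqrt((rx @ rx) * (pv @ pv)) >= obs - 1e-12
            total += 1
        assert p == pytest.approx(hits / total, abs=1e-12)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)


def test_spearman_constant_vector_rejected():
    with pytest.raises(ValueError):
        S.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_correlation_bands():
    assert S.correlation_band(0.1) == "very weak"
    assert S.correlation_band(-0.35) == "weak"
    assert S.correlation_band(0.55) == "moderate"
    assert S.correlation_band(0.75) == "strong"
    assert S.correlation_band(0.95) == "very strong"


def test_wilcoxon_matches_enumeration():
    rng = np.random.default_rng(2)
    for n in (6, 7, 8):
        d = rng.normal(0.5, 1.0, n)
        stat, p = S.wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        w_pos = sum(r for r, v in zip(ranks, d) if v > 0)
        total_rank = ranks.sum()
        ws = np.array([sum(r for r, s in zip(ranks, sg) if s)
                       for sg in itertools.product([0, 1], repeat=n)])
        w_obs = min(w_pos, total_rank - w_pos)
        p_exact = np.mean(np.minimum(ws, total_rank - ws) <= w_obs + 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-12)


def test_mann_whitney_matches_enumeration():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 5)
    y = rng.normal(1, 1, 4)
    u, p = S.mann_whitney(x, y)
    r = sps.rankdata(np.concatenate([x, y]))
    u_obs = sum(r[:5]) - 5 * 6 / 2
    us = np.array([sum(r[list(i)]) - 15
                   for i in itertools.combinations(range(9), 5)])
    n1n2 = 20
    p_exact = np.mean(np.minimum(us, n1n2 - us)
                      <= min(u_obs, n1n2 - u_obs) + 1e-12)
    assert p == pytest.approx(p_exact, abs=1e-12)


# ---------------------------------------------------------------------- tables


def test_long_table_round_trip(tmp_path):
    recs = [_rec(), _rec(visit="2y", value=13.0, n_voxels=95)]
    path = tmp_path / "table.csv"
    led = S.ExclusionLedger()
    led.add_records(recs)
    S.export_long_table(recs, path, ledger=led)
    assert path.exists()
    assert path.with_suffix(".ledger.json").exists() or \
        (tmp_path / "table.ledger.json").exists()
    back = S.read_long_table(path)
    assert back == recs
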