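"""ROI aggregation, exclusion bookkeeping and longitudinal statistics.

Per-muscle means are computed over valid voxels of a quantitative map;
muscles with fewer than 50 valid voxels are excluded (strict).  Global and
muscle-group averages weight each muscle mean by its voxel count, and the
left/right merge uses the same voxel-count weighting.  Longitudinal change
is Delta = parameter(follow-up) - parameter(baseline) on complete pairs,
and responsiveness is summarized by the standardized response mean,
SRM = mean(Delta) / SD(Delta) with the sample (n-1) SD.  Spearman
correlations carry the conventional qualitative band labels, and
Bonferroni-corrected significance levels are reported to four decimals.
Group comparisons (Wilcoxon signed-rank, Mann-Whitney U) are thin wrappers
with exact small-sample null distributions.  The long-format muscle table
is exported as tidy CSV for external mixed-model fitting.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import EXCLUSION_NAMES, MuscleLabelMap, QuantitativeMap

__all__ = [
    "MuscleRecord",
    "MUSCLE_GROUPS",
    "THIGH_CODES",
    "LEG_CODES",
    "ExclusionLedger",
    "CohortDesign",
    "aggregate_muscle",
    "weighted_average",
    "bilateral_average",
    "tally_cohort",
    "delta_over_time",
    "standardized_response_mean",
    "spearman",
    "correlation_band",
    "significance_levels",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "export_long_table",
    "MIN_VOXELS",
]

MIN_VOXELS = 50

# Muscle dictionary: 11 thigh + 7 lower-leg codes and their group membership.
THIGH_CODES = ("AL", "AM", "BF", "GRA", "RF", "SAR", "SM", "ST", "VI", "VL", "VM")
LEG_CODES = ("ED", "GL", "GM", "PER", "SOL", "TA", "TP")
MUSCLE_GROUPS = {
    "QUAD": ("RF", "VI", "VL", "VM"),
    "HSTR": ("BF", "SM", "ST"),
    "ANT": ("TA", "TP", "ED"),
    "FIB": ("PER",),
    "TRIC": ("GM", "GL", "SOL"),
}
# strength test <-> muscle-group pairing used for correlation analyses
STRENGTH_GROUP_PAIRING = {
    "knee_extension": "QUAD",
    "knee_flexion": "HSTR",
    "dorsiflexion": "ANT",
    "plantarflexion": "TRIC",
}

RECORD_COLUMNS = [
    "subject", "group", "visit", "side", "muscle", "parameter",
    "value", "n_voxels", "excluded", "reason",
]


@dataclass(frozen=True)
class MuscleRecord:
    """One row of the long-format muscle table."""

    subject: str
    group: str      # patient / control
    visit: str      # BL / 1y / 2y
    side: str       # L / R (or "LR" after bilateral merging)
    muscle: str
    parameter: str
    value: float
    n_voxels: int
    excluded: bool = False
    reason: str = "none"


class ExclusionLedger:
    """Append-only per-parameter tally of retained/excluded muscles."""

    def __init__(self) -> None:
        self._counts: dict[str, dict[str, int]] = {}

    def add(self, parameter: str, reason: str = "none") -> None:
        entry = self._counts.setdefault(parameter, {})
        entry[reason] = entry.get(reason, 0) + 1

    def add_records(self, records: Iterable[MuscleRecord]) -> None:
        for r in records:
            self.add(r.parameter, r.reason if r.excluded else "none")

    def total(self, parameter: str) -> int:
        return sum(self._counts.get(parameter, {}).values())

    def retained(self, parameter: str) -> int:
        return self._counts.get(parameter, {}).get("none", 0)

    def excluded(self, parameter: str) -> dict[str, int]:
        return {k: v for k, v in self._counts.get(parameter, {}).items() if k != "none"}

    def conserved(self, parameter: str) -> bool:
        return self.total(parameter) == self.retained(parameter) + sum(
            self.excluded(parameter).values()
        )

    def summary(self) -> dict:
        return {
            p: {
                "total": self.total(p),
                "retained": self.retained(p),
                "excluded": self.excluded(p),
            }
            for p in sorted(self._counts)
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def aggregate_muscle(
    qmap: QuantitativeMap,
    labels: MuscleLabelMap,
    parameter: Optional[str] = None,
    subject: str = "S1",
    group: str = "patient",
    visit: str = "BL",
    ledger: Optional[ExclusionLedger] = None,
) -> list[MuscleRecord]:
    """Mean parameter value per muscle over all valid voxels.

    Voxel-level exclusions must already be encoded in the map's validity
    mask; here the muscle-level rule applies: fewer than 50 valid voxels
    excludes the muscle.  A muscle present in the dictionary but absent
    from the label volume yields a count-0 excluded record.
    """
    if qmap.values.shape != labels.labels.shape:
        raise ValueError("map and label volume must be co-registered")
    parameter = parameter or qmap.name
    records = []
    for label, info in labels.muscles.items():
        sel = labels.mask(label) & qmap.valid
        n = int(np.count_nonzero(sel))
        value = float(np.mean(qmap.values[sel])) if n else float("nan")
        excluded = n < MIN_VOXELS
        records.append(
            MuscleRecord(
                subject=subject, group=group, visit=visit, side=info.side,
                muscle=info.code, parameter=parameter, value=value,
                n_voxels=n, excluded=excluded,
                reason="too_few_voxels" if excluded else "none",
            )
        )
    if ledger is not None:
        ledger.add_records(records)
    return records


def _retained(records: Iterable[MuscleRecord]) -> list[MuscleRecord]:
    return [r for r in records if not r.excluded]


def weighted_average(
    records: Iterable[MuscleRecord],
    scope: str = "all",
) -> Optional[float]:
    """Voxel-count-weighted mean of retained muscle means.

    ``scope``: "all", "global_thigh", "global_leg", or a muscle-group name
    (QUAD, HSTR, ANT, FIB, TRIC).  Returns None when no retained record
    falls in scope.
    """
    recs = _retained(records)
    if scope == "global_thigh":
        recs = [r for r in recs if r.muscle in THIGH_CODES]
    elif scope == "global_leg":
        recs = [r for r in recs if r.muscle in LEG_CODES]
    elif scope in MUSCLE_GROUPS:
        recs = [r for r in recs if r.muscle in MUSCLE_GROUPS[scope]]
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    weights = np.array([r.n_voxels for r in recs], dtype=float)
    values = np.array([r.value for r in recs], dtype=float)
    if weights.sum() == 0:
        return None
    return float(np.sum(values * weights) / weights.sum())


def bilateral_average(records: Sequence[MuscleRecord]) -> list[MuscleRecord]:
    """Merge left and right records per (subject, visit, muscle, parameter).

    The merge is voxel-count weighted, consistent with the pixel-weighted
    global averages.  When one side is missing or excluded, the available
    side is carried forward with reason "unilateral".
    """
    keyed: dict[tuple, list[MuscleRecord]] = {}
    for r in records:
        keyed.setdefault((r.subject, r.visit, r.muscle, r.parameter), []).append(r)
    merged = []
    for key, pair in keyed.items():
        ok = _retained(pair)
        if len(ok) == 0:
            merged.append(replace(pair[0], side="LR"))
            continue
        if len(ok) == 1:
            merged.append(replace(ok[0], side="LR", reason="unilateral"))
            continue
        w = np.array([r.n_voxels for r in ok], dtype=float)
        v = np.array([r.value for r in ok], dtype=float)
        merged.append(
            replace(
                ok[0], side="LR",
                value=float(np.sum(v * w) / w.sum()),
                n_voxels=int(w.sum()),
            )
        )
    return merged


@dataclass(frozen=True)
class CohortDesign:
    """Exam bookkeeping of a longitudinal imaging study."""

    patient_exams: tuple[int, ...] = (18, 16, 16)  # per visit
    control_exams: int = 13
    n_thigh_muscles: int = 11
    n_leg_muscles: int = 7
    sides: int = 2
    dti_muscles: int = 7   # lower leg only
    dti_sides: int = 1     # right only


def tally_cohort(design: CohortDesign = CohortDesign()) -> dict[str, int]:
    """Segmented-muscle totals implied by a cohort design.

    Every exam contributes (thigh + leg muscles) x sides for the
    relaxometry/Dixon modalities; the diffusion scan covers only the
    lower-leg muscles of one side.
    """
    n_muscles = (design.n_thigh_muscles + design.n_leg_muscles) * design.sides
    patient_exams = sum(design.patient_exams)
    patients = patient_exams * n_muscles
    controls = design.control_exams * n_muscles
    exams = patient_exams + design.control_exams
    dti_total = exams * design.dti_muscles * design.dti_sides
    return {
        "total": patients + controls,
        "patients": patients,
        "controls": controls,
        "dti_total": dti_total,
    }


@dataclass
class DeltaResult:
    deltas: dict[str, float] = field(default_factory=dict)
    mean: float = float("nan")
    sd: float = float("nan")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.deltas.values()), dtype=float)


def delta_over_time(
    values: Mapping[str, Mapping[str, float]],
    baseline: str = "BL",
    followup: str = "2y",
) -> DeltaResult:
    """Per-subject change Delta = value(follow-up) - value(baseline).

    Only subjects with both visits contribute (completers); unpaired
    subjects are dropped with a warning.  SD is the sample SD (n-1).
    """
    deltas = {}
    for subject, visits in values.items():
        if baseline in visits and followup in visits:
            deltas[subject] = float(visits[followup]) - float(visits[baseline])
        else:
            warnings.warn(f"subject {subject} lacks a {baseline}/{followup} pair; dropped",
                          stacklevel=2)
    arr = np.array(list(deltas.values()), dtype=float)
    mean = float(arr.mean()) if arr.size else float("nan")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return DeltaResult(deltas=deltas, mean=mean, sd=sd)


def standardized_response_mean(deltas: Sequence[float]) -> Optional[float]:
    """SRM = mean change / SD of change (sample SD); None when SD is 0."""
    arr = np.asarray(deltas, dtype=float)
    if arr.size < 2:
        raise ValueError("SRM needs at least 2 paired changes")
    sd = arr.std(ddof=1)
    if sd == 0:
        return None
    return float(arr.mean() / sd)


def correlation_band(rho: float) -> str:
    """Qualitative label of |rho|: very weak < 0.20 <= weak < 0.40 <=
    moderate < 0.60 <= strong < 0.80 <= very strong."""
    a = abs(rho)
    if a < 0.20:
        return "very weak"
    if a < 0.40:
        return "weak"
    if a < 0.60:
        return "moderate"
    if a < 0.80:
        return "strong"
    return "very strong"


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float, str]:
    """Spearman rank correlation (mid-rank ties) with its band label.

    Returns (rho, p-value, band).  For n up to ``exact_max_n`` the two-sided
    p-value comes from full enumeration of the permutation null of |rho|;
    above that the t approximation is used.  Constant input is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    n = len(x)
    if n <= exact_max_n:
        rx = sps.rankdata(x) - (n + 1) / 2.0
        ry = sps.rankdata(y) - (n + 1) / 2.0
        obs = abs(rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        hits = total = 0
        for perm in itertools.permutations(ry):
            pv = np.asarray(perm)
            r = abs(rx @ pv) / np.sqrt((rx @ rx) * (pv @ pv))
            hits += r >= obs - 1e-12
            total += 1
        p = hits / total
    return float(rho), float(p), correlation_band(float(rho))


def significance_levels(n_comparisons: int) -> float:
    """Bonferroni-corrected alpha = 0.05/n, rounded to 4 decimals for
    reporting (n = 9 -> 0.0056, n = 20 -> 0.0025)."""
    if n_comparisons < 1:
        raise ValueError("number of comparisons must be >= 1")
    return round(0.05 / n_comparisons, 4)


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 12):
    """Wilcoxon signed-rank test; exact null for small samples without
    ties, normal approximation above ``exact_max_n``."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    method = "exact" if (len(d) <= exact_max_n and len(np.unique(np.abs(d))) == len(d)) else "approx"
    res = sps.wilcoxon(d, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y, exact_max_n: int = 12):
    """Mann-Whitney U test; exact small-sample null, else normal approx."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def records_to_frame(records: Iterable[MuscleRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def export_long_table(
    records: Sequence[MuscleRecord],
    path: str | Path,
    ledger: Optional[ExclusionLedger] = None,
) -> pd.DataFrame:
    """Write the tidy long-format table (CSV) plus a ledger summary JSON."""
    df = records_to_frame(records)
    path = Path(path)
    df.to_csv(path, index=False)
    if ledger is None:
        ledger = ExclusionLedger()
        ledger.add_records(records)
    ledger.to_json(path.with_suffix(".ledger.json"))
    return df


def read_long_table(path: str | Path) -> list[MuscleRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MuscleRecord(
                subject=str(row.subject), group=str(row.group), visit=str(row.visit),
                side=str(row.side), muscle=str(row.muscle), parameter=str(row.parameter),
                value=float(row.value), n_voxels=int(row.n_voxels),
                excluded=bool(row.excluded), reason=str(row.reason),
            )
        )
    return records
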