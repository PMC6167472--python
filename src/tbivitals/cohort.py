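"""Cohort assembly: inclusion/exclusion rules and ND outcome classification.

The study population is isolated TBI: prehospital shock index >= 0.62 (or a
priority-1/unstable designation), head AIS > 1, no significant systemic
trauma (abdominal or thoracic AIS > 1 excluded), survival of at least
15 minutes after trauma-center admission, and available waveform data.

Neurological decline (ND) within the first 48 h is a composite of four
criteria applied to the longitudinal assessment timeline:

* new asymmetric pupillary dilatation (> 2 mm left/right difference, absent
  at the first recorded assessment);
* a GCS decline of >= 2 points not attributable to analgo-sedation (declines
  within 2 h after a sedation/analgesia administration are suppressed);
* interval worsening of the CT Marshall score (a later score strictly
  exceeding an earlier one) — the radiographic criterion;
* any intervention for cerebral edema (ICP monitor, EVD, osmotherapy,
  hyperventilation, craniotomy, decompressive craniectomy).

A patient meeting both clinical and radiographic criteria counts as a
single ND event (``nd_type = "both"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tbivitals.types import InputError

__all__ = [
    "AssessmentTimeline",
    "NDResult",
    "InclusionResult",
    "SHOCK_INDEX_THRESHOLD",
    "ND_HORIZON_MIN",
    "SEDATION_SUPPRESSION_MIN",
    "apply_inclusion",
    "classify_nd",
    "assemble_dataset",
]

SHOCK_INDEX_THRESHOLD = 0.62  # inclusive lower bound
MIN_SURVIVAL_MIN = 15
ND_HORIZON_MIN = 48 * 60
SEDATION_SUPPRESSION_MIN = 120  # declines within (t, t+120] of a dose are suppressed

EDEMA_INTERVENTIONS = frozenset(
    {
        "icp_monitor",
        "evd",
        "osmotherapy",
        "hyperventilation",
        "craniotomy",
        "decompressive_craniectomy",
    }
)

# rule name -> (column, predicate); applied in this order, all failures attributed
_RULES = (
    ("shock_index", "below shock-index threshold"),
    ("head_ais", "head AIS <= 1"),
    ("abdominal_ais", "abdominal AIS > 1"),
    ("thoracic_ais", "thoracic AIS > 1"),
    ("survival", "survived < 15 min"),
    ("waveform", "waveform unavailable"),
)


@dataclass
class InclusionResult:
    retained: pd.DataFrame
    rejected: pd.DataFrame  # with a 'rejection_reasons' column
    counts: dict[str, int]


def apply_inclusion(records: pd.DataFrame) -> InclusionResult:
    """Apply the cohort inclusion/exclusion rules.

    Expected columns: ``shock_index``, ``head_ais``, ``abdominal_ais``,
    ``thoracic_ais``, ``survival_minutes``, ``waveform_available``;
    optionally ``priority1`` (critically-ill field designation, which
    admits a patient regardless of shock index). A missing (NaN) value on a
    required rule makes that rule indeterminate and the patient is rejected
    with reason ``missing:<column>``. Every rejection is attributed: a
    patient failing several rules appears once in ``rejected`` with all
    reasons, and each per-rule count includes every patient failing it.
    The filter is row-order independent.
    """
    df = records.copy()
    priority = df["priority1"].fillna(False).astype(bool) if "priority1" in df else pd.Series(False, index=df.index)

    reasons: list[list[str]] = [[] for _ in range(len(df))]
    counts: dict[str, int] = {name: 0 for name, _ in _RULES}
    counts["missing"] = 0

    checks = {
        "shock_index": (df["shock_index"], lambda v, i: v >= SHOCK_INDEX_THRESHOLD or priority.iloc[i]),
        "head_ais": (df["head_ais"], lambda v, i: v > 1),
        "abdominal_ais": (df["abdominal_ais"], lambda v, i: v <= 1),
        "thoracic_ais": (df["thoracic_ais"], lambda v, i: v <= 1),
        "survival": (df["survival_minutes"], lambda v, i: v >= MIN_SURVIVAL_MIN),
        "waveform": (df["waveform_available"], lambda v, i: bool(v)),
    }
    for rule, (col, pred) in checks.items():
        values = col.to_numpy()
        for i, v in enumerate(values):
            if pd.isna(v):
                reasons[i].append(f"missing:{rule}")
                counts["missing"] += 1
            elif not pred(v, i):
                reasons[i].append(rule)
                counts[rule] += 1

    ok = np.array([not r for r in reasons])
    retained = df.loc[ok].copy()
    rejected = df.loc[~ok].copy()
    rejected["rejection_reasons"] = [";".join(r) for r, keep in zip(reasons, ok) if not keep]
    return InclusionResult(retained, rejected, counts)


@dataclass
class AssessmentTimeline:
    """Longitudinal assessments for one patient, times in minutes from TRU admission.

    ``gcs``: (time, score); ``pupils``: (time, left_mm, right_mm);
    ``sedation_times``: administration times of sedation/analgesia;
    ``interventions``: (time, name) with names from ``EDEMA_INTERVENTIONS``;
    ``marshall``: (time, score 1-6).
    """

    gcs: list[tuple[float, float]] = field(default_factory=list)
    pupils: list[tuple[float, float, float]] = field(default_factory=list)
    sedation_times: list[float] = field(default_factory=list)
    interventions: list[tuple[float, str]] = field(default_factory=list)
    marshall: list[tuple[float, int]] = field(default_factory=list)


@dataclass(frozen=True)
class NDResult:
    nd: bool
    nd_type: str  # clinical | radiographic | both | none
    first_event_time: float | None  # minutes, None if no event


def _within_horizon(t: float) -> bool:
    return 0 <= t <= ND_HORIZON_MIN


def classify_nd(
    timeline: AssessmentTimeline,
    gcs_baseline: str = "running_max",
) -> NDResult:
    """Classify neurological decline from one patient's 48 h timeline.

    ``gcs_baseline`` selects the reference for the 2-point GCS decline:
    ``"running_max"`` (default) compares each score against the best prior
    score; ``"admission"`` compares against the first recorded score only.
    Raises :class:`InputError` on an empty timeline (ND indeterminate).
    """
    if gcs_baseline not in ("running_max", "admission"):
        raise InputError(f"unknown gcs_baseline {gcs_baseline!r}")
    has_any = timeline.gcs or timeline.pupils or timeline.interventions or timeline.marshall
    if not has_any:
        raise InputError("empty assessment timeline: ND indeterminate")

    clinical_times: list[float] = []
    radiographic_times: list[float] = []

    # GCS decline >= 2 vs baseline, suppressed within 2 h of sedation
    gcs = sorted((t, v) for t, v in timeline.gcs if _within_horizon(t))
    sed = sorted(t for t in timeline.sedation_times)
    if gcs:
        baseline = gcs[0][1]
        for t, v in gcs[1:]:
            if baseline - v >= 2:
                suppressed = any(0 < t - s <= SEDATION_SUPPRESSION_MIN for s in sed)
                if not suppressed:
                    clinical_times.append(t)
            if gcs_baseline == "running_max":
                baseline = max(baseline, v)

    # new pupillary asymmetry > 2 mm (absent at the first assessment)
    pupils = sorted(timeline.pupils)
    if pupils:
        first_asym = abs(pupils[0][1] - pupils[0][2]) > 2.0
        if not first_asym:
            for t, left, right in pupils[1:]:
                if _within_horizon(t) and abs(left - right) > 2.0:
                    clinical_times.append(t)

    # any cerebral-edema intervention
    for t, name in timeline.interventions:
        if _within_horizon(t) and name in EDEMA_INTERVENTIONS:
            clinical_times.append(t)

    # radiographic: a later Marshall score strictly exceeding an earlier one
    marshall = sorted((t, v) for t, v in timeline.marshall if _within_horizon(t))
    if marshall:
        best = marshall[0][1]
        for t, v in marshall[1:]:
            if v > best:
                radiographic_times.append(t)
            best = min(best, v)

    clinical = bool(clinical_times)
    radiographic = bool(radiographic_times)
    if clinical and radiographic:
        nd_type = "both"
    elif clinical:
        nd_type = "clinical"
    elif radiographic:
        nd_type = "radiographic"
    else:
        nd_type = "none"
    all_times = clinical_times + radiographic_times
    return NDResult(
        nd=clinical or radiographic,
        nd_type=nd_type,
        first_event_time=min(all_times) if all_times else None,
    )


def assemble_dataset(
    records: pd.DataFrame,
    nd_outcomes: pd.DataFrame,
    feature_table: pd.DataFrame,
    id_col: str = "patient_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join retained patients, ND outcomes, and window features.

    Returns ``(analysis, exclusions)``: one analysis row per patient present
    (and feature-complete) in all three inputs; every other patient is
    listed in ``exclusions`` with the input(s) it is missing from —
    incomplete patients are reported, never silently dropped. Duplicate ids
    in any input raise :class:`InputError`.
    """
    for name, df in (("records", records), ("nd_outcomes", nd_outcomes), ("features", feature_table)):
        if df[id_col].duplicated().any():
            dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
            raise InputError(f"duplicate patient ids in {name}: {dupes}")
    ids = {
        "records": set(records[id_col]),
        "nd_outcomes": set(nd_outcomes[id_col]),
        "features": set(feature_table[id_col]),
    }
    complete = ids["records"] & ids["nd_outcomes"] & ids["features"]
    excl_rows = []
    for pid in sorted(set().union(*ids.values()) - complete):
        missing = [name for name, s in ids.items() if pid not in s]
        excl_rows.append({id_col: pid, "missing_from": ";".join(missing)})
    exclusions = pd.DataFrame(excl_rows, columns=[id_col, "missing_from"])
    analysis = (
        records[records[id_col].isin(complete)]
        .merge(nd_outcomes, on=id_col)
        .merge(feature_table, on=id_col)
        .reset_index(drop=True)
    )
    return analysis, exclusions
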