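"""NEDA-3 outcome classification and cohort exclusion rules.

A patient is NEDA ("no evidence of disease activity") at 2 years when all
three activity components are observed and negative: no relapses, no active
MRI lesions (new/enlarging T2 or Gd-enhancing), and no EDSS progression.  A
single observed positive component proves EDA regardless of missing data;
a patient with a missing component and no observed positive cannot be
classified and is excluded from the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd


class Status(str, Enum):
    NEDA = "NEDA"
    EDA = "EDA"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"


#: recent-natalizumab exclusion window (months before treatment start)
NTZ_WASHOUT_MONTHS = 9.0


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def validate_edss(value: float, name: str = "edss") -> float:
    """EDSS scores live on the 0-10 half-point grid."""
    v = float(value)
    if not 0.0 <= v <= 10.0 or (2 * v) != int(2 * v):
        raise ValueError(f"{name}={value!r} is not on the 0-10 half-point EDSS grid")
    return v


@dataclass
class FollowUpRecord:
    """Observable 2-year follow-up components for one patient."""

    patient_id: str
    relapse_count_2y: float | None
    new_t2_flag: bool | float | None
    gdplus_flag: bool | float | None
    edss_baseline: float
    edss_2y: float | None
    months_since_ntz_stop: float | None = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "FollowUpRecord":
        return cls(
            patient_id=str(row["patient_id"]),
            relapse_count_2y=row.get("relapse_count_2y"),
            new_t2_flag=row.get("new_t2_flag"),
            gdplus_flag=row.get("gdplus_flag"),
            edss_baseline=row["edss_baseline"],
            edss_2y=row.get("edss_2y"),
            months_since_ntz_stop=row.get("months_since_ntz_stop"),
        )


@dataclass
class ResponseLabel:
    patient_id: str
    status: Status


def edss_progression(baseline: float, at_2y: float) -> bool:
    """Single-timepoint EDSS progression on the baseline-dependent ladder.

    Progression is an increase of >= 1.5 points from a baseline of 0,
    >= 1.0 from a baseline in (0, 5.0], and >= 0.5 from a baseline >= 5.5.
    """
    b = validate_edss(baseline, "edss_baseline")
    a = validate_edss(at_2y, "edss_2y")
    if b == 0:
        return a - b >= 1.5
    if b <= 5.0:
        return a - b >= 1.0
    return a - b >= 0.5


def classify_neda3(record: FollowUpRecord) -> ResponseLabel:
    """Derive the EDA / NEDA / UNCLASSIFIABLE status for one patient.

    Any observed positive component dominates missingness (it already proves
    disease activity); NEDA requires every component observed and negative.
    """
    components: list[bool | None] = []

    if _is_missing(record.relapse_count_2y):
        components.append(None)
    else:
        count = float(record.relapse_count_2y)
        if count < 0:
            raise ValueError(f"negative relapse count for {record.patient_id}")
        components.append(count >= 1)

    for flag in (record.new_t2_flag, record.gdplus_flag):
        components.append(None if _is_missing(flag) else bool(flag))

    if _is_missing(record.edss_2y):
        components.append(None)
    else:
        components.append(edss_progression(record.edss_baseline, record.edss_2y))

    if any(c is True for c in components):
        status = Status.EDA
    elif any(c is None for c in components):
        status = Status.UNCLASSIFIABLE
    else:
        status = Status.NEDA
    return ResponseLabel(patient_id=record.patient_id, status=status)


def classify_followups(followups: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a follow-up table.

    Returns a two-column frame (patient_id, status).
    """
    labels = [
        classify_neda3(FollowUpRecord.from_row(row))
        for _, row in followups.iterrows()
    ]
    return pd.DataFrame(
        {
            "patient_id": [l.patient_id for l in labels],
            "status": [l.status.value for l in labels],
        }
    )


def apply_exclusions(followups: pd.DataFrame) -> pd.DataFrame:
    """Drop patients who stopped natalizumab less than 9 months before start.

    ``months_since_ntz_stop`` is NaN for patients never treated with
    natalizumab; those are retained, as is the exact 9-month boundary.
    """
    months = followups["months_since_ntz_stop"]
    keep = months.isna() | (months >= NTZ_WASHOUT_MONTHS)
    return followups.loc[keep].reset_index(drop=True)


def cohort_accounting(
    post_qc_counts: dict[str, int], unclassifiable_counts: dict[str, int]
) -> dict:
    """Patient accounting from post-QC cohort sizes to the analyzable set."""
    cohorts = sorted(post_qc_counts)
    if set(unclassifiable_counts) - set(post_qc_counts):
        raise ValueError("unclassifiable counts reference unknown cohorts")
    per_cohort = {
        c: {
            "post_qc": int(post_qc_counts[c]),
            "unclassifiable": int(unclassifiable_counts.get(c, 0)),
            "analyzable": int(post_qc_counts[c]) - int(unclassifiable_counts.get(c, 0)),
        }
        for c in cohorts
    }
    if any(v["analyzable"] < 0 for v in per_cohort.values()):
        raise ValueError("more unclassifiable than post-QC patients in a cohort")
    return {
        "per_cohort": per_cohort,
        "analyzable_total": sum(v["analyzable"] for v in per_cohort.values()),
    }


def accounting_from_labels(labels: pd.DataFrame, cohorts: pd.Series) -> dict:
    """Accounting computed from actual classified labels.

    ``labels`` is the (patient_id, status) frame, ``cohorts`` maps
    patient_id -> cohort name.
    """
    merged = labels.assign(cohort=labels["patient_id"].map(cohorts))
    if merged["cohort"].isna().any():
        missing = merged.loc[merged["cohort"].isna(), "patient_id"].tolist()
        raise ValueError(f"patients without cohort assignment: {missing[:5]}")
    post_qc = merged.groupby("cohort").size().to_dict()
    unclass = (
        merged[merged["status"] == Status.UNCLASSIFIABLE.value]
        .groupby("cohort")
        .size()
        .to_dict()
    )
    out = cohort_accounting(post_qc, unclass)
    counts = merged[merged["status"] != Status.UNCLASSIFIABLE.value][
        "status"
    ].value_counts()
    out["eda"] = int(counts.get(Status.EDA.value, 0))
    out["neda"] = int(counts.get(Status.NEDA.value, 0))
    return out
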