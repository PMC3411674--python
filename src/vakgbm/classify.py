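"""The 3-point VAK (Volume-Age-KPS) scoring, MGMT methylation calling and VAKM grouping.

One point each for: tumor volume >= 30,000 mm^3 (or mean lesion diameter >= 40 mm),
age >= 60 years, and KPS < 100. Patients with 0-1 points are VAK-A (good
prognosis), 2-3 points VAK-B (poor prognosis). MGMT status is called by a
median cutoff on the per-patient mean promoter-probe beta-value; crossing it
with the VAK class yields the four VAKM groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClassificationError
from .io import ClinicalCohort, ClinicalRecord

VAK_A = "VAK-A"
VAK_B = "VAK-B"

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class VakCutoffs:
    """Dichotomization cutoffs; defaults are the discovery-cohort medians."""

    volume_cutoff_mm3: float = 30_000.0
    diameter_cutoff_mm: float = 40.0
    age_cutoff_years: float = 60.0
    kps_cutoff: int = 100

    def __post_init__(self) -> None:
        if min(self.volume_cutoff_mm3, self.diameter_cutoff_mm, self.age_cutoff_years) <= 0:
            raise ValueError("all cutoffs must be positive")
        if not 0 < self.kps_cutoff <= 100:
            raise ValueError("kps_cutoff must be in (0, 100]")


@dataclass
class VakResult:
    patient_id: str
    size_point: int
    age_point: int
    kps_point: int
    total_points: int
    vak_class: str
    mgmt_status: str = UNKNOWN
    vakm_group: str = UNKNOWN


def size_criterion(
    volume_mm3: float | None,
    diameter_mm: float | None,
    cutoffs: VakCutoffs = VakCutoffs(),
) -> int:
    """1 point iff volume >= volume cutoff OR diameter >= diameter cutoff.

    A missing measure never qualifies; both missing is a classification error.
    """
    if volume_mm3 is None and diameter_mm is None:
        raise ClassificationError("both volume and diameter missing; size criterion undefined")
    if volume_mm3 is not None and volume_mm3 >= cutoffs.volume_cutoff_mm3:
        return 1
    if diameter_mm is not None and diameter_mm >= cutoffs.diameter_cutoff_mm:
        return 1
    return 0


def vak_class(total_points: int) -> str:
    """VAK-A for 0-1 points, VAK-B for 2-3."""
    if total_points not in (0, 1, 2, 3):
        raise ClassificationError(f"total_points must be in 0..3, got {total_points}")
    return VAK_A if total_points <= 1 else VAK_B


def vak_points(record: ClinicalRecord, cutoffs: VakCutoffs = VakCutoffs()) -> VakResult:
    """Score one patient: size, age and KPS points, their total, and the class."""
    if record.age_years is None:
        raise ClassificationError(f"{record.patient_id}: age missing")
    if record.kps is None:
        raise ClassificationError(f"{record.patient_id}: KPS missing")
    size_pt = size_criterion(record.volume_mm3, record.diameter_mm, cutoffs)
    age_pt = int(record.age_years >= cutoffs.age_cutoff_years)
    kps_pt = int(record.kps < cutoffs.kps_cutoff)
    total = size_pt + age_pt + kps_pt
    return VakResult(
        patient_id=record.patient_id,
        size_point=size_pt,
        age_point=age_pt,
        kps_point=kps_pt,
        total_points=total,
        vak_class=vak_class(total),
    )


def cohort_beta_median(cohort: ClinicalCohort) -> float | None:
    """Median of per-patient averaged beta-values, over patients with betas."""
    means = [r.mean_beta for r in cohort if r.mean_beta is not None]
    if not means:
        return None
    return float(np.median(means))


def mgmt_status(betas: list[float] | None, cohort_median: float | None) -> str:
    """Methylated iff the mean probe beta exceeds the cohort median.

    A beta exactly at the median is called unmethylated (the cutoff is strictly
    "above median"), keeping the split deterministic and at most half methylated.
    Missing betas give status ``unknown`` rather than an error.
    """
    if not betas or cohort_median is None:
        return UNKNOWN
    return METHYLATED if float(np.mean(betas)) > cohort_median else UNMETHYLATED


def vakm_group(vak_cls: str, mgmt: str) -> str:
    """Cross VAK class with MGMT methylation: VAK-A+M / VAK-A-M / VAK-B+M / VAK-B-M."""
    if vak_cls not in (VAK_A, VAK_B):
        raise ClassificationError(f"unknown VAK class '{vak_cls}'")
    if mgmt == METHYLATED:
        return f"{vak_cls}+M"
    if mgmt == UNMETHYLATED:
        return f"{vak_cls}-M"
    return UNKNOWN


def classify_cohort(
    cohort: ClinicalCohort, cutoffs: VakCutoffs = VakCutoffs()
) -> pd.DataFrame:
    """VAK-score a whole cohort, calling MGMT against the cohort beta median.

    Returns one row per patient: points, class, MGMT status and VAKM group.
    """
    median = cohort_beta_median(cohort)
    rows = []
    for rec in cohort:
        res = vak_points(rec, cutoffs)
        res.mgmt_status = mgmt_status(rec.mgmt_betas, median)
        res.vakm_group = vakm_group(res.vak_class, res.mgmt_status)
        rows.append(vars(res))
    return pd.DataFrame(rows)
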