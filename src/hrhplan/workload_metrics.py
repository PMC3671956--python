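"""Workload ratios, baseline skilled-attendance coverage, and salary checks.

Workload is expressed as annual events (facility deliveries or total
births) per staff-year, with either doctors or the full skilled cadre
(doctors + clinical officers + nurses) as denominator.  Baseline coverage —
the fraction of births attended in a facility by a skilled worker — is the
ratio of the two per-100,000 rates and is the starting point of the
scale-up projection.

Salary records (monthly US$ and the salary:GDP-per-capita ratio) admit a
consistency check: every cadre's pair implies the same annual GDP per
capita, ``12 * salary / ratio``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .regional_data import ReconciledRegion, SchemaError


class WorkloadError(ValueError):
    pass


class UndefinedCoverageError(WorkloadError):
    """Coverage is undefined because the birth rate is zero."""


@dataclass(frozen=True)
class WorkloadSummary:
    """Per-region workload ratios and baseline coverage.

    Ratios are ``nan`` where the denominator cadre has no staff (mirrors the
    "-" cells of the source table).
    """

    region: str
    deliveries_per_skilled_worker: float
    deliveries_per_doctor: float
    births_per_skilled_worker: float
    births_per_doctor: float
    baseline_coverage: float


@dataclass(frozen=True)
class SalaryRecord:
    cadre: str
    monthly_salary: float
    ratio_to_gdp: float

    def __post_init__(self) -> None:
        if self.monthly_salary <= 0:
            raise WorkloadError(f"{self.cadre}: monthly salary must be positive")
        if self.ratio_to_gdp <= 0:
            raise WorkloadError(f"{self.cadre}: salary:GDP ratio must be positive")


def workload_per_staff(region: ReconciledRegion, cadre: str, event: str) -> float:
    """Annual events per staff-year for one cadre.

    ``cadre`` is ``"doctor"`` or ``"skilled"`` (doctors + clinical officers
    + nurses); ``event`` is ``"deliveries"`` or ``"births"``.  A region with
    zero staff in the cadre yields ``nan`` — an undefined workload, flagged
    rather than raised, matching the dashes of the source table.
    """
    if cadre == "doctor":
        staff = region.region.doctors
    elif cadre == "skilled":
        staff = region.region.skilled_total
    else:
        raise WorkloadError(f"unknown cadre {cadre!r}; expected 'doctor' or 'skilled'")
    if event == "deliveries":
        volume = region.deliveries
    elif event == "births":
        volume = region.births
    else:
        raise WorkloadError(f"unknown event {event!r}; expected 'deliveries' or 'births'")
    if staff == 0:
        return math.nan
    return volume / staff


def baseline_coverage(region: ReconciledRegion) -> float:
    """Fraction of births delivered in a facility with a skilled worker.

    Computed as deliveries-per-100k over births-per-100k and clamped to
    [0, 1] for reporting (rates are measured with error, so the ratio can
    nominally exceed 1).
    """
    births_rate = region.region.births_per_100k
    deliveries_rate = region.region.deliveries_per_100k
    if births_rate is None or deliveries_rate is None:
        raise UndefinedCoverageError(f"{region.name}: workload rates not attached")
    if births_rate == 0:
        raise UndefinedCoverageError(f"{region.name}: zero birth rate")
    return min(1.0, max(0.0, deliveries_rate / births_rate))


def summarize_workload(region: ReconciledRegion) -> WorkloadSummary:
    return WorkloadSummary(
        region=region.name,
        deliveries_per_skilled_worker=workload_per_staff(region, "skilled", "deliveries"),
        deliveries_per_doctor=workload_per_staff(region, "doctor", "deliveries"),
        births_per_skilled_worker=workload_per_staff(region, "skilled", "births"),
        births_per_doctor=workload_per_staff(region, "doctor", "births"),
        baseline_coverage=baseline_coverage(region),
    )


def workload_frame(regions: Iterable[ReconciledRegion]) -> pd.DataFrame:
    """Workload table mirroring the source column order (deliveries then births)."""
    rows = [summarize_workload(r) for r in regions]
    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "deliveries_per_100k": [g.region.deliveries_per_100k for g in regions],
            "deliveries_per_skilled_worker": [r.deliveries_per_skilled_worker for r in rows],
            "deliveries_per_doctor": [r.deliveries_per_doctor for r in rows],
            "births_per_100k": [g.region.births_per_100k for g in regions],
            "births_per_skilled_worker": [r.births_per_skilled_worker for r in rows],
            "births_per_doctor": [r.births_per_doctor for r in rows],
        }
    )


def coverage_frame(regions: Iterable[ReconciledRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.name for r in regions],
            "baseline_coverage": [baseline_coverage(r) for r in regions],
        }
    )


def implied_gdp_per_capita(salary: float, ratio: float) -> float:
    """Annual GDP per capita implied by a monthly salary and a salary:GDP ratio."""
    if ratio <= 0:
        raise WorkloadError(f"salary:GDP ratio must be positive, got {ratio}")
    return 12.0 * salary / ratio


def load_salary_table(path: str | Path) -> list[SalaryRecord]:
    frame = pd.read_csv(path)
    required = ["cadre", "monthly_salary_usd", "ratio_to_gdp_per_capita"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [
        SalaryRecord(
            cadre=str(row["cadre"]),
            monthly_salary=float(row["monthly_salary_usd"]),
            ratio_to_gdp=float(row["ratio_to_gdp_per_capita"]),
        )
        for _, row in frame.iterrows()
    ]


def gdp_consistency(records: Sequence[SalaryRecord]) -> tuple[float, float]:
    """(mean implied GDP per capita, max relative spread) across cadres."""
    implied = [implied_gdp_per_capita(r.monthly_salary, r.ratio_to_gdp) for r in records]
    mean = sum(implied) / len(implied)
    spread = max(abs(v - mean) / mean for v in implied)
    return mean, spread
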