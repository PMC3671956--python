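"""Coverage scale-up simulator: staffing requirements, attrition, hiring, cost.

The model is quantity driven, in the tradition of the WHO Making Pregnancy
Safer staffing projector.  The staff required to attend a given number of
births at a given coverage is

    requirement = births * coverage / norm

with fixed norms of deliveries one worker can attend per year (175 for a
skilled birth attendant, 1,000 for a doctor, who is needed for the
complicated fraction of deliveries).  Each simulated year the staff stock
loses a fixed attrition fraction; hires then top the stock back up to the
requirement if — and only if — it has fallen below.  Salaries compound at a
fixed growth rate from base-year levels, and annual cost is stock times
salary.

Two coverage paths are provided.  The default "step" path raises the
requirement to the target-coverage level from the base year onward, so
base-year hires close the initial gap at once and later hires only replace
attrition.  The "linear" alternative ramps coverage evenly from the
baseline to the target across the horizon.

Integer headlines (requirements, cumulative gaps) are reported with floor;
internally stocks and hires stay real-valued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regional_data import ReconciledRegion
from .workload_metrics import baseline_coverage


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class StaffingNorms:
    """Annual deliveries one staff member can cover."""

    deliveries_per_sba: float = 175.0
    deliveries_per_doctor: float = 1000.0

    def __post_init__(self) -> None:
        if self.deliveries_per_sba <= 0 or self.deliveries_per_doctor <= 0:
            raise ProjectionError("staffing norms must be positive")
        if self.deliveries_per_doctor <= self.deliveries_per_sba:
            raise ProjectionError(
                "a doctor must cover more deliveries per year than an SBA"
            )

    def for_cadre(self, cadre: str) -> float:
        if cadre == "sba":
            return self.deliveries_per_sba
        if cadre == "doctor":
            return self.deliveries_per_doctor
        raise ProjectionError(f"unknown cadre {cadre!r}; expected 'sba' or 'doctor'")


@dataclass(frozen=True)
class ProjectionAssumptions:
    base_year: int = 2010
    target_year: int = 2015
    target_coverage: float = 0.95
    attrition: float = 0.10
    salary_growth: float = 0.03
    sba_salary: float = 2112.0
    doctor_salary: float = 2616.0
    births_growth: float = 0.0
    coverage_path: str = "step"

    def __post_init__(self) -> None:
        if self.base_year >= self.target_year:
            raise ProjectionError("base_year must precede target_year")
        if not 0.0 <= self.attrition < 1.0:
            raise ProjectionError("attrition must lie in [0, 1)")
        if not 0.0 < self.target_coverage <= 1.0:
            raise ProjectionError("target_coverage must lie in (0, 1]")
        if self.sba_salary <= 0 or self.doctor_salary <= 0:
            raise ProjectionError("salaries must be positive")
        if self.coverage_path not in ("step", "linear"):
            raise ProjectionError("coverage_path must be 'step' or 'linear'")

    @property
    def years(self) -> range:
        return range(self.base_year, self.target_year + 1)

    def salary_for(self, cadre: str) -> float:
        if cadre == "sba":
            return self.sba_salary
        if cadre == "doctor":
            return self.doctor_salary
        raise ProjectionError(f"unknown cadre {cadre!r}")


@dataclass(frozen=True)
class ProjectionTrajectory:
    """Year-by-year requirement, stock, hires and (optionally) cost for a cadre."""

    cadre: str
    years: tuple[int, ...]
    requirement: tuple[float, ...]
    stock: tuple[float, ...]
    hires: tuple[float, ...]
    salary: tuple[float, ...] = ()
    cost: tuple[float, ...] = ()

    @property
    def cumulative_hires(self) -> float:
        return sum(self.hires)

    def frame(self) -> pd.DataFrame:
        data = {
            "year": self.years,
            "requirement": self.requirement,
            "stock": self.stock,
            "hires": self.hires,
        }
        if self.salary:
            data["salary"] = self.salary
            data["cost"] = self.cost
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GapReport:
    """Per-region current need, target need, and cumulative additional staff."""

    cadre: str
    regions: tuple[str, ...]
    current_staff: tuple[int, ...]
    current_need: tuple[int, ...]
    need_at_target: tuple[int, ...]
    cumulative_additional: tuple[int, ...]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.regions,
                "current_staff": self.current_staff,
                "current_need": self.current_need,
                "need_at_target": self.need_at_target,
                "cumulative_additional": self.cumulative_additional,
            }
        )

    def total_excluding(self, excluded: Iterable[str]) -> int:
        skip = set(excluded)
        return sum(
            gap
            for name, gap in zip(self.regions, self.cumulative_additional)
            if name not in skip
        )


def required_staff(births: float, coverage: float, norm: float) -> float:
    """Real-valued staff requirement ``births * coverage / norm``.

    Headline integer reporting floors this value (a fraction of a post
    cannot deliver).
    """
    if norm <= 0:
        raise ProjectionError(f"norm must be positive, got {norm}")
    if births < 0:
        raise ProjectionError("births must be non-negative")
    if not 0.0 <= coverage <= 1.0:
        raise ProjectionError("coverage must lie in [0, 1]")
    return births * coverage / norm


def requirement_path(
    births: float,
    baseline: float,
    assumptions: ProjectionAssumptions,
    norm: float,
) -> dict[int, float]:
    """Requirement per year from base to target.

    Under the "step" path coverage sits at the target from the base year.
    Under "linear" it ramps evenly from the baseline coverage to the target.
    Births grow at ``births_growth`` per year from the base-year level.
    """
    years = assumptions.years
    span = assumptions.target_year - assumptions.base_year
    path: dict[int, float] = {}
    for year in years:
        t = year - assumptions.base_year
        births_t = births * (1.0 + assumptions.births_growth) ** t
        if assumptions.coverage_path == "step":
            cov = assumptions.target_coverage
        else:
            cov = baseline + (assumptions.target_coverage - baseline) * t / span
        path[year] = required_staff(births_t, cov, norm)
    return path


def simulate_trajectory(
    stock0: float,
    req_path: Mapping[int, float],
    assumptions: ProjectionAssumptions,
    cadre: str = "sba",
) -> ProjectionTrajectory:
    """Run the attrition/replacement stock-flow simulation.

    Base year: hires close any gap between the initial stock and the
    base-year requirement.  Every later year the stock first decays by the
    attrition fraction, then hires restore it to the requirement if it fell
    below (stock-flow identity ``stock_t = stock_{t-1} * (1 - attrition) +
    hires_t``).  Salaries and costs are attached for the cadre.
    """
    if stock0 < 0:
        raise ProjectionError("initial stock must be non-negative")
    years = list(assumptions.years)
    missing = [y for y in years if y not in req_path]
    if missing:
        raise ProjectionError(f"requirement path missing years {missing}")
    if any(req_path[y] < 0 for y in years):
        raise ProjectionError("requirements must be non-negative")
    salary0 = assumptions.salary_for(cadre)
    stock = stock0
    stocks, hires_seq, salaries, costs, reqs = [], [], [], [], []
    for year in years:
        req = req_path[year]
        if year > assumptions.base_year:
            stock *= 1.0 - assumptions.attrition
        hires = max(0.0, req - stock)
        stock += hires
        salary = salary0 * (1.0 + assumptions.salary_growth) ** (year - assumptions.base_year)
        stocks.append(stock)
        hires_seq.append(hires)
        salaries.append(salary)
        costs.append(stock * salary)
        reqs.append(req)
    return ProjectionTrajectory(
        cadre=cadre,
        years=tuple(years),
        requirement=tuple(reqs),
        stock=tuple(stocks),
        hires=tuple(hires_seq),
        salary=tuple(salaries),
        cost=tuple(costs),
    )


def national_projection(
    national: ReconciledRegion,
    assumptions: ProjectionAssumptions,
    norms: StaffingNorms,
) -> dict[str, ProjectionTrajectory]:
    """Project both cadres at national aggregation.

    The SBA stock is the nurse head-count (clinical officers are excluded
    from both cadres); the doctor stock is the doctor head-count.
    """
    baseline = baseline_coverage(national)
    stocks = {"sba": national.region.nurses, "doctor": national.region.doctors}
    out = {}
    for cadre in ("sba", "doctor"):
        path = requirement_path(
            national.births, baseline, assumptions, norms.for_cadre(cadre)
        )
        out[cadre] = simulate_trajectory(stocks[cadre], path, assumptions, cadre)
    return out


def cost_trajectory(
    trajectories: Mapping[str, ProjectionTrajectory],
    assumptions: ProjectionAssumptions,
) -> pd.DataFrame:
    """Total annual workforce cost (US$) summed over cadres.

    Returns a frame with one row per year and a ``cost_usd_millions``
    column truncated to one decimal, the convention used for headline
    figures.
    """
    for cadre in ("sba", "doctor"):
        if cadre not in trajectories:
            raise ProjectionError(f"missing trajectory for cadre {cadre!r}")
    years = list(assumptions.years)
    total = []
    for i, year in enumerate(years):
        cost = 0.0
        for traj in trajectories.values():
            if traj.years[i] != year:
                raise ProjectionError("trajectory years misaligned")
            cost += traj.cost[i]
        total.append(cost)
    return pd.DataFrame(
        {
            "year": years,
            "cost_usd": total,
            "cost_usd_millions": [usd_millions(c) for c in total],
        }
    )


def usd_millions(cost_usd: float) -> float:
    """Cost in US$ millions truncated to one decimal (37,774,008 -> 37.7)."""
    return math.floor(cost_usd / 1e5) / 10.0


def gap_report(
    regions: Sequence[ReconciledRegion],
    assumptions: ProjectionAssumptions,
    norms: StaffingNorms,
    cadre: str = "doctor",
) -> GapReport:
    """Per-region cumulative additional staff needed over the horizon.

    Each region runs its own step (or linear) requirement path and
    attrition/replacement simulation; ``cumulative_additional`` is total
    hires, floored.  ``current_need`` is the staff needed for today's
    facility deliveries at the norm, also floored.
    """
    names, current, need_now, need_target, cumulative = [], [], [], [], []
    norm = norms.for_cadre(cadre)
    for region in regions:
        stock0 = (
            region.region.doctors if cadre == "doctor" else region.region.nurses
        )
        baseline = baseline_coverage(region)
        path = requirement_path(region.births, baseline, assumptions, norm)
        traj = simulate_trajectory(stock0, path, assumptions, cadre)
        names.append(region.name)
        current.append(stock0)
        need_now.append(math.floor(region.deliveries / norm))
        need_target.append(
            math.floor(required_staff(region.births, assumptions.target_coverage, norm))
        )
        cumulative.append(math.floor(traj.cumulative_hires))
    return GapReport(
        cadre=cadre,
        regions=tuple(names),
        current_staff=tuple(current),
        current_need=tuple(need_now),
        need_at_target=tuple(need_target),
        cumulative_additional=tuple(cumulative),
    )
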