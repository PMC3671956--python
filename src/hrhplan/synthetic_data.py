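"""Synthetic regional panels with the structure the analysis assumes.

The generator emulates a country split into a small number of regions: a
right-skewed population distribution, one or two dense "metropolitan"
regions, staff allocated across regions with a tunable pro-urban bias, and
per-region birth and facility-delivery rates.  Staff counts for each cadre
are drawn from a multinomial with probabilities proportional to

    population * density ** urban_bias

so ``urban_bias = 0`` gives allocation proportional to population (zero
concentration index in expectation) and larger values concentrate staff in
denser regions.  Per-100,000 rates are computed exactly from the drawn
counts and populations, so generated fixtures reconcile with zero
discrepancy and the drawn coverage is recoverable to machine precision.

Defaults mirror the 2010 Zimbabwe panel: 10 regions, cadre totals 689
doctors / 35 clinical officers / 17,032 nurses, and a crude birth rate of
30.7 per 1,000 (the national 3,074 births per 100,000).

``generate_projection_scenario`` additionally produces a known-answer sheet
for the scale-up simulation computed by a deliberately naive year-by-year
loop, kept separate from the projection engine so it can serve as an
independent oracle in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regional_data import RATE_SCALE, RegionRecord
from .workforce_projection import ProjectionAssumptions, StaffingNorms


class SyntheticError(ValueError):
    pass


DEFAULT_CADRE_TOTALS = {"doctors": 689, "clinical_officers": 35, "nurses": 17032}


@dataclass(frozen=True)
class SyntheticScenario:
    n_regions: int = 10
    seed: int = 0
    urban_bias: float = 1.0
    crude_birth_rate: float = 30.7  # births per 1,000 population per year
    baseline_coverage_range: tuple[float, float] = (0.55, 0.90)
    population_dispersion: float = 0.5  # sigma of log-normal population draw
    cadre_totals: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CADRE_TOTALS)
    )

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise SyntheticError("need at least two regions")
        if self.urban_bias < 0:
            raise SyntheticError("urban_bias must be non-negative")
        if self.crude_birth_rate <= 0:
            raise SyntheticError("crude birth rate must be positive")
        lo, hi = self.baseline_coverage_range
        if not 0.0 < lo <= hi <= 1.0:
            raise SyntheticError("coverage range must satisfy 0 < lo <= hi <= 1")
        if self.population_dispersion < 0:
            raise SyntheticError("population dispersion must be non-negative")
        for cadre, total in self.cadre_totals.items():
            if total < 0:
                raise SyntheticError(f"negative total for {cadre}")
        # one nurse is forced into every region so each has a usable
        # count/rate pair; fewer nurses than regions is infeasible
        if self.cadre_totals.get("nurses", 0) < self.n_regions:
            raise SyntheticError("need at least one nurse per region")


@dataclass(frozen=True)
class SyntheticPanel:
    records: list[RegionRecord]
    densities: dict[str, float]
    areas: dict[str, float]
    coverage: dict[str, float]


def generate_regions(scenario: SyntheticScenario) -> SyntheticPanel:
    """Draw a synthetic panel of regions (reproducible from the seed)."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_regions
    names = [f"Region {chr(ord('A') + i)}" if n <= 26 else f"Region {i:03d}"
             for i in range(n)]

    pops = rng.lognormal(mean=math.log(1e6), sigma=scenario.population_dispersion, size=n)
    # 1-2 metropolitan regions: small land area, hence high density
    n_metro = 1 if n < 6 else 2
    metro = set(np.argsort(pops)[-n_metro:])
    densities = np.empty(n)
    for i in range(n):
        if i in metro:
            densities[i] = rng.uniform(800.0, 2000.0)
        else:
            densities[i] = rng.uniform(5.0, 60.0)
    areas = pops / densities

    weights = pops * densities**scenario.urban_bias
    probs = weights / weights.sum()
    counts: dict[str, np.ndarray] = {}
    for cadre, total in scenario.cadre_totals.items():
        reserved = np.zeros(n, dtype=int)
        remaining = total
        if cadre == "nurses":  # one nurse everywhere keeps every region reconcilable
            reserved += 1
            remaining -= n
        counts[cadre] = reserved + rng.multinomial(remaining, probs)

    lo, hi = scenario.baseline_coverage_range
    coverage = rng.uniform(lo, hi, size=n)
    births = pops * scenario.crude_birth_rate / 1000.0
    deliveries = births * coverage

    records = []
    for i, name in enumerate(names):
        doctors = int(counts.get("doctors", np.zeros(n, int))[i])
        officers = int(counts.get("clinical_officers", np.zeros(n, int))[i])
        nurses = int(counts["nurses"][i])
        skilled = doctors + officers + nurses

        def rate(c: int) -> float | None:
            return c / pops[i] * RATE_SCALE if c > 0 else None

        records.append(
            RegionRecord(
                name=name,
                doctors=doctors,
                clinical_officers=officers,
                nurses=nurses,
                skilled_total=skilled,
                doctors_per_100k=rate(doctors),
                clinical_officers_per_100k=rate(officers),
                nurses_per_100k=rate(nurses),
                skilled_per_100k=rate(skilled),
                deliveries_per_100k=deliveries[i] / pops[i] * RATE_SCALE,
                births_per_100k=births[i] / pops[i] * RATE_SCALE,
                land_area_km2=float(areas[i]),
            )
        )
    return SyntheticPanel(
        records=records,
        densities={name: float(densities[i]) for i, name in enumerate(names)},
        areas={name: float(areas[i]) for i, name in enumerate(names)},
        coverage={name: float(coverage[i]) for i, name in enumerate(names)},
    )


def _fmt(value: float | None) -> str:
    return "-" if value is None else repr(float(value))


def write_fixture_csvs(panel: SyntheticPanel, outdir: str | Path) -> dict[str, Path]:
    """Emit the same CSV schemas the loaders consume (full float precision).

    Rates are written with ``repr`` so that reconciliation recovers the
    generated populations exactly; identical panels produce byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    staff_path = outdir / "table3_staff.csv"
    totals = {
        "doctors": sum(r.doctors for r in panel.records),
        "clinical_officers": sum(r.clinical_officers for r in panel.records),
        "nurses": sum(r.nurses for r in panel.records),
        "skilled": sum(r.skilled_total for r in panel.records),
    }
    total_pop = sum(
        r.nurses / r.nurses_per_100k * RATE_SCALE for r in panel.records
    )
    with staff_path.open("w", newline="") as fh:
        fh.write(
            "region,doctors,doctors_per_100k,clinical_officers,co_per_100k,"
            "nurses,nurses_per_100k,skilled,skilled_per_100k\n"
        )
        for r in panel.records:
            fh.write(
                f"{r.name},{r.doctors},{_fmt(r.doctors_per_100k)},"
                f"{r.clinical_officers},{_fmt(r.clinical_officers_per_100k)},"
                f"{r.nurses},{_fmt(r.nurses_per_100k)},"
                f"{r.skilled_total},{_fmt(r.skilled_per_100k)}\n"
            )
        def total_rate(cadre: str) -> float | None:
            return totals[cadre] / total_pop * RATE_SCALE if totals[cadre] else None

        fh.write(
            f"TOTAL,{totals['doctors']},{_fmt(total_rate('doctors'))},"
            f"{totals['clinical_officers']},{_fmt(total_rate('clinical_officers'))},"
            f"{totals['nurses']},{_fmt(total_rate('nurses'))},"
            f"{totals['skilled']},{_fmt(total_rate('skilled'))}\n"
        )
    workload_path = outdir / "table6_workload.csv"
    with workload_path.open("w", newline="") as fh:
        fh.write("region,deliveries_per_100k,births_per_100k\n")
        total_births = total_deliv = 0.0
        for r in panel.records:
            pop = r.nurses / r.nurses_per_100k * RATE_SCALE
            total_births += r.births_per_100k * pop / RATE_SCALE
            total_deliv += r.deliveries_per_100k * pop / RATE_SCALE
            fh.write(f"{r.name},{_fmt(r.deliveries_per_100k)},{_fmt(r.births_per_100k)}\n")
        fh.write(
            f"TOTAL,{_fmt(total_deliv / total_pop * RATE_SCALE)},"
            f"{_fmt(total_births / total_pop * RATE_SCALE)}\n"
        )
    areas_path = outdir / "region_areas.csv"
    with areas_path.open("w", newline="") as fh:
        fh.write("region,land_area_km2\n")
        for r in panel.records:
            fh.write(f"{r.name},{_fmt(r.land_area_km2)}\n")
    return {"staff": staff_path, "workload": workload_path, "areas": areas_path}


def reference_projection(
    stock0: float,
    births: float,
    baseline_coverage: float,
    assumptions: ProjectionAssumptions,
    norm: float,
) -> dict[str, list[float]]:
    """Straight-line, loop-by-loop scale-up oracle (independent of the engine).

    Recomputes requirement, stock, hires and cumulative hires one year at a
    time with explicit arithmetic.  Intentionally naive; used to verify the
    projection engine on generated scenarios.
    """
    years = []
    reqs = []
    stocks = []
    hires_list = []
    cumulative = 0.0
    stock = stock0
    horizon = assumptions.target_year - assumptions.base_year
    year = assumptions.base_year
    while year <= assumptions.target_year:
        elapsed = year - assumptions.base_year
        births_now = births
        for _ in range(elapsed):
            births_now = births_now * (1.0 + assumptions.births_growth)
        if assumptions.coverage_path == "step":
            cov = assumptions.target_coverage
        else:
            cov = (
                baseline_coverage
                + (assumptions.target_coverage - baseline_coverage) * elapsed / horizon
            )
        req = births_now * cov / norm
        if year != assumptions.base_year:
            stock = stock - stock * assumptions.attrition
        if stock < req:
            hired = req - stock
        else:
            hired = 0.0
        stock = stock + hired
        cumulative = cumulative + hired
        years.append(year)
        reqs.append(req)
        stocks.append(stock)
        hires_list.append(hired)
        year = year + 1
    return {
        "year": years,
        "requirement": reqs,
        "stock": stocks,
        "hires": hires_list,
        "cumulative_hires": [cumulative],
    }


def generate_projection_scenario(
    scenario: SyntheticScenario,
    assumptions: ProjectionAssumptions,
    norms: StaffingNorms | None = None,
    outdir: str | Path | None = None,
) -> tuple[SyntheticPanel, pd.DataFrame]:
    """Panel plus a per-region known-answer sheet for the doctor projection."""
    norms = norms or StaffingNorms()
    panel = generate_regions(scenario)
    rows = []
    for record in panel.records:
        pop = record.nurses / record.nurses_per_100k * RATE_SCALE
        births = record.births_per_100k * pop / RATE_SCALE
        cov = record.deliveries_per_100k / record.births_per_100k
        ref = reference_projection(
            record.doctors, births, cov, assumptions, norms.deliveries_per_doctor
        )
        rows.append(
            {
                "region": record.name,
                "births": births,
                "baseline_coverage": cov,
                "final_stock": ref["stock"][-1],
                "cumulative_hires": ref["cumulative_hires"][0],
            }
        )
    sheet = pd.DataFrame(rows)
    if outdir is not None:
        write_fixture_csvs(panel, outdir)
        sheet.to_csv(Path(outdir) / "answer_sheet.csv", index=False)
    return panel, sheet
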