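"""Load regional staffing tables and reconstruct populations and birth volumes.

The public workforce returns report, for each region, the head-count of
doctors, clinical officers and nurses together with the corresponding
density per 100,000 population, but not the population itself.  Each
count/rate pair therefore implies a population estimate

    population = count / rate * 100,000

and the pairs of one region should agree up to the rounding of the printed
rate.  ``reconcile_region`` combines them into a consensus estimate by
inverse-variance weighting: a rate printed with half-ULP ``h`` (0.005 for
two-decimal tables) carries a relative rounding error of about ``h / rate``,
so pairs are weighted by ``rate**2``.  Low head-count cadres (whose rates are
printed with very coarse relative precision) are thereby kept in the data
without letting their rounding noise distort the consensus.

Annual births and facility deliveries are filled in from the per-100,000
workload rates of the companion table.  A row named ``TOTAL`` is the
national aggregate; it is parsed and reconciled like a region but kept out
of the regional list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RATE_SCALE = 100_000.0
#: Half of the resolution at which per-100k rates are printed (two decimals).
DEFAULT_RATE_HALF_ULP = 0.005
#: Relative disagreement between implied populations tolerated beyond the
#: rounding allowance of each pair.
DEFAULT_TOLERANCE = 0.01

TOTAL_NAME = "TOTAL"

_CADRES = ("doctors", "clinical_officers", "nurses", "skilled")

_TABLE3_COLUMNS = [
    "region",
    "doctors", "doctors_per_100k",
    "clinical_officers", "co_per_100k",
    "nurses", "nurses_per_100k",
    "skilled", "skilled_per_100k",
]


class RegionalDataError(ValueError):
    """Base class for errors raised while loading or reconciling tables."""


class InvalidRateError(RegionalDataError):
    """A staff density rate is zero or negative where a positive one is required."""


class InconsistencyError(RegionalDataError):
    """A positive staff count is paired with a zero rate (or similar impossibility)."""


class SchemaError(RegionalDataError):
    """An input table lacks required columns or is empty."""


class ReconciliationError(RegionalDataError):
    """The populations implied by a region's count/rate pairs disagree."""


@dataclass(frozen=True)
class RegionRecord:
    """One region's staffing counts and per-100,000 rates.

    Rates are ``None`` when the source table prints "-" (no staff of that
    cadre, hence no defined density).  ``deliveries_per_100k`` and
    ``births_per_100k`` come from the workload table and may be ``None``
    until attached.
    """

    name: str
    doctors: int
    clinical_officers: int
    nurses: int
    skilled_total: int
    doctors_per_100k: float | None = None
    clinical_officers_per_100k: float | None = None
    nurses_per_100k: float | None = None
    skilled_per_100k: float | None = None
    deliveries_per_100k: float | None = None
    births_per_100k: float | None = None
    land_area_km2: float | None = None

    def __post_init__(self) -> None:
        for cadre in ("doctors", "clinical_officers", "nurses", "skilled_total"):
            if getattr(self, cadre) < 0:
                raise RegionalDataError(f"{self.name}: negative count for {cadre}")
        expected = self.doctors + self.clinical_officers + self.nurses
        if self.skilled_total != expected:
            warnings.warn(
                f"{self.name}: skilled total {self.skilled_total} != "
                f"doctors+clinical officers+nurses = {expected}",
                stacklevel=2,
            )
        if (
            self.deliveries_per_100k is not None
            and self.births_per_100k is not None
            and self.births_per_100k < self.deliveries_per_100k
        ):
            raise RegionalDataError(
                f"{self.name}: births/100k below deliveries/100k"
            )

    def count_rate_pairs(self) -> list[tuple[str, int, float]]:
        """(cadre, count, rate) for every cadre with a positive count and rate."""
        pairs = []
        for cadre, rate in (
            ("doctors", self.doctors_per_100k),
            ("clinical_officers", self.clinical_officers_per_100k),
            ("nurses", self.nurses_per_100k),
            ("skilled", self.skilled_per_100k),
        ):
            count = self.skilled_total if cadre == "skilled" else getattr(self, cadre)
            if count > 0 and rate is not None and rate > 0:
                pairs.append((cadre, count, rate))
            elif count > 0 and rate is not None and rate <= 0:
                raise InconsistencyError(
                    f"{self.name}: {cadre} count {count} with non-positive rate {rate}"
                )
        return pairs


@dataclass(frozen=True)
class ReconciledRegion:
    """A region with its consensus population and annual event volumes."""

    region: RegionRecord
    population: float
    deliveries: float
    births: float
    max_discrepancy: float

    @property
    def name(self) -> str:
        return self.region.name


def derive_population(count: float, rate: float) -> float:
    """Invert a staff density: ``population = count / rate * 100,000``.

    ``rate`` is staff per 100,000 population.  A zero rate alongside a
    positive count is an inconsistency (staff exist but density says none);
    any other non-positive rate is simply invalid.
    """
    if rate <= 0:
        if count > 0 and rate == 0:
            raise InconsistencyError(
                f"count {count} with rate 0: staff present but zero density"
            )
        raise InvalidRateError(f"rate must be positive, got {rate}")
    if count < 0:
        raise RegionalDataError(f"count must be non-negative, got {count}")
    return count / rate * RATE_SCALE


def reconcile_region(
    record: RegionRecord,
    tolerance: float = DEFAULT_TOLERANCE,
    rate_half_ulp: float = DEFAULT_RATE_HALF_ULP,
) -> ReconciledRegion:
    """Combine a region's count/rate pairs into a consensus population.

    The consensus is the inverse-variance weighted mean of the implied
    populations (weights ``rate**2``, see module docstring).  Each pair is
    then checked against the consensus: a relative deviation larger than
    ``tolerance`` plus the pair's own rounding allowance (``rate_half_ulp /
    rate``) raises :class:`ReconciliationError`.  ``max_discrepancy`` is the
    largest relative deviation observed, recorded for every region.
    """
    pairs = record.count_rate_pairs()
    if not pairs:
        raise ReconciliationError(
            f"{record.name}: no cadre has both a positive count and a positive rate"
        )
    implied = np.array([derive_population(c, r) for _, c, r in pairs])
    weights = np.array([r * r for _, _, r in pairs])
    population = float(np.average(implied, weights=weights))
    deviations = np.abs(implied - population) / population
    max_discrepancy = float(deviations.max())
    for (cadre, _, rate), dev in zip(pairs, deviations):
        allowance = tolerance + rate_half_ulp / rate
        if dev > allowance:
            raise ReconciliationError(
                f"{record.name}: population implied by {cadre} deviates "
                f"{dev:.2%} from consensus (allowance {allowance:.2%})"
            )
    deliveries = births = float("nan")
    if record.deliveries_per_100k is not None:
        deliveries = record.deliveries_per_100k * population / RATE_SCALE
    if record.births_per_100k is not None:
        births = record.births_per_100k * population / RATE_SCALE
    return ReconciledRegion(
        region=record,
        population=population,
        deliveries=deliveries,
        births=births,
        max_discrepancy=max_discrepancy,
    )


def _parse_cell(value: object, column: str, region: str) -> tuple[float | None, bool]:
    """Parse one cell; "-" means absent.  Returns (value, present)."""
    if isinstance(value, str):
        value = value.strip().replace(",", "")
        if value == "-" or value == "":
            return None, False
        try:
            return float(value), True
        except ValueError:
            raise SchemaError(
                f"non-numeric cell {value!r} in column {column!r}, region {region!r}"
            ) from None
    if pd.isna(value):
        return None, False
    return float(value), True


def load_region_table(path: str | Path) -> tuple[list[RegionRecord], RegionRecord]:
    """Read the staffing table; returns (regions, total_row).

    The file must have a header naming ``region`` and the cadre count/rate
    columns.  "-" cells are read as a zero count with an absent rate.  The
    row named ``TOTAL`` is returned separately and never treated as a region.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in _TABLE3_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[RegionRecord] = []
    total: RegionRecord | None = None
    for _, row in frame.iterrows():
        name = str(row["region"]).strip()
        values: dict[str, float | None] = {}
        for col in _TABLE3_COLUMNS[1:]:
            values[col], _ = _parse_cell(row[col], col, name)

        def count_of(col: str) -> int:
            v = values[col]
            return int(v) if v is not None else 0

        record = RegionRecord(
            name=name,
            doctors=count_of("doctors"),
            clinical_officers=count_of("clinical_officers"),
            nurses=count_of("nurses"),
            skilled_total=count_of("skilled"),
            doctors_per_100k=values["doctors_per_100k"],
            clinical_officers_per_100k=values["co_per_100k"],
            nurses_per_100k=values["nurses_per_100k"],
            skilled_per_100k=values["skilled_per_100k"],
        )
        if name == TOTAL_NAME:
            total = record
        else:
            records.append(record)
    if not records:
        raise SchemaError(f"{path}: no regional rows found")
    if total is None:
        raise SchemaError(f"{path}: no {TOTAL_NAME} row found")
    return records, total


def load_workload_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read the delivery/birth rate table: region -> (deliveries, births) per 100k."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    required = ["region", "deliveries_per_100k", "births_per_100k"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return {
        str(row["region"]).strip(): (
            float(row["deliveries_per_100k"]),
            float(row["births_per_100k"]),
        )
        for _, row in frame.iterrows()
    }


def load_area_table(path: str | Path) -> dict[str, float]:
    """Read region land areas (km2): region -> area."""
    frame = pd.read_csv(path)
    required = ["region", "land_area_km2"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return {
        str(row["region"]).strip(): float(row["land_area_km2"])
        for _, row in frame.iterrows()
    }


def attach_workload(
    records: Iterable[RegionRecord],
    workload: Mapping[str, tuple[float, float]],
    areas: Mapping[str, float] | None = None,
) -> list[RegionRecord]:
    """Fill delivery/birth rates (and optionally land areas) into records."""
    out = []
    for record in records:
        updates: dict[str, float] = {}
        if record.name in workload:
            deliveries, births = workload[record.name]
            updates["deliveries_per_100k"] = deliveries
            updates["births_per_100k"] = births
        if areas and record.name in areas:
            updates["land_area_km2"] = areas[record.name]
        out.append(replace(record, **updates) if updates else record)
    return out


def reconcile_all(
    records: Iterable[RegionRecord],
    tolerance: float = DEFAULT_TOLERANCE,
    rate_half_ulp: float = DEFAULT_RATE_HALF_ULP,
) -> list[ReconciledRegion]:
    return [reconcile_region(r, tolerance, rate_half_ulp) for r in records]


def packaged_fixture(name: str) -> Path:
    """Path to one of the CSV tables shipped with the package."""
    return Path(resources.files("hrhplan") / "data" / name)


def load_packaged_regions() -> tuple[list[ReconciledRegion], ReconciledRegion, dict[str, float]]:
    """Load and reconcile the packaged 2010 Zimbabwe tables.

    Returns (regions, national_total, areas).  The national total is the
    TOTAL row reconciled like a region.
    """
    records, total = load_region_table(packaged_fixture("table3_staff.csv"))
    workload = load_workload_table(packaged_fixture("table6_workload.csv"))
    areas = load_area_table(packaged_fixture("region_areas.csv"))
    records = attach_workload(records, workload, areas)
    (total,) = attach_workload([total], workload)
    return reconcile_all(records), reconcile_region(total), areas


def reconciled_frame(regions: Iterable[ReconciledRegion]) -> pd.DataFrame:
    """Tabular view of reconciled regions (population, deliveries, births)."""
    return pd.DataFrame(
        {
            "region": [r.name for r in regions],
            "population": [r.population for r in regions],
            "deliveries": [r.deliveries for r in regions],
            "births": [r.births for r in regions],
            "max_discrepancy": [r.max_discrepancy for r in regions],
        }
    )
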