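"""Concentration curves and indices for grouped regional staff allocations.

Regions are ranked by population density (ascending), the proxy for
urbanity.  The concentration curve plots cumulative staff share against
cumulative population share along that ranking; the concentration index is
twice the area between the curve and the diagonal, computed for grouped
data with the trapezoid (Fuller-type) formula

    CI = 1 - sum_i p_i * (Q_i + Q_{i-1})

where ``p_i`` is the population share of group ``i`` and ``Q_i`` the
cumulative staff share through group ``i``.  A positive index means staff
are concentrated in denser (urban) regions; an exactly proportional
allocation yields zero; the index lies in ``[-1, 1]``.

Whether an allocation differs significantly from proportionality is judged
with a delete-one-group jackknife standard error: the regions are the units
at which allocation decisions (and reporting error) operate, so resampling
them, rather than individual staff, captures the relevant uncertainty.
An allocation with |z| >= 1.96 is reported as significantly non-proportional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regional_data import ReconciledRegion

Z_CRITICAL = 1.96
_SHARE_ATOL = 1e-6


class EquityError(ValueError):
    pass


@dataclass(frozen=True)
class ConcentrationResult:
    """Concentration curve (and, once computed, index and test) for one cadre.

    ``ordering`` lists regions by ascending density; ``cum_pop_share`` and
    ``cum_staff_share`` are the curve coordinates per region (each ending at
    1).  ``pop_shares`` and ``staff_counts`` keep the underlying group data
    so the index and its jackknife standard error can be recomputed.
    """

    cadre: str
    ordering: tuple[str, ...]
    densities: tuple[float, ...]
    pop_shares: tuple[float, ...]
    staff_counts: tuple[float, ...]
    cum_pop_share: tuple[float, ...]
    cum_staff_share: tuple[float, ...]
    index: float | None = None
    std_error: float | None = None
    z: float | None = None
    significant: bool | None = None


def _staff_count(region: ReconciledRegion, cadre: str) -> float:
    record = region.region
    try:
        return {
            "doctors": record.doctors,
            "clinical_officers": record.clinical_officers,
            "nurses": record.nurses,
            "skilled": record.skilled_total,
        }[cadre]
    except KeyError:
        raise EquityError(f"unknown cadre {cadre!r}") from None


def densities_from_areas(
    regions: Sequence[ReconciledRegion],
    areas: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Population densities (persons/km2) from land areas.

    Areas are taken from the mapping if given, else from each record's
    ``land_area_km2``.  Regions lacking an area are reported together.
    """
    missing = []
    out: dict[str, float] = {}
    for region in regions:
        area = None
        if areas is not None and region.name in areas:
            area = areas[region.name]
        elif region.region.land_area_km2 is not None:
            area = region.region.land_area_km2
        if area is None or area <= 0:
            missing.append(region.name)
        else:
            out[region.name] = region.population / area
    if missing:
        raise EquityError(f"regions lacking land areas: {missing}")
    return out


def concentration_curve(
    regions: Sequence[ReconciledRegion],
    cadre: str,
    densities: Mapping[str, float],
) -> ConcentrationResult:
    """Build the concentration curve for one cadre.

    Regions are sorted by ascending density (ties broken alphabetically for
    determinism) and the cumulative population and staff shares emitted per
    region.
    """
    if len(regions) < 2:
        raise EquityError("need at least two regions for a concentration curve")
    missing = [r.name for r in regions if r.name not in densities]
    if missing:
        raise EquityError(f"regions lacking densities: {missing}")
    if any(densities[r.name] <= 0 for r in regions):
        raise EquityError("all densities must be positive")
    ordered = sorted(regions, key=lambda r: (densities[r.name], r.name))
    pops = np.array([r.population for r in ordered], dtype=float)
    staff = np.array([_staff_count(r, cadre) for r in ordered], dtype=float)
    if staff.sum() <= 0:
        raise EquityError(f"no {cadre} staff in any region")
    p = pops / pops.sum()
    q = np.cumsum(staff / staff.sum())
    return ConcentrationResult(
        cadre=cadre,
        ordering=tuple(r.name for r in ordered),
        densities=tuple(densities[r.name] for r in ordered),
        pop_shares=tuple(p),
        staff_counts=tuple(staff),
        cum_pop_share=tuple(np.cumsum(p)),
        cum_staff_share=tuple(q),
    )


def _index_from_shares(p: np.ndarray, staff: np.ndarray) -> float:
    q = np.cumsum(staff) / staff.sum()
    q_prev = np.concatenate([[0.0], q[:-1]])
    return float(1.0 - np.sum(p * (q + q_prev)))


def concentration_index(curve: ConcentrationResult) -> float:
    """Grouped trapezoid concentration index of a curve (positive = pro-urban)."""
    p = np.asarray(curve.pop_shares)
    staff = np.asarray(curve.staff_counts, dtype=float)
    for name, cum in (
        ("population", curve.cum_pop_share),
        ("staff", curve.cum_staff_share),
    ):
        if abs(cum[-1] - 1.0) > _SHARE_ATOL:
            raise EquityError(f"cumulative {name} shares do not reach 1")
    return _index_from_shares(p, staff)


def proportionality_test(curve: ConcentrationResult) -> ConcentrationResult:
    """Jackknife z-test of the index against proportional allocation.

    Deletes one region at a time, recomputes the index on the remaining
    groups, and forms the jackknife standard error.  Returns a copy of the
    curve with ``index``, ``std_error``, ``z`` and ``significant`` filled.
    A degenerate zero standard error (e.g. exactly proportional allocation)
    yields z = 0 when the index is itself (numerically) zero.
    """
    p = np.asarray(curve.pop_shares)
    if np.any(p <= 0):
        raise EquityError("every group must have a positive population share")
    staff = np.asarray(curve.staff_counts, dtype=float)
    index = concentration_index(curve)
    n = len(p)
    loo = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        p_i = p[keep] / p[keep].sum()
        loo[i] = _index_from_shares(p_i, staff[keep])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    if se == 0.0:
        z = 0.0 if abs(index) < 1e-12 else float("inf") * np.sign(index)
    else:
        z = index / se
    from dataclasses import replace

    return replace(
        curve,
        index=index,
        std_error=se,
        z=float(z),
        significant=bool(abs(z) >= Z_CRITICAL),
    )


def analyse_cadres(
    regions: Sequence[ReconciledRegion],
    cadres: Iterable[str],
    densities: Mapping[str, float],
) -> list[ConcentrationResult]:
    return [
        proportionality_test(concentration_curve(regions, cadre, densities))
        for cadre in cadres
    ]


def curve_frame(result: ConcentrationResult) -> pd.DataFrame:
    """Curve point set (one row per region, ascending density)."""
    return pd.DataFrame(
        {
            "region": result.ordering,
            "density": result.densities,
            "cum_pop_share": result.cum_pop_share,
            "cum_staff_share": result.cum_staff_share,
        }
    )


def summary_frame(results: Sequence[ConcentrationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cadre": [r.cadre for r in results],
            "index": [r.index for r in results],
            "std_error": [r.std_error for r in results],
            "z": [r.z for r in results],
            "verdict": [
                "significant" if r.significant else "not significant" for r in results
            ],
        }
    )
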