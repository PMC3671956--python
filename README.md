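# hrhplan

Regional health-workforce analysis for maternal and newborn care: population
reconstruction from staffing tables, workload and equity measurement, and a
coverage scale-up projection with attrition and replacement hiring. The
packaged data describe Zimbabwe's public-sector workforce in 2010 (ten
regions; doctors, clinical officers, and nurses/midwives), and the same
pipeline runs on any panel with the same table structure — real or generated
by the built-in synthetic-data module.

It is written for health-systems analysts and HRH (human resources for
health) planners who have the kind of data ministries actually publish —
staff head-counts with densities per 100,000, delivery and birth rates per
100,000 — and need defensible regional populations, per-staff workloads,
equity indices and staffing/cost projections out of them.

## The methods in brief

**Reconciliation.** A head-count `C` with density `r` per 100,000 implies a
population `C/r × 10⁵`. The consensus over a region's cadres is the
inverse-variance weighted mean (weights `r²`, since a rate printed to two
decimals carries relative rounding noise ≈ `0.005/r`), with per-pair
consistency checks. Births and deliveries follow from per-100k rates.

**Workload & coverage.** Events per staff-year by cadre, and baseline
skilled-attendance coverage = deliveries rate / births rate.

**Equity.** Regions ranked by population density; the grouped concentration
index `CI = 1 − Σ pᵢ(Qᵢ + Qᵢ₋₁)` (twice the area between the concentration
curve and the diagonal; positive = pro-urban), with a delete-one-region
jackknife z-test against proportional allocation.

**Projection.** Requirement = births × coverage / norm (175 deliveries per
skilled birth attendant per year, 1,000 per doctor). Each year the stock
decays by 10% attrition and hires restore it to the requirement only if it
fell below; salaries (US$2,112 / US$2,616 per year) grow 3%/year; cost =
stock × salary. Coverage steps to the 95% target in the base year by
default (a linear ramp is available).

## Worked example

```sh
hrhplan all --out out/
```

runs every stage on the packaged tables and prints, among other sections:

```
Concentration of staff across regions (ordered by density)

            cadre index std_error    z         verdict
          doctors  0.54     0.136 3.94     significant
clinical_officers  0.51     0.300 1.69 not significant
           nurses  0.18     0.101 1.74 not significant

Additional staff required by region

             region  current_staff  current_need  need_at_target  cumulative_additional
           Bulawayo            168            10              10                      0
             Harare            349            32              36                      0
         Manicaland             26            29              46                     43
...

Workforce cost trajectory

 year cost_usd_millions
 2010            $37.7m
 ...
 2015            $25.8m
```

Reading it: doctors are strongly concentrated in the dense metropolitan
regions (index 0.54, significantly non-proportional), while nurses are
spread nearly in proportion to population. Manicaland's 26 doctors fall
short of the 29 needed for today's facility deliveries and the 46 needed
for 95% coverage; holding its stock at that requirement through 2015 under
10% attrition takes 43 cumulative hires. Nationally, though, existing
stocks (17,032 nurses, 689 doctors) exceed the 95%-coverage requirements
(1,778 skilled birth attendants, 311 doctors), so the projection hires
nobody at national aggregation and the wage bill declines from $37.7m to
$25.8m as attrition outpaces salary growth.

Library use mirrors the CLI:

```python
from hrhplan import (load_packaged_regions, ProjectionAssumptions,
                     StaffingNorms, gap_report)

regions, national, areas = load_packaged_regions()
report = gap_report(regions, ProjectionAssumptions(), StaffingNorms())
print(report.frame())
```

Synthetic panels with a tunable urban-concentration bias come from
`hrhplan synth --out dir --seed 42 --urban-bias 1.5` or
`hrhplan.generate_regions(SyntheticScenario(...))`; they use the same CSV
schemas the loaders consume.

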