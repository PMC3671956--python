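# Methods

## Setting

`hrhplan` analyses the public-sector maternal/newborn-health workforce of a
country divided into administrative regions — the packaged data describe
Zimbabwe's ten regions in 2010 (two metropolitan: Harare and Bulawayo).
Three cadres appear: doctors, clinical officers, and nurses (a category
that includes midwives); "skilled" means all three together. The package
answers four questions: how large is each region's population and birth
cohort (neither is published directly); how heavily loaded is the current
staff; how equitably are staff distributed across regions; and what staff
and wage bill would be needed to raise skilled birth attendance to a
target coverage.

## Population reconciliation

The staffing table prints, per region and cadre, a head-count `C` and a
density `r` per 100,000 population, so each (C, r) pair implies a
population `C / r × 100,000`. Pairs of one region should agree up to the
rounding of `r`, which is printed to two decimals: a pair's implied
population carries a relative rounding uncertainty of roughly
`0.005 / r`. The consensus population is therefore the inverse-variance
weighted mean with weights `r²`. This keeps small cadres (clinical
officers, with rates as low as 0.08 per 100k and hence ±6% rounding noise)
in the data without letting them distort the estimate, which is dominated
by the nurse and skilled-total pairs.

Consistency is enforced per pair: a relative deviation from the consensus
exceeding `tolerance + 0.005/r` (tolerance default 1%) raises a
reconciliation error naming the region. The reported `max_discrepancy` is
the largest relative deviation observed. On the packaged tables every
region reconciles; the worst well-measured pair deviates ≈0.2%.

The national aggregate is the TOTAL row reconciled by the same rule
(population ≈ 10.655 million). Annual births and facility deliveries are
the per-100,000 rates of the workload table times the reconciled
population; nationally ≈ 327,600 births and ≈ 215,800 facility
deliveries per year.

An unweighted mean was considered and rejected: with the coarse clinical
officer rates it shifts several regional estimates by 0.4–4% in a
direction driven purely by print rounding, and the national doctors rate
(6.47, rounded up from 6.466) drags the national population low by 0.05%.

## Workload and coverage

Workload is events per staff-year: annual deliveries (or births) divided
by doctors or by the full skilled cadre. A zero denominator yields an
undefined (NaN) ratio, mirroring the dashes of the source table, not an
exception. Baseline coverage — the fraction of births attended in a
facility — is the ratio of the two per-100k rates, clamped to [0, 1];
nationally 0.659 (reported as 66%), ranging from 0.50 (Mashonaland
Central) to 0.88 (Bulawayo).

Salary records (monthly US$, salary:GDP-per-capita ratio) admit the check
that all cadres imply one annual GDP per capita via `12 × salary / ratio`;
the packaged table's three cadres agree within 0.15%.

## Concentration analysis

Regions are ranked by population density (ascending; ties broken
alphabetically), the proxy for urbanity. The land areas needed for
densities are not part of the source data; the package ships the standard
provincial areas (km²) as an editable fixture used only for ranking — the
index depends on the ordering, not on area magnitudes.

With `p_i` the population share of group `i` along the ranking and `Q_i`
the cumulative staff share, the grouped (trapezoid/Fuller) concentration
index is

    CI = 1 − Σ_i p_i (Q_i + Q_{i−1})   ∈ [−1, 1],

twice the area between the concentration curve and the diagonal, positive
when staff concentrate in denser regions. On the packaged data: doctors
0.537, clinical officers 0.506, nurses 0.176.

Significance against proportional allocation uses a delete-one-region
jackknife standard error. The regions are the units at which allocation
(and reporting error) operate, so resampling groups — not individual staff
— captures the relevant uncertainty; a multinomial model over 17,000
individual nurses would declare even a mild 0.18 index overwhelmingly
significant, which mistakes the question (it tests sampling noise in a
census, not allocational proportionality). Verdicts at |z| ≥ 1.96:
doctors significantly pro-urban (z ≈ 3.9), clinical officers and nurses
not significant (z ≈ 1.7). An exactly proportional allocation has CI = 0,
zero jackknife spread, and is reported as z = 0, not significant.

## Scale-up projection

The simulator is quantity-driven in the tradition of the WHO Making
Pregnancy Safer staffing projector: the staff needed to attend `B` births
at coverage `c` is `B·c / n`, with norms `n` of 175 deliveries/year per
skilled birth attendant and 1,000 per doctor (the doctor covering the
complicated fraction). Defaults: base year 2010, target year 2015, target
coverage 95%, attrition 10%/year, salary growth 3%/year, base salaries
US$2,112 (SBA) and US$2,616 (doctor) — twelve times the monthly
mid-scale salaries — and births held at the base-year level
(`births_growth = 0`, configurable).

Dynamics per year: the stock decays by the attrition fraction, then hires
top it back up to the requirement if and only if it fell below
(`stock_t = stock_{t−1}(1 − a) + hires_t`, hires ≥ 0). Under the default
"step" coverage path the requirement sits at the target-coverage level
from the base year, so base-year hires close the initial gap at once and
later hires replace attrition only; a "linear" path ramping coverage
evenly to the target is provided for sensitivity analysis (it always needs
at most as many cumulative hires as the step path). Stocks and hires are
real-valued internally; headline integers are floored (a fraction of a
post cannot deliver). Costs are stock × salary, salaries compounding from
the base year; totals print in US$ millions truncated to one decimal.

Aggregation matters and both modes are explicit. The national projection
runs on the reconciled TOTAL row with the nurse head-count (17,032) as the
SBA stock and 689 doctors — clinical officers (35) belong to neither
cadre. Nationally both stocks exceed their requirements (1,778.1 SBAs,
311.2 doctors) throughout, so no hires occur and the wage bill falls from
$37.7m to $25.8m — attrition at 10% outpaces salary growth at 3%. The gap
report instead simulates each region separately, where the uneven doctor
distribution produces hiring: e.g. Manicaland starts with 26 doctors
against a current need of 29.6 and a 95%-coverage requirement of 46.6, so
it accumulates ≈ 44 hires (reported 43 after flooring) — an initial gap of
≈ 21 plus five years of 10% replacement. Whether nurses counted as SBAs
truly hold midwifery skills is a recognised data limitation; the
projection takes the head-counts at face value.

## Synthetic data

The generator emulates the structure the analysis assumes, not the
Zimbabwe data generatively. Populations are log-normal (median 1 million,
σ = 0.5); one region (two when n ≥ 6) is metropolitan with density drawn
from 800–2,000 persons/km² against 5–60 elsewhere; staff are multinomial
across regions with probabilities ∝ population × density^`urban_bias`;
per-region coverage is uniform on (0.55, 0.90). Default totals mirror the
packaged panel (689/35/17,032 across 10 regions) and the crude birth rate
is 30.7 per 1,000, matching the national 3,074 births per 100,000. One
nurse is forced into every region so each region retains a usable
count/rate pair. Rates are emitted at full float precision, so generated
fixtures reconcile with zero discrepancy and the drawn coverage is
recoverable to 1e-12 — deliberately unlike the real tables, whose 2-dp
rounding the reconciler must absorb; passing round-trip tests on synthetic
data therefore says nothing about rounding robustness, which is exercised
on the packaged tables instead. All draws flow from a single integer seed;
identical seeds give byte-identical fixture files.

A deliberately naive year-by-year projection oracle (explicit loops, no
shared code with the engine) produces known-answer sheets for generated
scenarios; the engine must match it to 1e-9.

## Numerical conventions and edge cases

- Counts are integers; populations, volumes, stocks, hires are floats; no
  premature rounding. Floor for headline staff integers; truncation to
  0.1 for US$ millions.
- Cumulative-share endpoints are checked to 1e-6 before an index is
  computed; curve/oracle agreement is required to 1e-12.
- A cadre with zero staff yields NaN workload (flagged, not raised); zero
  birth rate makes coverage an error, since no denominator exists.
- "-" cells parse as zero count with an absent rate; a positive count with
  an explicit zero rate is an inconsistency error.
- Reported two-decimal quantities are compared at |Δ| ≤ 0.01 throughout
  the tests.

## Known limitations

- Populations are reconstructed, not observed; their precision is bounded
  by the two-decimal printing of the source rates (≈ 0.1% for the large
  cadres). Quantities that sit within rounding distance of an integer
  boundary (regional gap totals, most visibly) inherit ±1-unit ambiguity.
- The density ranking depends on land areas supplied as a fixture;
  near-ties among mid-density provinces move the concentration indices in
  the third decimal.
- The projection has no stochastic attrition, age/grade structure, or
  training-pipeline constraint, and treats staff time as fully available
  for delivery care.
- The jackknife proportionality test is a design choice for grouped
  allocation data, not an estimate of any individual-level sampling
  variance.
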