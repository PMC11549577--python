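# Methods

## The decision problem

A hospital considering a dose-calculation app for pediatric emergency
drugs faces a recurring annual cost (maintenance and updates, staff
training, optionally dedicated tablets) and a per-administration benefit:
fewer dosing errors, hence fewer adverse drug events (ADEs), hence avoided
hospital costs, plus a small amount of preparation time saved. `medcea`
models this as a single-year, expected-value decision analysis for one
drug at a time, from the perspective of the implementing hospital. There
is no discounting, no multi-year horizon, and no quality-of-life
valuation; the comparator (conventional preparation) carries zero
incremental cost.

## Effect model

An administration is an error when the prepared dose deviates from the
correct weight-based dose by strictly more than 10% in either direction
(overdose above, underdose below; at most one error per administration).
Preventable errors per administration default to the pooled-denominator
estimator `((OD_c+UD_c) − (OD_a+UD_a)) / n_c`, which reproduces the
published per-administration ratios exactly from the published arm counts;
the arm-specific-rates difference is selectable (`policy="arm_rates"`) and
agrees exactly when the arms are equal-sized. The estimate may be negative
(app arm worse); it is carried through with its sign and flagged at the
ROI stage rather than clipped.

The epinephrine evidence base reports 44 total control errors while its
component overdose/underdose counts sum to 43; the model always uses the
component counts (they parameterize the uncertainty analysis) and logs a
warning when a configured `reported_errors` total disagrees.

## ADE cascade and costing

Expected ADEs per administration are `N_err · P(ADE)`, split into NCC MERP
categories E and F with `P(CatE) = 1 − P(CatF)` enforced structurally:
only P(CatF) is a sampled parameter, because sampling both rows
independently would break normalization. Mortality and multiple concurrent
ADEs are excluded by assumption (conservative: benefits are understated).

Category F costs `CLOS × daily inpatient cost`, where CLOS = 0.64 extra
inpatient days conditional on an ADE (the printed one-decimal mean is 0.6;
the costing uses the stated 0.64) at US $229.7/day. Category E uses the
excess reimbursement attached to complication-related stays (91.84% of the
average stay cost, i.e. US $22,080). Because the source does not pin down
whether that excess stands alone or sits on top of the implied base stay,
both formulations are first-class and every report records which one was
used:

* `excess_only` (default): Cat E costs US $22,080; epinephrine break-even
  31.6 administrations.
* `stay_plus_excess`: Cat E costs 22,080/0.9184 + 22,080 ≈ US $46,122;
  epinephrine break-even 15.2 administrations, close to the published
  16 (15.8). Neither formulation reproduces 15.8 exactly; the exact
  aggregation behind the published break-even table is under-specified,
  so the test suite asserts windows derived arithmetically from the
  parameter means ([14, 18] and [28, 35]) instead of the printed values.

## Economics

Annual program cost `C` is maintenance/update (20% of the US $186,026
development cost → US $37,205/yr; the development cost itself is excluded)
plus per-group training totals (nurses US $885.5 + physicians US $522.7)
plus an optional device cost (US $600/yr scenario). `ICER_err = (C − n·t)
/ (n · N_err)` with `t` the valued time saved per administration (zero by
default — see below) and `n` the annual volume; `ICER_ADE = ICER_err /
P(ADE)`. Break-even is `C / b` with `b` the per-administration benefit,
reported both as the real value and the smallest integer volume with
ROI ≥ 1; a non-positive benefit yields a "never profitable" signal, not an
exception.

Two volumes per scenario: `annual_administrations` (the unit's actual 2019
volume, used for ROI-at-volume) and `icer_administrations` (the ICER
denominator). They differ only where the published cost-per-error figures
are inconsistent with the published volumes (epinephrine 534 implies
~141/yr although the unit volume is 40; norepinephrine 1077 implies
~74/yr although the volume is 141 — an apparent row swap in the source
tables). The packaged configs encode the pairing that reproduces the
published figures and the loader logs the discrepancy.

Time saved (9.5 s/administration for epinephrine) is valued at
`wage_per_second`, default 0: the source names no wage, and at ~10 s the
contribution is negligible against ADE costs, so the default cannot flip
any conclusion.

## Uncertainty

Parameter distributions: uniform with support exactly ±20% of the mean
(the printed bounds equal 0.8·mean and 1.2·mean, so ±20% is read as the
full support, not a central interval) or normal with the printed SD.
Probabilities are truncated to [0, 1] and costs/times/counts/CLOS to
[0, ∞) by rejection sampling — the source is silent, unphysical draws
would corrupt the analysis, and rejection avoids the point masses clipping
creates. Count parameters are sampled continuously, matching their
continuous printed bounds. Draws are mutually independent apart from the
CatE/CatF complement. One printed uniform bound (nurse training upper
1052.6 instead of the ±20% value 1062.6) is used verbatim.

The probabilistic sensitivity analysis samples every non-fixed parameter
once per draw, in a fixed canonical order from a single seeded
`numpy.random.Generator`, and re-runs the full deterministic pipeline, so
the all-fixed degenerate case reproduces the deterministic result bit for
bit and identical (config, draws, seed) is bit-reproducible. Default
10,000 draws. Never-profitable draws are counted and excluded from
percentiles with a warning. Percentiles are empirical nearest-rank order
statistics (no interpolation). The printed normal P(ADE) CI (9.1–13.5%) is
asymmetric and therefore inconsistent with N(0.111, 0.011); the stated
normal family is followed for sampling, while tornado endpoints of normal
parameters use the printed CI verbatim where available (else mean ±
1.96·SD, truncated). Uniform tornado endpoints are the support ends; fixed
parameters get zero-width bars; bars are sorted by outcome range
(stable, so ties keep canonical order).

With the 2019 epinephrine inputs the four widest tornado bars on the
break-even volume are, in order: the complication-cost excess, P(ADE),
maintenance cost, and control-group underdoses — the last three within a
few percent of each other, under either Cat E formulation.

## Synthetic trials

The generator emulates the record-level data beneath the trial summaries:
per administration an error class is drawn multinomially with arm-specific
overdose/underdose probabilities; error deviations are uniform on
(0.10, 1.0] in absolute value (only the ±10% threshold matters
downstream, so the magnitude law is a modelling choice); correct doses are
uniform inside (−0.10, 0.10); preparation times are normal truncated at
zero. The ±0.10 boundary is strictly not an error. What passing tests
show: the summary statistics the economic model consumes are recovered
from record-level data (rates to 0.5 percentage points at 10⁵ per arm).
What they do not show: anything about real dosing-deviation magnitudes,
patient covariates, or correlation between timing and errors — none of
which the economic model uses.

## Numerical choices and problem sizes

Reporting rounds half-up at output time only (ratios to 3 decimals, money
to whole dollars, break-even to 1 decimal plus the integer ceiling); JSON
outputs keep full precision, and output files carry no timestamps so runs
are byte-reproducible. The integer break-even is computed by direct search
up from ⌊C/b⌋, robust to the division landing exactly on an integer.
Rejection sampling aborts with a clear error after 10⁵ failed tries
(truncation region with negligible mass). The test suite uses 10,000-draw
PSA runs where stability across seeds is asserted, 10⁵-per-arm synthetic
trials for parameter recovery, and a 10⁶-draw event-level simulation as
the independent oracle for the expected-value cascade; the acceptance
script runs 10,000 draws per drug.

## Known limitations

Single year, single drug at a time, one currency conversion, no
correlation structure between parameters, no acceptability curves over
willingness-to-pay, and the published break-even table and ROI (2.5 at 40
administrations; this model computes 2.64 under `stay_plus_excess`) are
approximated, not reproduced exactly, for the reasons above.
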