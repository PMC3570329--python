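# Methods

This note records the analytic conventions, the synthetic-data mechanism,
and the design choices made where claims-analysis practice leaves room for
interpretation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Cohort construction

A patient enters the cohort at the *index date*: their earliest oral 5-ASA
fill. Three exclusions apply, in a fixed, logged order, so attrition
tables are reproducible:

1. **Washout.** New use requires 90 days before the index fill with no
   5-ASA dispensing. "Three months" is implemented as 90 days because
   calendar-month arithmetic is ambiguous. The earliest observed fill has
   no earlier fill by construction, so the operative check is
   *observability*: the patient must be continuously plan-eligible over
   the 90 pre-index days. A patient whose eligibility begins closer to
   their first fill has left-truncated history and is excluded — the
   stricter alternative of indexing on a later fill is deliberately not
   taken, since a later fill is a refill, not initiation. An
   `--all-drugs-washout` flag additionally requires no dispensing of any
   drug in the washout.
2. **Crohn's disease.** Any medical claim coded ICD-9 555.x, at any time
   in the available history (the exclusion is a diagnosis, not a
   time-window event).
3. **Coverage.** Eligibility must cover the full closed observation window
   [index, index + 364 d]; abutting eligibility periods are merged, any
   one-day hole fails.

Age at index is `index year − birth year` (claims extracts rarely carry
full birth dates); sex and birth year come from a demographics table
(`patients.csv`) alongside the three claims files.

## Adherence (MPR)

The denominator is fixed at 365 days for every member — adherence is
defined over the first year of therapy regardless of when the patient
discontinues; persistence is analyzed separately. The numerator under the
default `sum` policy is the total dispensed days of supply of *any* 5-ASA
product in the window, with each fill truncated at the window end and the
total capped at 365. Thresholds are inclusive: MPR ≥ 0.80 is adherent,
MPR ≥ 0.50 the complementary cut.

The `pdc` policy counts distinct covered days instead: supply is consumed
one day per day, and early refills are banked (carry-forward stockpiling),
so overlapping supply is never double-counted. On any input
`sum ≥ pdc`, with equality when no fills overlap; both are property-tested
against an independent day-by-day oracle. An `--index-product-only` flag
restricts the numerator to the index product for the stricter reading of
per-product adherence.

## Persistence episodes

Episode construction scans index-product fills in date order with banked
supply: a fill arriving before the previous runout starts consuming when
the banked supply is exhausted, so early refills cannot create artificial
gaps. Discontinuation conventions, stated explicitly because the
literature rarely fixes them:

* **Gap rule.** Treatment is ceased at the first runout followed by a
  60-day grace period with no 5-ASA fill. By default a fill of *any*
  5-ASA product closes a gap (the patient received 5-ASA treatment), but a
  different-product fill is itself a switch; this reconciles the
  any-product gap wording with switch-as-non-persistence. A
  `--strict-index-gap` flag restricts gap closure to the index product.
* **Event times.** A gap discontinuation is timed at runout + 1 days from
  index (the first unmedicated day, with the index day counted as day 1);
  a switch is timed at the switch fill's day offset. Times lie in
  [1, 365].
* **Right-edge rule.** A gap counts only when the entire grace period
  elapses inside the 365-day window, i.e. the runout is on or before day
  305 (1-based). A patient who refills steadily until late in the year
  and then stops cannot be distinguished, within the year, from one
  pausing briefly — such episodes are censored at 365, not discontinued.
  Consequently `persistent_at_365 ⟺ event type CENSORED ⟺ event time
  365`, and the Kaplan–Meier estimate at day 365 equals the empirical
  persistent proportion exactly (all censoring occurs at 365).
* **Switch rule.** Any different-product 5-ASA fill in the window is a
  switch, even if index-product fills continue afterwards (non-persistence
  *to the initial medication*); `--require-abandonment` demands that no
  index-product fill follow it. When both a switch and a qualifying gap
  exist, the earlier event wins; a different-product fill inside a silent
  window voids that gap, so classification is exclusive by construction.

Kaplan–Meier estimation and the asymptotic log-rank test are delegated to
lifelines; a seeded permutation log-rank (add-one p-value, labels
reshuffled) is provided as a small-sample cross-check and is used in the
tests as an independent oracle for the chi-square asymptotics.

## Covariates and chronic disease score

Comorbidity is read off the medication profile, not diagnoses: a flag
(hypertension, heart disease, respiratory illness, diabetes) is true when
at least one marker-class fill occurs in the lookback, by default the 365
days before index through the window end. Corticosteroid exposure is
split into *prior* (fill in the 365 pre-index days) and *current* (fill
inside the window). Age ≥ 60 is inclusive.

The chronic disease score sums integer weights over the *distinct*
medication classes observed in the lookback, plus optional co-occurrence
adjustments, and is dichotomized at a configurable cut (default 6; the
`--median-cut` flag recomputes the cut as the cohort median, using the
ceiling for non-integer medians). The shipped weight table (cardiac 4,
hypertension 1, respiratory 2, diabetes 2, epilepsy 2, rheumatologic 1,
ulcer 1; +1 when cardiac and hypertension co-occur) is an *adaptation* of
the medication-based chronic-disease-score tradition, not a canonical
published table; every correctness test therefore uses explicitly
configured toy tables, and analyses needing a specific scoring system
should supply their own via YAML.

## Determinant models

Each binary outcome (adherent at 80 %, persistent at 365) is modeled with
two independent covariate blocks, mirroring common practice of separating
patient demographics (male, age ≥ 60, prior steroid, current steroid —
steroid use sits in this block because it is a treatment-history
characteristic rather than a comorbidity) from comorbidities
(four flags + high CDS); a `--combined` flag pools them. Backward
elimination removes the covariate with the largest Wald p while it exceeds
`removal_alpha` (default 0.05 — the conventional threshold, exposed as a
knob), refitting after each removal; exact p ties remove the first-listed
covariate, making the procedure deterministic and row-order invariant.
Dropped covariates are reported `NS`. Intervals are Wald,
exp(β ± 1.96·SE) — symmetric on the log scale, matching how such tables
are conventionally printed. Maximum-likelihood fits go through statsmodels
`Logit`; rank deficiency and (quasi-)separation are surfaced as errors
naming the offending covariate rather than silently returning inflated
standard errors.

## Synthetic claims generator

The generator emulates the structure a provincial-drug-plan 5-ASA extract
presents to this pipeline. Patient-level draws (demographics, index date
and product, latent class, comorbidity and steroid indicators, eligibility)
and fill-level draws use independent child streams of one `SeedSequence`,
so outputs are byte-identical under a fixed seed.

**Mechanism.** Each patient carries a latent *prompt refiller* indicator
with `logit P(prompt) = intercept + β_male·male + β_age·(age≥60) +
β_ster·current_steroid`. Refill delay beyond runout is
`max(0, round(X))`, X lognormal with class-specific mean (defaults: 2 d
prompt, 25 d slow; log-scale dispersion 0.6) — a mean of exactly 0 yields
delay 0, so the gapless limit holds exactly. Because the two delay
regimes sit far on either side of the 80 % MPR threshold, adherence
coincides with the latent class (exactly so when stopping is disabled),
making the configured β the *true conditional log-odds of adherence*;
this is what the parameter-recovery tests exercise, and it is why a
latent-class design was chosen over a continuous location shift of the
delay distribution, whose induced adherence log-odds would be some
untracked monotone function of β. At each runout the patient stops with
probability `1 − exp(−h·cycle)` (per-product daily hazard h, cycle =
supply + delay) or switches with a per-refill probability; a switch emits
a single fill of a different product and ends the stream — switchers'
subsequent therapy on the new product is not simulated, a deliberate
simplification that slightly depresses simulated all-product MPR among
switchers.

**Defaults** follow the published descriptive profile of Quebec
public-plan 5-ASA users: 43.4 % male; age-band mix 3.6/17.0/30.7/43.7/5.0 %
(<20/20–39/40–59/60–79/80+); comorbidity prevalences 50.1/41.3/33.9/32.7 %
(hypertension/heart/respiratory/diabetes); prior and current
corticosteroid use 30.0 % and 32.6 %; index-product shares proportional to
published per-product user counts; days-supply mixture
7/15/30/60 d with probabilities .15/.20/.55/.10 (median 30, mean ≈ 27);
per-product daily stopping hazards backed out of published 1-year
persistence by an exponential approximation (9.0e-4 for the once-daily
product, 2.0–2.3e-3 for the others). Because slow refillers also
discontinue through the 60-day rule when a delay draw exceeds the grace
period, simulated persistence runs a few points below the exponential
back-out — the generator reproduces the qualitative regime (adherence in
the high 20s %, persistence in the low-to-mid 40s %), not exact published
values. Promptness coefficients default to β_male 0.25, β_age 0.47,
β_ster 0.34 with intercept −0.45, giving adherence odds ratios of the
size typically reported (1.2–1.6). Exclusion-path knobs
(`crohns_prob`, `left_truncated_prob`, `short_coverage_prob`) default to
0 so coverage filters pass untouched; tests enable them to exercise
attrition.

**What the generator does not emulate:** hospitalization supply gaps,
co-pay behavior, dose titration, sampling/stockpiling idiosyncrasies,
multi-episode restarts, or correlated comorbidity structure. Passing
tests therefore demonstrate algorithmic correctness of the pipeline and
recoverability of planted effects under this mechanism — not calibration
to any real population.

**Recovery protocol.** The odds-ratio recovery experiment configures the
male promptness coefficient to 0.4 at n = 5000 with stopping hazard and
switch probability set to 0, so the adherence outcome isolates the
promptness channel (a nonzero stopping hazard attenuates the marginal OR
for reasons unrelated to refill behavior), and fits the three true
covariates jointly; the acceptance test requires the 95 % Wald CI to cover
exp(0.4) in at least 90 % of 50 seeded replicates.

## Numerical and reporting conventions

* Dates are ISO 8601; date intervals are closed; a fill on day *d* with
  supply *s* covers days *d … d+s−1*.
* Printed percentages and ratios use round-half-up at one decimal
  (away-from-zero for negatives), so table arithmetic is bit-reproducible;
  `round()`'s banker's rounding is never used for reports.
* Malformed input rows fail fast by default with the 1-based file line;
  `--skip-bad-rows` switches to skip-and-log. Silent data loss is treated
  as worse than a crash.
* Readers sort by (patient, date) with a stable mergesort, making every
  downstream result invariant to input row order.
* Chi-square comparisons use the Pearson statistic on the k×2 table
  without continuity correction; expected cells < 1 log a warning.
* Problem sizes in the test suite — 1,100 generated patients for the
  oracle sweeps, 50 replicates of n = 5000 for OR recovery, 200
  replicates for stepwise operating characteristics, 999–1,999
  permutations for the log-rank cross-check — were chosen to give
  comfortable statistical resolution (3-SE margins, Monte-Carlo error well
  below the asserted tolerances) at desk-scale runtimes.

## Known limitations

* The washout checks only 5-ASA fills by default; true treatment-naivety
  cannot be established from a 90-day window.
* `days_supply` is required and trusted; no imputation is attempted for
  extracts with missing supply fields.
* The CDS default table is an adaptation (above); CDS-based findings
  should be read as sensitivity analyses unless a validated table is
  configured.
* Only the first definitive cessation is modeled; restart episodes are out
  of scope.
* ICD-9 only; no ICD-10 mapping.
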