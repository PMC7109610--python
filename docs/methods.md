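# Methods

## Scope and model

`mshrs` monetises responses to the Multiple Sclerosis Health Resource
Utilization Survey (MS-HRS), a 24-item resource-use questionnaire, from
the societal perspective, and implements the psychometric validation
battery appropriate for a costing instrument. Costs are classified into
direct medical (inpatient care, day admissions, consultations,
examinations, over-the-counter medication, consumables, professional
care), direct nonmedical (investments/aids, informal care) and indirect
costs (absenteeism, disability pension, presenteeism).
Disease-modifying-therapy (DMT) cost is carried separately and excluded
from the direct-medical subtotal by convention; all validation analyses
exclude it.

Quantification follows microcosting: every consumed unit is enumerated
and priced individually. Valuation uses fixed unit costs at a reference
price level (the packaged default is the 2011 German table set) and the
human-capital approach for productivity: any hour not worked is valued at
the average hourly labor cost.

## Key formulas and conventions

* **Quarter conventions.** Costs are reported per quarter. Count-based
  quantities reported over a recall window of `d` days (0 < d ≤ 365) are
  rescaled by `91.25 / d` (91.25 = 365/4); weekly-rate items (care hours,
  work hours) use 13 whole weeks per quarter. Both constants live in
  `PeriodModel` and are configurable.
* **Absenteeism.** Per sick day: `annual_work_hours / annual_work_days ×
  hourly_labor_cost` = 1406.2/233 × €29.90 ≈ €180.45. Sick days are
  recall-scaled to the quarter before valuation.
* **Disability pension.** `pct/100 × annual_work_hours ×
  hourly_labor_cost / 4` per quarter; at 100% the annualised value equals
  the cap €42,045.38 = 1406.2 × 29.90 exactly.
* **Presenteeism.** The 0–10 reduced-productivity score maps linearly to
  a lost fraction `score/10`, applied to hours actually attended:
  `weekly_hours × 13 − sick_days × weekly_hours/5` (floored at 0). Netting
  sick leave out of the base prevents double counting the same hour as
  both absence and reduced productivity.
* **Informal care.** Hours are stored as reported but capped at 60 h/week
  at valuation (opportunity-cost convention), priced at €21.09/h over 13
  weeks.
* **DMT.** Annual net cost per drug-year divided by 4; the table covers
  2010–2017 and marks pre-launch years as not available (fingolimod 2010).
* **Indexation / currency.** Patient-reported expenditures are moved to
  the reference price level by `(1+r)^(Δyears)` with default r = 0.02;
  EUR→USD uses the fixed annual-average rate 1.392. Expenditures pass
  through without recall scaling: the instrument asks for spending over
  the window being costed.
* **Missingness.** An unanswered item is a `missing_flags` entry, never a
  zero (empty CSV cell = missing; explicit 0 = true zero, which the
  adaptive electronic questionnaire produces for gated follow-ups). No
  imputation anywhere: missing inputs propagate as missing components,
  subtotals cover observed components only, and the breakdown carries a
  completeness flag.
* **Rounding.** Monetary arithmetic is unrounded internally; rounding to
  cents happens at reporting. The worked fixture (2 neurologist contacts,
  1 MRI, 10 h/week informal care, 5 sick days) therefore totals €3,853.61;
  summing components pre-rounded to cents would give €3,853.62.

## Psychometrics

* **Stability filter.** A respondent is stable when no relapse occurred in
  the 3-month retest window or the 3 months before baseline, and the EDSS
  did not increase across pre-window → baseline → retest (improvement is
  allowed). Missing history excludes the record with a logged reason.
* **ICC.** One-way random-effects, single measurement — ICC(1,1) =
  (MS_between − MS_within) / (MS_between + (k−1)·MS_within) with k = 2,
  from the one-way ANOVA table; capped at 1, undefined (raised) when the
  total variance is zero. Bands: <0.5 poor, <0.75 moderate, <0.9 good,
  else excellent. Two-way forms are deliberately out of scope.
* **Guttman lower bounds.** Over the standardized monetised components
  excluding DMT: λ2 = [Σ_{i≠j} c_ij + √(k/(k−1) Σ_{i≠j} c_ij²)] / V_total,
  λ6 = 1 − Σ_i (1/(C⁻¹)_ii) / V_total (the item error variance from the
  inverse covariance equals (1−R²_i)·Var_i). Items are standardized before
  computation because raw component scales differ by orders of magnitude;
  standardization happens on the final quarterly monetised items.
* **Known groups.** EDSS bins 0–1.0 / 1.5–2.5 / 3.0–4.0 / 4.5–5.5;
  Kruskal-Wallis omnibus plus all 6 pairwise Mann-Whitney U tests,
  Bonferroni-corrected within the pairwise family (adjusted p =
  min(1, 6·p)). Records with EDSS between or beyond the bins are excluded
  and counted. Ties use midranks with tie-corrected variance; an exact
  enumeration mode (`exact=True`) exists for very small samples and is
  verified against full-permutation oracles in the tests.
* **Convergent/discriminant validity.** Spearman rank correlations of
  total cost (DMT excluded) with PRO summary scores, pairwise-complete,
  ≥10 pairs required; constant vectors raise an explicit undefined-
  statistic error.

## Synthetic cohorts

The generator emulates what the validation needs, not the full disease
process:

* a latent severity gradient over the four EDSS bins (occupancy
  0.273/0.367/0.286/0.074, matching the published bin sizes
  562/756/589/152);
* zero-inflated resource use: each component is occurrence (Bernoulli,
  probability rising with severity) × magnitude (log-normal for money and
  hours, zero-truncated Poisson for counts). This reproduces the
  published pattern of median-zero, heavy-tailed items. Defaults were
  calibrated once to the published per-bin subtotal means and item user
  shares; the achieved per-bin mean quarterly totals are ≈1177/2151/3070/
  4698 EUR against the published 1099/2295/3112/4733 — a shape-level
  match, which is the calibration's goal;
* retest pairs from a variance-components model on the cost scale:
  per-subject latent value (SD `retest_between_sd`, default 2000 around a
  mean of 2462) plus fresh within-wave noise whose SD is derived from the
  target ICC, so the generating ICC is exact by construction. A
  `1 − stable_p` fraction (default 46%) receives a relapse or an EDSS
  step-up so the stability filter is exercised;
* PRO scores from a Gaussian copula on the normal scores of the realized
  cost midranks, mixed at the Pearson level `2 sin(π·ρ_s/6)` that induces
  the target Spearman ρ_s. Ties (the zero-cost mass) attenuate realized
  correlations by roughly 0.01–0.02 at the default zero share.

What the generator does **not** emulate: within-respondent correlation
between components beyond the shared severity scalar, longitudinal
progression beyond two waves, seasonal effects, and reporting error.
Passing tests therefore demonstrate correctness of the costing arithmetic
and the estimators under a realistic zero-inflated severity-graded
structure — not that the instrument itself is valid in any new
population.

## Numerical and design choices

* Exact rational arithmetic (`fractions.Fraction`) for proportions such
  as the completion rate; floats only at display.
* ICC parameter recovery is assessed on all generated pairs
  (`stable_p=1`): the variance-components model defines the true ICC over
  all subjects, and the recovery experiment (true ICC ∈ {0.5, 0.83,
  0.95}, n = 1,000 pairs, 100 replicates, ±0.05) is sized so the
  estimator's sampling SD (≈0.024 at ICC 0.5) keeps ≥95% of replicates in
  band.
* Random seeds: every simulation entry point takes an explicit seed; the
  PRO copula must be seeded independently of the cost draws (a shared
  seed makes the "noise" identical to the log-normal deviates of the
  costs and silently inflates the realized correlation — the CLI derives
  an offset sub-seed for this reason).
* Problem sizes in the test suite and acceptance script (1,000-response
  oracle sweeps, n = 1,000 × 100 replicates for recovery, 500/bin for
  known groups, n = 2,000 end-to-end) are chosen as the smallest sizes at
  which the sampling tolerances above are meaningful.
* Degenerate inputs are first-class: empty cohorts, all-zero responses,
  single-item matrices, zero-variance items, empty EDSS bins and
  missing-history retest records all have defined (error or flagged)
  behaviour, tested explicitly.

## Known limitations

* The ×4 annualisation is a convention; per-patient annualisation over
  varying observation windows will differ from 4× the mean quarterly
  cost.
* The instrument collects "number of stays" alongside days; valuation is
  per day, so the schema stores days per ward type and ignores stay
  counts for costing.
* Unit costs are a 2011 German table; any other setting requires a new
  valuation config (the engine reads all prices from the YAML config and
  hard-codes none).
* The survey-level generator and the retest generator are coupled only
  through the cohort's identifiers; wave-2 raw item answers are not
  re-materialised, only wave totals, which is sufficient for the
  reliability analyses but not for wave-2 item-level costing.
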