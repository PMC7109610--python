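# mshrs

Costing engine and psychometric validation toolkit for the **Multiple
Sclerosis Health Resource Utilization Survey (MS-HRS)**, a 24-item
resource-use questionnaire for people with multiple sclerosis.

Health-economic studies in MS need patient-level cost data from the
societal perspective — hospital stays, consultations, examinations,
out-of-pocket spending, informal care, and productivity losses — but
survey answers arrive as raw counts and hours over heterogeneous recall
windows. `mshrs` turns those answers into monetised quarterly cost
breakdowns, and provides the statistical machinery to validate the
instrument itself. It is aimed at health economists and clinical
researchers running MS cost-of-illness or cost-effectiveness studies.

## What it computes

**Costing (microcosting + human capital).** Every consumed unit is priced
individually from a versioned unit-cost table (the packaged default is a
2011 German table set). Quantities reported over a recall window of *d*
days are rescaled by 91.25/*d* to a standard quarter; weekly rates use 13
weeks. Productivity losses follow the human-capital approach:

* absenteeism: sick days × (1406.2 h / 233 d) × €29.90 ≈ €180.45/day,
* disability pension: pct × €42,045.38 / year (the cap equals
  1406.2 × 29.90 exactly),
* presenteeism: (score/10) × attended hours × €29.90, with attended hours
  net of sick leave so no hour is counted twice,
* informal care: hours (capped at 60 h/week) × €21.09.

Costs are classified into direct medical, direct nonmedical and indirect;
disease-modifying-therapy (DMT) cost is carried separately and excluded
from validation analyses. Unanswered items are *missing*, never zero, and
propagate as missing components (no imputation).

**Validation battery.** Test-retest reliability via the one-way
random-effects ICC(1,1) on a clinically stable subgroup (no relapse, no
EDSS increase), with bands poor/moderate/good/excellent at 0.5/0.75/0.9;
Guttman λ2/λ6 lower bounds over the standardized monetised components;
known-group validity across EDSS bins 0–1.0 / 1.5–2.5 / 3.0–4.0 / 4.5–5.5
(Kruskal-Wallis + Bonferroni-adjusted pairwise Mann-Whitney U);
convergent/discriminant validity as Spearman correlations with
patient-reported outcomes.

**Synthetic cohorts.** A seeded generator produces cohorts with
zero-inflated, severity-graded resource use, paired retest waves with an
exact target ICC, and PRO scores rank-coupled to cost at target Spearman
correlations — so the whole pipeline is testable without study data.

## Worked example

```python
from mshrs import SurveyResponse, load_valuation, total_cost, annualize

tables, dmt_table, adj = load_valuation()   # packaged 2011 tables
resp = SurveyResponse(
    respondent_id="P001",
    recall_days=91.25,                       # one quarter
    consultations={"neurologist": 2},
    examinations={"mri": 1},
    informal_care_hours_per_week=10,
    sick_days=5,
    dmt_name="GIL",
)
q = total_cost(resp, tables, dmt_table, adj, dmt_year=2011)
```

prints (via the items and totals on `q`):

```
 consultations:      89.44 EUR/quarter      # 2 x 44.72
  examinations:     120.21 EUR/quarter      # 1 MRI
 informal_care:    2741.70 EUR/quarter      # 10 h/wk x 21.09 x 13
   absenteeism:     902.26 EUR/quarter      # 5 days x 180.45
           dmt:    6674.65 EUR/quarter      # 26698.58 / 4
total excl DMT:    3853.61 EUR/quarter
total incl DMT:   10528.26 EUR/quarter
annual incl DMT:   42113.03 EUR/year        # annualize(q), x4 convention
```

The DMT line dominates — the expected pattern for relapsing-remitting MS
in early disease, where therapy cost outweighs all service use combined.

## Command line

```sh
mshrs simulate --n 2000 --seed 1 --out sim/        # cohort + retest + truth
mshrs cost     --responses sim/cohort.csv --out costed/
mshrs validate --cohort sim/cohort.csv --retest sim/retest.csv --out report/
```

`cost` writes one tidy row per respondent-wave plus a cohort summary
(users n/%, mean, SD, median, IQR per item); `validate` writes a JSON and
a readable text report (ICC with band, λ2/λ6, known-group table,
correlation table).

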