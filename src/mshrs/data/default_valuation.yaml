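# Default German valuation tables, 2011 price level.
# Unit costs are societal opportunity-cost approximations; where a market
# price was unavailable the value was derived once at source and is carried
# here as a constant:
#   - nurse contact: rated with the lowest available monetary value
#   - psychologist contact: valued as a psychotherapist visit
#   - other specialists: mean of the example specialties
#   - examination "other": fee-schedule approximation, carried as a constant
# Update this file (or ship a sibling) to localise prices; the engine never
# hard-codes monetary constants.
reference_year: 2011
source: "German national unit costs, 2011 price level"

inpatient_per_day:
  hospital: 593.04
  rehabilitation: 121.85
  nursing: 69.80

day_admission_per_day:
  hospital: 385.48
  rehabilitation: 46.68
  nursing: 46.15

consultation_per_contact:
  general_practitioner: 20.06
  neurologist: 44.72
  other_specialist: 34.73
  nurse: 16.42
  physiotherapist: 16.42
  psychologist: 78.08
  occupational_therapist: 37.51
  optician: 34.78
  speech_therapist: 38.59
  acupuncturist: 18.24
  other_alternative: 27.40

examination_per_unit:
  mri: 120.21
  ct: 73.78
  lumbar_puncture: 38.90
  blood_test: 1.10
  other: 60.66

professional_care_per_hour: 27.57
informal_care_per_hour: 21.09
disability_pension_cap_per_year: 42045.38

labor_market:
  annual_work_hours: 1406.2
  annual_work_days: 233
  hourly_labor_cost: 29.90
  informal_care_cap_hours_per_week: 60
  standard_week_days: 5

price_adjustment:
  default_inflation_rate: 0.02
  eur_usd_rate: 1.392

# Annual net cost per disease-modifying therapy (defined daily dose x 365),
# by price year.  null = not on the market that year.
dmt_annual_costs:
  source: "annual DDD net costs 2010-2017"
  AVO: {2010: 18069.27, 2011: 18611.35, 2012: 18182.19, 2013: 17981.00,
        2014: 19437.31, 2015: 19333.96, 2016: 19247.42, 2017: 18865.10}
  REB: {2010: 22626.46, 2011: 23305.25, 2012: 22900.46, 2013: 22765.35,
        2014: 24432.98, 2015: 24155.25, 2016: 23987.27, 2017: 23529.38}
  BET: {2010: 17977.14, 2011: 18516.45, 2012: 18132.07, 2013: 17815.29,
        2014: 17601.95, 2015: 17517.70, 2016: 17384.09, 2017: 17047.81}
  EXT: {2010: 15528.45, 2011: 15994.30, 2012: 15604.68, 2013: 15431.93,
        2014: 15441.48, 2015: 15370.25, 2016: 14680.25, 2017: 15715.49}
  COP: {2010: 16623.45, 2011: 17122.15, 2012: 16377.93, 2013: 16197.00,
        2014: 17035.61, 2015: 16733.32, 2016: 16648.48, 2017: 16352.26}
  GIL: {2010: null, 2011: 26698.58, 2012: 25907.56, 2013: 22571.44,
        2014: 18965.36, 2015: 20393.73, 2016: 21516.72, 2017: 20784.68}
  TYS: {2010: 24625.10, 2011: 25363.85, 2012: 24586.58, 2013: 24214.41,
        2014: 26194.92, 2015: 24280.75, 2016: 23321.06, 2017: 22902.02}
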