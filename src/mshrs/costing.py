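"""Monetisation of survey responses: per-quarter cost breakdowns.

Each raw response is converted to EUR amounts per component following the
microcosting principle — every consumed resource is enumerated and priced
individually.  Count-based quantities reported over an arbitrary recall
window are first rescaled to a standard quarter (91.25 days = 365/4);
weekly-rate items use 13 whole weeks per quarter.  Productivity losses
follow the human-capital approach: any hour not worked is valued at the
average hourly labor cost.

Components whose inputs were unanswered propagate as *missing*, not zero:
subtotals then cover only the observed components and the breakdown is
marked incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    EXAM_TYPES,
    PROVIDER_TYPES,
    SurveyResponse,
    WARD_TYPES,
)
from .valuation import (
    DMTCostTable,
    LaborMarketParams,
    PriceAdjustment,
    ValuationTables,
    indexate,
)

DIRECT_MEDICAL_ITEMS = (
    "inpatient",
    "day_admission",
    "consultations",
    "examinations",
    "otc",
    "consumables",
    "professional_care",
)
DIRECT_NONMEDICAL_ITEMS = ("investments", "informal_care")
INDIRECT_ITEMS = ("absenteeism", "disability_pension", "presenteeism")
ALL_ITEMS = DIRECT_MEDICAL_ITEMS + DIRECT_NONMEDICAL_ITEMS + INDIRECT_ITEMS + ("dmt",)


@dataclass(frozen=True)
class PeriodModel:
    """Calendar conventions for the reporting quarter."""

    quarter_days: float = 91.25
    weeks_per_quarter: int = 13
    quarters_per_year: int = 4

    def __post_init__(self) -> None:
        if not np.isclose(self.quarter_days * self.quarters_per_year, 365.0):
            raise ValueError("quarter_days x quarters_per_year must equal 365")
        if self.weeks_per_quarter * 7 > 92:
            raise ValueError("weeks_per_quarter inconsistent with a quarter")


@dataclass(frozen=True)
class CostBreakdown:
    """Monetised costs (EUR) for one respondent-wave.

    ``None`` marks a component whose survey inputs were unanswered;
    subtotals sum only observed components and ``complete`` is False.
    """

    respondent_id: str
    period: str  # "quarter" or "year"
    items: Mapping[str, float | None]
    missing_components: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.items) - set(ALL_ITEMS)
        if unknown:
            raise ValueError(f"unknown cost items: {sorted(unknown)}")
        for name, v in self.items.items():
            if v is not None and v < -1e-9:
                raise ValueError(f"negative amount for {name}: {v}")
        if self.period not in ("quarter", "year"):
            raise ValueError("period must be 'quarter' or 'year'")

    def _sum(self, names: Sequence[str]) -> float:
        return float(sum(self.items.get(n) or 0.0 for n in names))

    @property
    def direct_medical_excl_dmt(self) -> float:
        return self._sum(DIRECT_MEDICAL_ITEMS)

    @property
    def direct_nonmedical(self) -> float:
        return self._sum(DIRECT_NONMEDICAL_ITEMS)

    @property
    def indirect(self) -> float:
        return self._sum(INDIRECT_ITEMS)

    @property
    def dmt(self) -> float:
        return float(self.items.get("dmt") or 0.0)

    @property
    def total_excl_dmt(self) -> float:
        return self.direct_medical_excl_dmt + self.direct_nonmedical + self.indirect

    @property
    def total_incl_dmt(self) -> float:
        return self.total_excl_dmt + self.dmt

    @property
    def complete(self) -> bool:
        return not self.missing_components

    def to_dict(self) -> dict[str, object]:
        row: dict[str, object] = {"respondent_id": self.respondent_id, "period": self.period}
        for name in ALL_ITEMS:
            row[name] = self.items.get(name)
        row["direct_medical_excl_dmt"] = self.direct_medical_excl_dmt
        row["direct_nonmedical"] = self.direct_nonmedical
        row["indirect"] = self.indirect
        row["total_excl_dmt"] = self.total_excl_dmt
        row["total_incl_dmt"] = self.total_incl_dmt
        row["complete"] = self.complete
        return row


def recall_scale(quantity: float, recall_days: float, period: PeriodModel) -> float:
    """Rescale a quantity reported over ``recall_days`` to one quarter."""
    if not (0 < recall_days <= 365):
        raise ValueError(f"recall window {recall_days} days outside (0, 365]")
    return quantity * period.quarter_days / recall_days


def _map_component(
    mapping: Mapping[str, int],
    keys: Sequence[str],
    prices: Mapping[str, float],
    prefix: str,
    resp: SurveyResponse,
    period: PeriodModel,
) -> tuple[float | None, set[str]]:
    """Price a count map, recall-scaled; fully-missing map -> None."""
    missing = {f"{prefix}.{k}" for k in keys if f"{prefix}.{k}" in resp.missing_flags}
    observed = [k for k in keys if f"{prefix}.{k}" not in resp.missing_flags]
    if not observed:
        return None, missing
    raw = sum(mapping.get(k, 0) * prices[k] for k in observed)
    return recall_scale(raw, resp.recall_days, period), missing


def direct_medical_cost(
    resp: SurveyResponse, tables: ValuationTables, period: PeriodModel = PeriodModel()
) -> tuple[dict[str, float | None], set[str]]:
    """Direct medical components (excluding DMT) in EUR per quarter.

    Counts are recall-scaled before pricing; out-of-pocket expenditures
    (over-the-counter medication, consumables) pass through as reported;
    professional care is a weekly rate priced over 13 weeks.
    """
    items: dict[str, float | None] = {}
    missing: set[str] = set()

    for name, attr, keys, prices in (
        ("inpatient", "inpatient_days", WARD_TYPES, tables.inpatient_per_day),
        ("day_admission", "day_admissions", WARD_TYPES, tables.day_admission_per_day),
        ("consultations", "consultations", PROVIDER_TYPES, tables.consultation_per_contact),
        ("examinations", "examinations", EXAM_TYPES, tables.examination_per_unit),
    ):
        value, miss = _map_component(getattr(resp, attr), keys, prices, attr, resp, period)
        items[name] = value
        missing |= miss

    for name, attr in (("otc", "otc_expenditure"), ("consumables", "consumables_expenditure")):
        if attr in resp.missing_flags:
            items[name] = None
            missing.add(attr)
        else:
            items[name] = float(getattr(resp, attr))

    if "professional_care_hours_per_week" in resp.missing_flags:
        items["professional_care"] = None
        missing.add("professional_care_hours_per_week")
    else:
        items["professional_care"] = (
            resp.professional_care_hours_per_week
            * tables.professional_care_per_hour
            * period.weeks_per_quarter
        )
    return items, missing


def dmt_cost_quarter(
    resp: SurveyResponse, dmt_table: DMTCostTable, year: int
) -> float | None:
    """Quarterly DMT cost: annual table value / 4; 0 without therapy."""
    if "dmt_name" in resp.missing_flags:
        return None
    if resp.dmt_name == "none":
        return 0.0
    return dmt_table.annual_cost(resp.dmt_name, year) / 4.0


def informal_care_cost(
    hours_per_week: float,
    tables: ValuationTables,
    period: PeriodModel = PeriodModel(),
) -> float:
    """Informal care per quarter, capped at 60 h/week (opportunity cost)."""
    if hours_per_week < 0:
        raise ValueError("hours must be nonnegative")
    cap = tables.labor.informal_care_cap_hours_per_week
    return min(hours_per_week, cap) * tables.informal_care_per_hour * period.weeks_per_quarter


def absenteeism_cost(sick_days: float, labor: LaborMarketParams) -> float:
    """Sick-leave loss: days x (annual hours / annual days) x hourly cost."""
    if sick_days < 0:
        raise ValueError("sick days must be nonnegative")
    return sick_days * labor.sick_leave_per_day


def disability_pension_cost(
    pct: float, labor: LaborMarketParams, period: PeriodModel = PeriodModel()
) -> float:
    """Quarterly share of the capped annual disability-pension loss."""
    if not (0 <= pct <= 100):
        raise ValueError("disability percentage must lie in [0, 100]")
    return pct / 100.0 * labor.annual_productivity_value / period.quarters_per_year


def presenteeism_cost(
    score: int,
    weekly_work_hours: float,
    sick_days: float,
    labor: LaborMarketParams,
    period: PeriodModel = PeriodModel(),
) -> float:
    """Reduced on-the-job productivity, valued over hours actually attended.

    A sick day removes ``weekly_work_hours / standard_week_days`` contracted
    hours from the quarter's base so absence and presenteeism never double
    count the same hour.  The 0-10 productivity-reduction score maps
    linearly to a lost fraction score/10.
    """
    if score not in range(0, 11):
        raise ValueError("presenteeism score must be an integer in 0..10")
    if weekly_work_hours < 0 or sick_days < 0:
        raise ValueError("hours and sick days must be nonnegative")
    attended = max(
        0.0,
        weekly_work_hours * period.weeks_per_quarter
        - sick_days * weekly_work_hours / labor.standard_week_days,
    )
    return score / 10.0 * attended * labor.hourly_labor_cost


def total_cost(
    resp: SurveyResponse,
    tables: ValuationTables,
    dmt_table: DMTCostTable | None = None,
    adj: PriceAdjustment | None = None,
    period: PeriodModel = PeriodModel(),
    include_dmt: bool = True,
    dmt_year: int | None = None,
) -> CostBreakdown:
    """Assemble the full per-quarter cost breakdown for one response.

    Reported expenditures (over-the-counter, consumables, investments) are
    indexated from the assessment year to the valuation reference year.
    Unanswered items propagate as missing components.
    """
    labor = tables.labor
    items, missing = direct_medical_cost(resp, tables, period)

    # price-level adjustment of patient-reported expenditures
    if adj is not None and resp.assessment_date is not None:
        factor = indexate(
            1.0, resp.assessment_date.year, tables.reference_year, adj.default_inflation_rate
        )
    else:
        factor = 1.0
    for name in ("otc", "consumables"):
        if items[name] is not None:
            items[name] = items[name] * factor

    if "investments_expenditure" in resp.missing_flags:
        items["investments"] = None
        missing.add("investments_expenditure")
    else:
        items["investments"] = resp.investments_expenditure * factor

    if "informal_care_hours_per_week" in resp.missing_flags:
        items["informal_care"] = None
        missing.add("informal_care_hours_per_week")
    else:
        items["informal_care"] = informal_care_cost(
            resp.informal_care_hours_per_week, tables, period
        )

    if "sick_days" in resp.missing_flags:
        items["absenteeism"] = None
        missing.add("sick_days")
        sick_q = 0.0
    else:
        sick_q = recall_scale(float(resp.sick_days), resp.recall_days, period)
        items["absenteeism"] = absenteeism_cost(sick_q, labor)

    if "disability_pension_pct" in resp.missing_flags:
        items["disability_pension"] = None
        missing.add("disability_pension_pct")
    else:
        items["disability_pension"] = disability_pension_cost(
            resp.disability_pension_pct, labor, period
        )

    pres_inputs_missing = {"presenteeism_score", "weekly_work_hours"} & resp.missing_flags
    if pres_inputs_missing or "sick_days" in resp.missing_flags:
        items["presenteeism"] = None
        missing |= pres_inputs_missing
    else:
        items["presenteeism"] = presenteeism_cost(
            resp.presenteeism_score, resp.weekly_work_hours, sick_q, labor, period
        )

    if include_dmt and dmt_table is not None:
        year = dmt_year if dmt_year is not None else tables.reference_year
        value = dmt_cost_quarter(resp, dmt_table, year)
        items["dmt"] = value
        if value is None:
            missing.add("dmt_name")
    else:
        items["dmt"] = 0.0

    return CostBreakdown(
        respondent_id=resp.respondent_id,
        period="quarter",
        items=items,
        missing_components=frozenset(missing),
    )


def annualize(q: CostBreakdown) -> CostBreakdown:
    """Scale a quarterly breakdown to a calendar year (x 4)."""
    if q.period != "quarter":
        raise ValueError("breakdown is already annual")
    items = {k: (None if v is None else v * 4.0) for k, v in q.items.items()}
    return replace(q, period="year", items=items)


# ---------------------------------------------------------------------------
# cohort-level reporting

def breakdowns_to_frame(breakdowns: Iterable[CostBreakdown]) -> pd.DataFrame:
    """Tidy table: one row per respondent-wave, one column per cost field."""
    return pd.DataFrame([b.to_dict() for b in breakdowns])


_SUMMARY_COLUMNS = list(ALL_ITEMS) + [
    "direct_medical_excl_dmt",
    "direct_nonmedical",
    "indirect",
    "total_excl_dmt",
    "total_incl_dmt",
]


def cohort_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-item user counts and distribution summaries for a costed cohort.

    A *user* of an item is a respondent with a positive observed amount.
    Statistics are computed over observed (non-missing) values only.
    """
    rows = []
    for name in _SUMMARY_COLUMNS:
        values = pd.to_numeric(frame[name], errors="coerce").dropna()
        n = len(values)
        users = int((values > 0).sum())
        q1, med, q3 = (
            values.quantile([0.25, 0.5, 0.75]) if n else (np.nan, np.nan, np.nan)
        )
        rows.append(
            {
                "item": name,
                "n_observed": n,
                "users_n": users,
                "users_pct": round(100.0 * users / n, 2) if n else np.nan,
                "mean": round(values.mean(), 2) if n else np.nan,
                "sd": round(values.std(ddof=1), 2) if n > 1 else np.nan,
                "median": round(med, 2) if n else np.nan,
                "iqr_low": round(q1, 2) if n else np.nan,
                "iqr_high": round(q3, 2) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
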