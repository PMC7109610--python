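"""Monetary constants and price transformations.

All monetary parameters — per-unit resource costs, annual
disease-modifying-therapy (DMT) costs, labor-market parameters for the
human-capital approach, and indexation/currency constants — live in a
versioned YAML config so that prices can be localised without touching
code.  The packaged default is the 2011 German table set.

Internal arithmetic is unrounded; rounding to cents happens only at
reporting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .schema import DMT_CODES, EXAM_TYPES, PROVIDER_TYPES, WARD_TYPES


class VocabularyError(KeyError):
    """Unknown cost category or item key."""


class NotAvailableError(ValueError):
    """A drug-year combination with no market price."""


class YearRangeError(ValueError):
    """A year outside the coverage of the DMT cost table."""


@dataclass(frozen=True)
class LaborMarketParams:
    """Labor-market inputs for human-capital valuation of lost work time."""

    annual_work_hours: float = 1406.2
    annual_work_days: float = 233.0
    hourly_labor_cost: float = 29.90
    informal_care_cap_hours_per_week: float = 60.0
    standard_week_days: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "annual_work_hours",
            "annual_work_days",
            "hourly_labor_cost",
            "informal_care_cap_hours_per_week",
            "standard_week_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.informal_care_cap_hours_per_week > 168:
            raise ValueError("informal care cap cannot exceed hours in a week")

    @property
    def sick_leave_per_day(self) -> float:
        """Daily productivity loss: (annual hours / annual days) x hourly cost."""
        return self.annual_work_hours / self.annual_work_days * self.hourly_labor_cost

    @property
    def annual_productivity_value(self) -> float:
        """Full-year productivity value: annual hours x hourly cost."""
        return self.annual_work_hours * self.hourly_labor_cost


@dataclass(frozen=True)
class PriceAdjustment:
    """Indexation and currency-conversion constants."""

    default_inflation_rate: float = 0.02
    eur_usd_rate: float = 1.392

    def __post_init__(self) -> None:
        if not (-0.5 < self.default_inflation_rate < 0.5):
            raise ValueError("inflation rate outside plausible range (-0.5, 0.5)")
        if self.eur_usd_rate <= 0:
            raise ValueError("exchange rate must be positive")


@dataclass(frozen=True)
class DMTCostTable:
    """Annual net cost in EUR per (drug, price year)."""

    costs: Mapping[str, Mapping[int, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, by_year in self.costs.items():
            if drug not in DMT_CODES or drug == "none":
                raise VocabularyError(f"unknown drug code {drug!r}")
            for year, value in by_year.items():
                if value is not None and value <= 0:
                    raise ValueError(f"nonpositive cost for {drug} {year}")

    @property
    def years(self) -> tuple[int, ...]:
        ys = sorted({y for by_year in self.costs.values() for y in by_year})
        return tuple(ys)

    def annual_cost(self, drug: str, year: int) -> float:
        if drug not in self.costs:
            raise VocabularyError(
                f"unknown drug {drug!r}; valid: {', '.join(sorted(self.costs))}"
            )
        by_year = self.costs[drug]
        if year not in by_year:
            ys = self.years
            raise YearRangeError(
                f"year {year} outside table coverage {ys[0]}-{ys[-1]}"
            )
        value = by_year[year]
        if value is None:
            raise NotAvailableError(f"{drug} has no price for {year}")
        return value


_CATEGORY_KEYS = {
    "inpatient": WARD_TYPES,
    "day_admission": WARD_TYPES,
    "consultation": PROVIDER_TYPES,
    "examination": EXAM_TYPES,
}


@dataclass(frozen=True)
class ValuationTables:
    """Unit costs in EUR at ``reference_year`` price level."""

    reference_year: int
    inpatient_per_day: Mapping[str, float]
    day_admission_per_day: Mapping[str, float]
    consultation_per_contact: Mapping[str, float]
    examination_per_unit: Mapping[str, float]
    professional_care_per_hour: float
    informal_care_per_hour: float
    disability_pension_cap_per_year: float
    labor: LaborMarketParams = field(default_factory=LaborMarketParams)
    source: str = ""

    def __post_init__(self) -> None:
        for name in (
            "inpatient_per_day",
            "day_admission_per_day",
            "consultation_per_contact",
            "examination_per_unit",
        ):
            for key, value in getattr(self, name).items():
                if value <= 0:
                    raise ValueError(f"{name}[{key}] must be strictly positive")
        for name in ("professional_care_per_hour", "informal_care_per_hour"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        cap = self.labor.annual_productivity_value
        if not math.isclose(cap, self.disability_pension_cap_per_year, abs_tol=0.005):
            raise ValueError(
                "disability pension cap inconsistent with labor parameters: "
                f"{self.disability_pension_cap_per_year} vs {cap:.4f}"
            )

    @property
    def sick_leave_per_day(self) -> float:
        return self.labor.sick_leave_per_day


def lookup_unit_cost(tables: ValuationTables, category: str, item: str) -> float:
    """Per-unit EUR cost for a resource item.

    Categories: inpatient / day_admission (per day), consultation (per
    contact), examination (per unit), professional_care / informal_care
    (per hour; item ignored).
    """
    if category == "professional_care":
        return tables.professional_care_per_hour
    if category == "informal_care":
        return tables.informal_care_per_hour
    if category not in _CATEGORY_KEYS:
        raise VocabularyError(
            f"unknown category {category!r}; valid: "
            f"{', '.join(list(_CATEGORY_KEYS) + ['professional_care', 'informal_care'])}"
        )
    table = {
        "inpatient": tables.inpatient_per_day,
        "day_admission": tables.day_admission_per_day,
        "consultation": tables.consultation_per_contact,
        "examination": tables.examination_per_unit,
    }[category]
    if item not in table:
        raise VocabularyError(
            f"unknown {category} item {item!r}; valid: {', '.join(table)}"
        )
    return table[item]


def dmt_annual_cost(table: DMTCostTable, drug: str, year: int) -> float:
    """Annual EUR cost of a disease-modifying therapy for a price year."""
    return table.annual_cost(drug, year)


def indexate(amount: float, from_year: int, to_year: int, rate: float = 0.02) -> float:
    """Move an amount between price levels: amount x (1+rate)^(to-from)."""
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    return amount * (1.0 + rate) ** (to_year - from_year)


def convert_eur_usd(amount: float, adj: PriceAdjustment) -> float:
    """Convert EUR to USD at the configured annual average exchange rate."""
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    return amount * adj.eur_usd_rate


def load_valuation(
    path: str | Path | None = None,
) -> tuple[ValuationTables, DMTCostTable, PriceAdjustment]:
    """Load valuation config from YAML; packaged 2011 defaults if no path."""
    if path is None:
        text = (
            resources.files("mshrs.data").joinpath("default_valuation.yaml").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)

    labor = LaborMarketParams(**raw["labor_market"])
    tables = ValuationTables(
        reference_year=int(raw["reference_year"]),
        inpatient_per_day=dict(raw["inpatient_per_day"]),
        day_admission_per_day=dict(raw["day_admission_per_day"]),
        consultation_per_contact=dict(raw["consultation_per_contact"]),
        examination_per_unit=dict(raw["examination_per_unit"]),
        professional_care_per_hour=float(raw["professional_care_per_hour"]),
        informal_care_per_hour=float(raw["informal_care_per_hour"]),
        disability_pension_cap_per_year=float(raw["disability_pension_cap_per_year"]),
        labor=labor,
        source=str(raw.get("source", "")),
    )
    dmt_raw = dict(raw["dmt_annual_costs"])
    dmt_raw.pop("source", None)
    dmt = DMTCostTable(
        costs={
            drug: {int(y): (None if v is None else float(v)) for y, v in by_year.items()}
            for drug, by_year in dmt_raw.items()
        }
    )
    adj = PriceAdjustment(**raw["price_adjustment"])
    return tables, dmt, adj
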