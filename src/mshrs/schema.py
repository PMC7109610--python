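"""Data model for MS-HRS respondent records.

The survey collects, per respondent and assessment wave, raw resource-use
quantities over a recall window: inpatient and day-admission days by ward
type, outpatient consultations by provider, examinations by modality,
out-of-pocket expenditures, care hours, and employment/productivity items.
A companion clinical record carries age, sex, EDSS, relapse history,
employment status and optional patient-reported-outcome (PRO) summary
scores.

Missing answers are first-class: an unanswered item is recorded in
``missing_flags`` and never silently coerced to zero, because downstream
analyses make no imputations.  In the CSV dialect an empty cell means
missing while an explicit ``0`` is a true zero (the electronic survey's
adaptive skip logic produces true zeros for gated follow-up items).
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import math
from dataclasses import dataclass, field, fields as _dc_fields
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

WARD_TYPES = ("hospital", "rehabilitation", "nursing")
PROVIDER_TYPES = (
    "general_practitioner",
    "neurologist",
    "other_specialist",
    "nurse",
    "physiotherapist",
    "psychologist",
    "occupational_therapist",
    "optician",
    "speech_therapist",
    "acupuncturist",
    "other_alternative",
)
EXAM_TYPES = ("mri", "ct", "lumbar_puncture", "blood_test", "other")
DMT_CODES = ("AVO", "REB", "BET", "EXT", "COP", "GIL", "TYS", "none")

#: scalar survey items that may carry a missing flag
SCALAR_ITEMS = (
    "otc_expenditure",
    "consumables_expenditure",
    "professional_care_hours_per_week",
    "informal_care_hours_per_week",
    "investments_expenditure",
    "weekly_work_hours",
    "sick_days",
    "presenteeism_score",
    "disability_pension_pct",
    "dmt_name",
)

_MAP_FIELDS = {
    "inpatient_days": WARD_TYPES,
    "day_admissions": WARD_TYPES,
    "consultations": PROVIDER_TYPES,
    "examinations": EXAM_TYPES,
}

MAX_RECALL_DAYS = 365.0  # recall windows are capped at 12 months
MAX_WEEK_HOURS = 168.0


class SchemaError(ValueError):
    """Raised when a record violates the survey data model."""

    def __init__(self, message: str, *, row: object = None, field: str | None = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"record {row!r}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


@dataclass
class SurveyResponse:
    """One respondent-wave's raw answers to the cost items."""

    respondent_id: str
    wave: int = 0
    assessment_date: _dt.date | None = None
    recall_days: float = 91.25
    inpatient_days: dict[str, int] = field(default_factory=dict)
    day_admissions: dict[str, int] = field(default_factory=dict)
    consultations: dict[str, int] = field(default_factory=dict)
    examinations: dict[str, int] = field(default_factory=dict)
    otc_expenditure: float | None = 0.0
    consumables_expenditure: float | None = 0.0
    professional_care_hours_per_week: float | None = 0.0
    informal_care_hours_per_week: float | None = 0.0
    investments_expenditure: float | None = 0.0
    weekly_work_hours: float | None = 0.0
    sick_days: int | None = 0
    presenteeism_score: int | None = 0
    disability_pension_pct: float | None = 0.0
    dmt_name: str | None = "none"
    missing_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.missing_flags = frozenset(self.missing_flags)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        rid = self.respondent_id
        if self.wave < 0 or int(self.wave) != self.wave:
            raise SchemaError("wave must be a nonnegative integer", row=rid, field="wave")
        if not (0 < self.recall_days <= MAX_RECALL_DAYS):
            raise SchemaError(
                f"recall window of {self.recall_days} days is outside (0, 365]",
                row=rid,
                field="recall_days",
            )
        for name, keys in _MAP_FIELDS.items():
            mapping = getattr(self, name)
            for key, value in mapping.items():
                if key not in keys:
                    raise SchemaError(
                        f"unknown key '{key}' (valid: {', '.join(keys)})",
                        row=rid,
                        field=name,
                    )
                flag = f"{name}.{key}"
                if flag in self.missing_flags:
                    raise SchemaError(
                        "item both flagged missing and carrying a value",
                        row=rid,
                        field=flag,
                    )
                if value is None or value < 0 or int(value) != value:
                    raise SchemaError(
                        f"count must be a nonnegative integer, got {value!r}",
                        row=rid,
                        field=flag,
                    )
            # canonical form: every unflagged key carries an explicit count
            normalized = {
                k: int(mapping.get(k, 0))
                for k in keys
                if f"{name}.{k}" not in self.missing_flags
            }
            object.__setattr__(self, name, normalized)
        for name in SCALAR_ITEMS:
            value = getattr(self, name)
            flagged = name in self.missing_flags
            if flagged and value is not None:
                raise SchemaError(
                    "item both flagged missing and carrying a value", row=rid, field=name
                )
            if not flagged and value is None:
                raise SchemaError(
                    "unanswered item must be listed in missing_flags", row=rid, field=name
                )
        known_flags = set(SCALAR_ITEMS) | {
            f"{name}.{key}" for name, keys in _MAP_FIELDS.items() for key in keys
        }
        for flag in self.missing_flags:
            if flag not in known_flags:
                raise SchemaError(f"unknown missing flag '{flag}'", row=rid, field=flag)
        self._check_numeric_ranges(rid)

    def _check_numeric_ranges(self, rid: str) -> None:
        def chk(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise SchemaError(msg, row=rid, field=name)

        for name in (
            "otc_expenditure",
            "consumables_expenditure",
            "investments_expenditure",
        ):
            v = getattr(self, name)
            if v is not None:
                chk(v >= 0, name, f"money amount must be >= 0, got {v}")
        for name in (
            "professional_care_hours_per_week",
            "informal_care_hours_per_week",
            "weekly_work_hours",
        ):
            v = getattr(self, name)
            if v is not None:
                chk(0 <= v <= MAX_WEEK_HOURS, name, f"weekly hours must be in [0, 168], got {v}")
        if self.sick_days is not None:
            chk(
                self.sick_days >= 0 and int(self.sick_days) == self.sick_days,
                "sick_days",
                f"sick days must be a nonnegative integer, got {self.sick_days}",
            )
        if self.presenteeism_score is not None:
            chk(
                self.presenteeism_score in range(0, 11),
                "presenteeism_score",
                f"presenteeism score must be an integer in 0..10, got {self.presenteeism_score}",
            )
        if self.disability_pension_pct is not None:
            chk(
                0 <= self.disability_pension_pct <= 100,
                "disability_pension_pct",
                f"disability pension must be a percentage in [0, 100], got {self.disability_pension_pct}",
            )
        if self.dmt_name is not None and self.dmt_name not in DMT_CODES:
            raise SchemaError(
                f"unknown DMT code {self.dmt_name!r} (valid: {', '.join(DMT_CODES)})",
                row=rid,
                field="dmt_name",
            )

    def is_missing(self, item: str) -> bool:
        return item in self.missing_flags


@dataclass
class RespondentRecord:
    """Clinical and demographic companion record for one respondent."""

    respondent_id: str
    age: float | None = None
    sex: str | None = None
    edss: float | None = None
    relapses_last_year: int | None = None
    disease_duration_years: float | None = None
    employed: bool = False
    full_time: bool = False
    completed_survey: bool = True
    pro_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rid = self.respondent_id
        if self.edss is not None:
            if not (0 <= self.edss <= 10) or not math.isclose(
                self.edss * 2, round(self.edss * 2), abs_tol=1e-9
            ):
                raise SchemaError(
                    f"EDSS must be a multiple of 0.5 in [0, 10], got {self.edss}",
                    row=rid,
                    field="edss",
                )
        if self.relapses_last_year is not None and self.relapses_last_year < 0:
            raise SchemaError("relapse count must be >= 0", row=rid, field="relapses_last_year")
        if self.full_time and not self.employed:
            raise SchemaError("full_time implies employed", row=rid, field="full_time")

    @property
    def edss_in_validation_range(self) -> bool:
        """Validation analyses are restricted to EDSS 0-6.0."""
        return self.edss is not None and self.edss <= 6.0


# ---------------------------------------------------------------------------
# serialisation

_RESP_BOOL_FIELDS = ("employed", "full_time", "completed_survey")
_RESP_SCALAR_FIELDS = ("age", "sex", "edss", "relapses_last_year", "disease_duration_years")


def _survey_columns() -> list[str]:
    cols = ["respondent_id", "wave", "assessment_date", "recall_days"]
    for name, keys in _MAP_FIELDS.items():
        cols += [f"{name}_{k}" for k in keys]
    cols += list(SCALAR_ITEMS)
    return cols


def _respondent_columns(pro_names: Sequence[str]) -> list[str]:
    return list(_RESP_SCALAR_FIELDS) + list(_RESP_BOOL_FIELDS) + [f"pro_{p}" for p in pro_names]


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _survey_row(resp: SurveyResponse) -> dict[str, str]:
    row: dict[str, str] = {
        "respondent_id": resp.respondent_id,
        "wave": str(resp.wave),
        "assessment_date": resp.assessment_date.isoformat() if resp.assessment_date else "",
        "recall_days": _fmt(resp.recall_days),
    }
    for name, keys in _MAP_FIELDS.items():
        mapping = getattr(resp, name)
        for k in keys:
            col = f"{name}_{k}"
            if f"{name}.{k}" in resp.missing_flags:
                row[col] = ""
            else:
                row[col] = _fmt(mapping.get(k, 0))
    for name in SCALAR_ITEMS:
        row[name] = "" if name in resp.missing_flags else _fmt(getattr(resp, name))
    return row


def _respondent_row(rec: RespondentRecord, pro_names: Sequence[str]) -> dict[str, str]:
    row = {name: _fmt(getattr(rec, name)) for name in _RESP_SCALAR_FIELDS}
    row.update({name: _fmt(getattr(rec, name)) for name in _RESP_BOOL_FIELDS})
    for p in pro_names:
        row[f"pro_{p}"] = _fmt(rec.pro_scores.get(p))
    return row


def _parse_int(text: str, row: str, col: str) -> int:
    try:
        f = float(text)
    except ValueError:
        raise SchemaError(f"cannot parse {text!r} as integer", row=row, field=col) from None
    if f != int(f):
        raise SchemaError(f"expected integer, got {text!r}", row=row, field=col)
    return int(f)


def _parse_float(text: str, row: str, col: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"cannot parse {text!r} as number", row=row, field=col) from None


def _parse_bool(text: str, row: str, col: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise SchemaError(f"cannot parse {text!r} as boolean", row=row, field=col)


def _survey_from_row(row: Mapping[str, str]) -> SurveyResponse:
    rid = str(row.get("respondent_id", "")).strip()
    if not rid:
        raise SchemaError("missing respondent_id", row=row.get("respondent_id"))
    missing: set[str] = set()
    kwargs: dict[str, object] = {"respondent_id": rid}
    wave = str(row.get("wave", "0")).strip()
    kwargs["wave"] = _parse_int(wave, rid, "wave") if wave else 0
    date_text = str(row.get("assessment_date", "")).strip()
    kwargs["assessment_date"] = _dt.date.fromisoformat(date_text) if date_text else None
    recall = str(row.get("recall_days", "")).strip()
    if not recall:
        raise SchemaError("recall_days is required", row=rid, field="recall_days")
    kwargs["recall_days"] = _parse_float(recall, rid, "recall_days")
    for name, keys in _MAP_FIELDS.items():
        mapping: dict[str, int] = {}
        for k in keys:
            col = f"{name}_{k}"
            text = str(row.get(col, "")).strip()
            if text == "":
                missing.add(f"{name}.{k}")
            else:
                mapping[k] = _parse_int(text, rid, col)
        kwargs[name] = mapping
    int_items = ("sick_days", "presenteeism_score")
    for name in SCALAR_ITEMS:
        text = str(row.get(name, "")).strip()
        if text == "":
            missing.add(name)
            kwargs[name] = None
        elif name == "dmt_name":
            kwargs[name] = text
        elif name in int_items:
            kwargs[name] = _parse_int(text, rid, name)
        else:
            kwargs[name] = _parse_float(text, rid, name)
    kwargs["missing_flags"] = frozenset(missing)
    return SurveyResponse(**kwargs)


def _respondent_from_row(row: Mapping[str, str], rid: str) -> RespondentRecord:
    kwargs: dict[str, object] = {"respondent_id": rid}
    for name in _RESP_SCALAR_FIELDS:
        text = str(row.get(name, "")).strip()
        if text == "":
            kwargs[name] = None
        elif name == "sex":
            kwargs[name] = text
        elif name == "relapses_last_year":
            kwargs[name] = _parse_int(text, rid, name)
        else:
            kwargs[name] = _parse_float(text, rid, name)
    for name in _RESP_BOOL_FIELDS:
        kwargs[name] = _parse_bool(str(row.get(name, "")), rid, name)
    pro: dict[str, float] = {}
    for col, text in row.items():
        if col.startswith("pro_") and str(text).strip() != "":
            pro[col[4:]] = _parse_float(str(text), rid, col)
    kwargs["pro_scores"] = pro
    return RespondentRecord(**kwargs)


def _detect_format(path: Path, format: str | None) -> str:
    if format:
        return format
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_responses(
    path: str | Path, format: str | None = None
) -> list[tuple[SurveyResponse, RespondentRecord]]:
    """Read respondent records from CSV or JSON.

    Empty CSV cells (or absent JSON keys) become ``missing_flags`` entries;
    they are never interpreted as zeros.  Any record violating a model
    invariant raises :class:`SchemaError` naming the record and field.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    records: list[tuple[SurveyResponse, RespondentRecord]] = []
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                resp = _survey_from_row(row)
                rec = _respondent_from_row(row, resp.respondent_id)
                records.append((resp, rec))
    elif fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        for obj in payload:
            records.append(_pair_from_json(obj))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return records


def _pair_from_json(obj: Mapping) -> tuple[SurveyResponse, RespondentRecord]:
    survey = dict(obj.get("survey", obj))
    respondent = dict(obj.get("respondent", {}))
    rid = str(survey.get("respondent_id", "")).strip()
    if not rid:
        raise SchemaError("missing respondent_id", row=survey.get("respondent_id"))
    missing: set[str] = set()
    kwargs: dict[str, object] = {"respondent_id": rid}
    kwargs["wave"] = int(survey.get("wave", 0))
    date_text = survey.get("assessment_date")
    kwargs["assessment_date"] = _dt.date.fromisoformat(date_text) if date_text else None
    if "recall_days" not in survey:
        raise SchemaError("recall_days is required", row=rid, field="recall_days")
    kwargs["recall_days"] = float(survey["recall_days"])
    for name, keys in _MAP_FIELDS.items():
        given = dict(survey.get(name, {}))
        mapping = {}
        for k in keys:
            if k in given:
                mapping[k] = given[k]
            else:
                missing.add(f"{name}.{k}")
        for k in given:
            if k not in keys:
                raise SchemaError(f"unknown key '{k}'", row=rid, field=name)
        kwargs[name] = mapping
    for name in SCALAR_ITEMS:
        if name in survey and survey[name] is not None:
            kwargs[name] = survey[name]
        else:
            kwargs[name] = None
            missing.add(name)
    kwargs["missing_flags"] = frozenset(missing)
    resp = SurveyResponse(**kwargs)

    rk: dict[str, object] = {"respondent_id": rid}
    for name in _RESP_SCALAR_FIELDS:
        rk[name] = respondent.get(name)
    for name in _RESP_BOOL_FIELDS:
        rk[name] = bool(respondent.get(name, False))
    rk["pro_scores"] = dict(respondent.get("pro_scores", {}))
    return resp, RespondentRecord(**rk)


def _pair_to_json(resp: SurveyResponse, rec: RespondentRecord) -> dict:
    survey: dict[str, object] = {
        "respondent_id": resp.respondent_id,
        "wave": resp.wave,
        "recall_days": resp.recall_days,
    }
    if resp.assessment_date:
        survey["assessment_date"] = resp.assessment_date.isoformat()
    for name, keys in _MAP_FIELDS.items():
        survey[name] = {
            k: getattr(resp, name).get(k, 0)
            for k in keys
            if f"{name}.{k}" not in resp.missing_flags
        }
    for name in SCALAR_ITEMS:
        if name not in resp.missing_flags:
            survey[name] = getattr(resp, name)
    respondent: dict[str, object] = {}
    for name in _RESP_SCALAR_FIELDS:
        if getattr(rec, name) is not None:
            respondent[name] = getattr(rec, name)
    for name in _RESP_BOOL_FIELDS:
        respondent[name] = getattr(rec, name)
    if rec.pro_scores:
        respondent["pro_scores"] = dict(rec.pro_scores)
    return {"survey": survey, "respondent": respondent}


def write_responses(
    path: str | Path,
    records: Iterable[tuple[SurveyResponse, RespondentRecord]],
    format: str | None = None,
) -> None:
    """Write records to CSV (empty cell = missing) or JSON (absent key = missing)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    records = list(records)
    if fmt == "json":
        payload = [_pair_to_json(resp, rec) for resp, rec in records]
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return
    pro_names = sorted({p for _, rec in records for p in rec.pro_scores})
    columns = _survey_columns() + _respondent_columns(pro_names)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for resp, rec in records:
            row = _survey_row(resp)
            row.update(_respondent_row(rec, pro_names))
            writer.writerow(row)


def completion_rate(records: Sequence[RespondentRecord]) -> Fraction:
    """Share of respondents who completed the survey, as an exact fraction."""
    if not records:
        raise ValueError("completion_rate requires a nonempty record list")
    done = sum(1 for r in records if r.completed_survey)
    return Fraction(done, len(records))
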