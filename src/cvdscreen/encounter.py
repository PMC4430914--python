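"""Participant encounter records for door-to-door CVD screening.

A screening encounter is acquired in four steps: (1) demographics,
(2) medical history, (3) risk-factor measurements, (4) decision support.
This module houses the record types for steps 1-3, on-screen style
validation of each step, and the small derived quantities the decision
support consumes: body-mass index, a representative blood-pressure pair
summarised from up to three cuff readings, and age estimated from a
remembered historical event for participants who do not know their year
of birth.

All record types are frozen dataclasses; validation never mutates a
record.  Medical-history flags are tri-state (``True`` / ``False`` /
``None`` = unknown); downstream rules treat unknown as "no" but the
stored value is preserved for audit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

TriState = Optional[bool]

GENDERS = ("male", "female")
GLUCOSE_TYPES = ("fasting", "random")


@dataclass(frozen=True)
class ValidationRanges:
    """Clinically plausible bounds used by the on-screen checks.

    The defaults are deliberately wide: the validator exists to catch
    transcription errors (a glucose of 9999 mg/dL), not to second-guess
    genuinely extreme physiology.  All bounds are (low, high) inclusive.
    """

    age: tuple[float, float] = (18, 120)
    sbp: tuple[float, float] = (60, 300)
    dbp: tuple[float, float] = (30, 200)
    glucose: tuple[float, float] = (20, 600)
    tc: tuple[float, float] = (50, 500)
    hdl: tuple[float, float] = (10, 150)
    ldl: tuple[float, float] = (20, 400)
    tg: tuple[float, float] = (20, 1000)
    height: tuple[float, float] = (100, 250)
    weight: tuple[float, float] = (20, 250)


DEFAULT_RANGES = ValidationRanges()


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    age: int
    gender: str
    location: str = ""
    name: str = ""


@dataclass(frozen=True)
class MedicalHistory:
    past_mi_angina: TriState = None
    past_stroke: TriState = None
    past_pvd: TriState = None
    past_diabetes: TriState = None
    family_mi_angina: TriState = None
    family_stroke: TriState = None
    family_diabetes: TriState = None
    # not on the printed acquisition list, but the hypertension
    # sub-condition requires it
    hypertension_history: TriState = None
    on_bp_lowering: TriState = None
    on_lipid_lowering: TriState = None
    on_antiplatelet: TriState = None
    target_sbp: Optional[float] = None
    target_dbp: Optional[float] = None

    @property
    def past_cvd(self) -> bool:
        """Any prior MI/angina, stroke or peripheral vascular disease."""
        return bool(self.past_mi_angina) or bool(self.past_stroke) or bool(self.past_pvd)


@dataclass(frozen=True)
class RiskFactorProfile:
    """Step-3 measurements plus references to steps 1-2.

    ``sbp``/``dbp`` hold a single representative pair; ``bp_readings``
    holds the raw cuff readings (up to three) when available.  All lipid
    fields and glucose are mg/dL; height cm; weight kg.
    """

    demographics: Demographics
    history: MedicalHistory = field(default_factory=MedicalHistory)
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    bp_readings: tuple[tuple[float, float], ...] = ()
    glucose_value: Optional[float] = None
    glucose_type: Optional[str] = None
    tc: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    tg: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    smoker: bool = False


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    violations: tuple[tuple[str, object, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "valid", not self.violations)


def _check_range(field_name: str, value, bounds, violations: list) -> None:
    if value is None:
        return
    lo, hi = bounds
    if not (lo <= value <= hi):
        violations.append((field_name, value, f"range {lo}-{hi}"))


def validate_step(
    profile: RiskFactorProfile,
    step_id: int,
    ranges: ValidationRanges = DEFAULT_RANGES,
) -> ValidationResult:
    """Run the on-screen checks for one acquisition step.

    Returns every violation found (field, offending value, rule); the
    profile is never modified.  Step 4 carries no user-entered inputs,
    so it always validates.

    Raises
    ------
    ValueError
        If ``step_id`` is not 1-4 (a caller bug, not a data error).
    """
    if step_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown step_id {step_id!r}; must be 1-4")
    violations: list[tuple[str, object, str]] = []
    if step_id == 1:
        demo = profile.demographics
        if not demo.patient_id:
            violations.append(("patient_id", demo.patient_id, "non-empty"))
        if demo.gender not in GENDERS:
            violations.append(("gender", demo.gender, "one of male/female"))
        _check_range("age", demo.age, ranges.age, violations)
    elif step_id == 2:
        hist = profile.history
        _check_range("target_sbp", hist.target_sbp, ranges.sbp, violations)
        _check_range("target_dbp", hist.target_dbp, ranges.dbp, violations)
        if (
            hist.target_sbp is not None
            and hist.target_dbp is not None
            and hist.target_sbp <= hist.target_dbp
        ):
            violations.append(
                ("target_sbp", (hist.target_sbp, hist.target_dbp), "sbp>dbp")
            )
    elif step_id == 3:
        _check_range("sbp", profile.sbp, ranges.sbp, violations)
        _check_range("dbp", profile.dbp, ranges.dbp, violations)
        if (
            profile.sbp is not None
            and profile.dbp is not None
            and profile.sbp <= profile.dbp
        ):
            violations.append(("sbp", (profile.sbp, profile.dbp), "sbp>dbp"))
        if len(profile.bp_readings) > 3:
            violations.append(
                ("bp_readings", len(profile.bp_readings), "at most 3 readings")
            )
        for i, (s, d) in enumerate(profile.bp_readings):
            _check_range(f"bp_readings[{i}].sbp", s, ranges.sbp, violations)
            _check_range(f"bp_readings[{i}].dbp", d, ranges.dbp, violations)
            if s <= d:
                violations.append((f"bp_readings[{i}]", (s, d), "sbp>dbp"))
        _check_range("glucose_value", profile.glucose_value, ranges.glucose, violations)
        if profile.glucose_value is not None and profile.glucose_type not in GLUCOSE_TYPES:
            violations.append(
                ("glucose_type", profile.glucose_type, "fasting or random required")
            )
        _check_range("tc", profile.tc, ranges.tc, violations)
        _check_range("hdl", profile.hdl, ranges.hdl, violations)
        _check_range("ldl", profile.ldl, ranges.ldl, violations)
        _check_range("tg", profile.tg, ranges.tg, violations)
        _check_range("height", profile.height, ranges.height, violations)
        _check_range("weight", profile.weight, ranges.weight, violations)
    return ValidationResult(valid=not violations, violations=tuple(violations))


def validate_all(
    profile: RiskFactorProfile, ranges: ValidationRanges = DEFAULT_RANGES
) -> ValidationResult:
    """Validate every step; union of violations."""
    violations: list[tuple[str, object, str]] = []
    for step in (1, 2, 3, 4):
        violations.extend(validate_step(profile, step, ranges).violations)
    return ValidationResult(valid=not violations, violations=tuple(violations))


def compute_bmi(height_cm: float, weight_kg: float, decimals: Optional[int] = 1) -> float:
    """Body-mass index, kg/m².

    Reported to one decimal place by default; pass ``decimals=None`` for
    the unrounded value (category thresholds are applied unrounded to
    avoid boundary artefacts).
    """
    if height_cm is None or height_cm <= 0:
        raise ValueError(f"height must be positive, got {height_cm!r}")
    if weight_kg is None or weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg!r}")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    return round(bmi, decimals) if decimals is not None else bmi


def summarize_bp(
    bp_readings: Sequence[tuple[float, float]]
) -> tuple[int, int]:
    """Collapse up to three cuff readings to one representative pair.

    With three readings the first is discarded (acclimatisation) and the
    last two averaged; with one or two, all are averaged.  Output is
    rounded half-up to integer mmHg so the result is deterministic.
    """
    if not bp_readings:
        raise ValueError("at least one BP reading required")
    if len(bp_readings) > 3:
        raise ValueError("at most three BP readings expected")
    used = bp_readings[-2:] if len(bp_readings) == 3 else bp_readings
    sbp = sum(r[0] for r in used) / len(used)
    dbp = sum(r[1] for r in used) / len(used)
    half_up = lambda x: int(math.floor(x + 0.5))
    return half_up(sbp), half_up(dbp)


def effective_bp(profile: RiskFactorProfile) -> tuple[Optional[float], Optional[float]]:
    """The BP pair fed to the risk chart and rules.

    The summarised cuff readings when present, otherwise the single
    stored pair.
    """
    if profile.bp_readings:
        return summarize_bp(profile.bp_readings)
    return profile.sbp, profile.dbp


def estimate_age_from_event(
    event_year: int, age_at_event: int, current_year: int
) -> int:
    """Estimate current age from a remembered historical event.

    Participants who do not know their year of birth often remember how
    old they were at a well-known event (e.g. Indian Independence,
    1947).  Age = current_year - (event_year - age_at_event).
    """
    if age_at_event < 0:
        raise ValueError("age at event cannot be negative")
    if event_year > current_year:
        raise ValueError("event year is in the future")
    birth_year = event_year - age_at_event
    if birth_year < 0:
        raise ValueError(f"inferred birth year {birth_year} is negative")
    if birth_year > current_year:
        raise ValueError("inferred birth year is in the future")
    return current_year - birth_year


# ---------------------------------------------------------------------------
# serialization: nested JSON for single encounters, flat dict for CSV rows

def profile_to_dict(profile: RiskFactorProfile) -> dict:
    d = asdict(profile)
    d["bp_readings"] = [list(r) for r in profile.bp_readings]
    return d


def profile_from_dict(d: dict) -> RiskFactorProfile:
    demo = Demographics(**d["demographics"])
    hist = MedicalHistory(**d.get("history", {}))
    rest = {
        k: v
        for k, v in d.items()
        if k not in ("demographics", "history", "bp_readings")
    }
    readings = tuple(tuple(r) for r in d.get("bp_readings", ()))
    return RiskFactorProfile(
        demographics=demo, history=hist, bp_readings=readings, **rest
    )


def profile_to_json(profile: RiskFactorProfile) -> str:
    return json.dumps(profile_to_dict(profile), indent=2, sort_keys=True)


def profile_from_json(text: str) -> RiskFactorProfile:
    return profile_from_dict(json.loads(text))


#: flat CSV columns for cohort files, in order
FLAT_COLUMNS = [
    "patient_id", "age", "gender", "location", "name",
    "past_mi_angina", "past_stroke", "past_pvd", "past_diabetes",
    "family_mi_angina", "family_stroke", "family_diabetes",
    "hypertension_history", "on_bp_lowering", "on_lipid_lowering",
    "on_antiplatelet", "target_sbp", "target_dbp",
    "sbp", "dbp", "sbp1", "dbp1", "sbp2", "dbp2", "sbp3", "dbp3",
    "glucose_value", "glucose_type", "tc", "hdl", "ldl", "tg",
    "height", "weight", "smoker",
]

_BOOL_COLS = [
    "past_mi_angina", "past_stroke", "past_pvd", "past_diabetes",
    "family_mi_angina", "family_stroke", "family_diabetes",
    "hypertension_history", "on_bp_lowering", "on_lipid_lowering",
    "on_antiplatelet", "smoker",
]


def profile_to_row(profile: RiskFactorProfile) -> dict:
    """One flat CSV row per participant; tri-state booleans as yes/no/''."""
    row: dict = {c: "" for c in FLAT_COLUMNS}
    demo, hist = profile.demographics, profile.history
    row.update(
        patient_id=demo.patient_id, age=demo.age, gender=demo.gender,
        location=demo.location, name=demo.name,
    )
    for c in _BOOL_COLS:
        v = getattr(hist, c, None) if c != "smoker" else profile.smoker
        row[c] = "" if v is None else ("yes" if v else "no")
    for c in ("target_sbp", "target_dbp"):
        v = getattr(hist, c)
        row[c] = "" if v is None else v
    for c in ("sbp", "dbp", "glucose_value", "glucose_type", "tc", "hdl",
              "ldl", "tg", "height", "weight"):
        v = getattr(profile, c)
        row[c] = "" if v is None else v
    for i, (s, d) in enumerate(profile.bp_readings[:3], start=1):
        row[f"sbp{i}"], row[f"dbp{i}"] = s, d
    return row


def profile_from_row(row: dict) -> RiskFactorProfile:
    def tri(v) -> TriState:
        if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
            return None
        if isinstance(v, bool):
            return v
        return str(v).strip().lower() in ("yes", "true", "1")

    def num(v) -> Optional[float]:
        if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    demo = Demographics(
        patient_id=str(row["patient_id"]),
        age=int(row["age"]),
        gender=str(row["gender"]),
        location=str(row.get("location", "") or ""),
        name=str(row.get("name", "") or ""),
    )
    hist = MedicalHistory(
        **{c: tri(row.get(c)) for c in _BOOL_COLS if c != "smoker"},
        target_sbp=num(row.get("target_sbp")),
        target_dbp=num(row.get("target_dbp")),
    )
    readings = []
    for i in (1, 2, 3):
        s, d = num(row.get(f"sbp{i}")), num(row.get(f"dbp{i}"))
        if s is not None and d is not None:
            readings.append((s, d))
    gtype = row.get("glucose_type")
    if gtype is not None and (gtype == "" or (isinstance(gtype, float) and math.isnan(gtype))):
        gtype = None
    return RiskFactorProfile(
        demographics=demo,
        history=hist,
        sbp=num(row.get("sbp")),
        dbp=num(row.get("dbp")),
        bp_readings=tuple(readings),
        glucose_value=num(row.get("glucose_value")),
        glucose_type=gtype if gtype is None else str(gtype),
        tc=num(row.get("tc")),
        hdl=num(row.get("hdl")),
        ldl=num(row.get("ldl")),
        tg=num(row.get("tg")),
        height=num(row.get("height")),
        weight=num(row.get("weight")),
        smoker=bool(tri(row.get("smoker"))),
    )


def write_cohort_csv(profiles: Sequence[RiskFactorProfile], path) -> None:
    """Write a flat one-row-per-participant cohort CSV."""
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.DictWriter(fh, fieldnames=FLAT_COLUMNS)
        writer.writeheader()
        for p in profiles:
            writer.writerow(profile_to_row(p))


def read_cohort_csv(path) -> list[RiskFactorProfile]:
    """Read a flat cohort CSV written by :func:`write_cohort_csv`."""
    import csv as _csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = _csv.DictReader(fh)
        return [profile_from_row(row) for row in reader]


__all__ = [
    "Demographics", "MedicalHistory", "RiskFactorProfile", "ValidationResult",
    "ValidationRanges", "DEFAULT_RANGES", "validate_step", "validate_all",
    "compute_bmi", "summarize_bp", "effective_bp", "estimate_age_from_event",
    "profile_to_dict", "profile_from_dict", "profile_to_json",
    "profile_from_json", "profile_to_row", "profile_from_row", "FLAT_COLUMNS",
    "write_cohort_csv", "read_cohort_csv",
]
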