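"""Chart-based 10-year absolute cardiovascular risk categorisation.

The WHO/ISH risk charts predict the 10-year risk of a fatal or
non-fatal cardiovascular event as one of five colour-coded bands
(<10%, 10-<20%, 20-<30%, 30-<40%, >=40%) from six categorical inputs:
diabetes status, gender, smoking status, age band, systolic blood
pressure band, and — in the High-Information (HI) chart variant —
total-cholesterol band.  The Low-Information (LI) variant omits
cholesterol and is used whenever cholesterol is unknown.

This engine is chart-agnostic: the cell values are loaded from a CSV
table (the published charts can be transcribed into the documented
dialect), and the repository ships clearly labelled *synthetic* fixture
charts for testing (see :mod:`cvdscreen.fixtures`).  Band edges follow
a half-open convention throughout: the lower edge of each band is
inclusive, the upper edge exclusive, and the topmost band is closed
above.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Mapping, Optional

from .encounter import RiskFactorProfile, effective_bp, validate_step


class RiskBand(IntEnum):
    """Five ordered 10-year absolute risk bands."""

    R0_10 = 0      # <10%
    R10_20 = 1     # 10 to <20%
    R20_30 = 2     # 20 to <30%
    R30_40 = 3     # 30 to <40%
    R40_PLUS = 4   # >=40%

    @property
    def lower_pct(self) -> int:
        """Lower edge of the band in percent (0, 10, 20, 30, 40)."""
        return self.value * 10


AGE_BANDS = ("40-49", "50-59", "60-69", "70+")
SBP_BANDS = ("lt140", "140-159", "160-179", "180+")
TC_BANDS = ("lt5", "5-6", "6-7", "7-8", "8+")
VARIANTS = ("LI", "HI")

#: mg/dL of total cholesterol per mmol/L (molar conversion)
MG_PER_MMOL_CHOL = 38.67

_AGE_EDGES = (40, 50, 60, 70)
_SBP_EDGES = (140, 160, 180)
_TC_EDGES_MMOL = (5.0, 6.0, 7.0, 8.0)

ChartKey = tuple[bool, str, bool, str, str, Optional[str]]


class ChartError(ValueError):
    """Raised when a chart file is malformed or incomplete."""


def age_band(age: float) -> tuple[str, bool]:
    """Band an age; ages below the chart range clamp to the lowest band.

    Returns (band label, clamped flag).
    """
    if age < _AGE_EDGES[0]:
        return AGE_BANDS[0], True
    for i, edge in enumerate(_AGE_EDGES[1:]):
        if age < edge:
            return AGE_BANDS[i], False
    return AGE_BANDS[-1], False


def sbp_band(sbp: float) -> str:
    for i, edge in enumerate(_SBP_EDGES):
        if sbp < edge:
            return SBP_BANDS[i]
    return SBP_BANDS[-1]


def tc_band_from_mmol(tc_mmol: float) -> str:
    for i, edge in enumerate(_TC_EDGES_MMOL):
        if tc_mmol < edge:
            return TC_BANDS[i]
    return TC_BANDS[-1]


def tc_band_from_mgdl(tc_mgdl: float) -> str:
    """Band a cholesterol stored in mg/dL against the mmol/L chart edges."""
    return tc_band_from_mmol(tc_mgdl / MG_PER_MMOL_CHOL)


@dataclass(frozen=True)
class ChartTable:
    """A total categorical lookup table for one chart variant.

    ``cells`` maps (diabetes, gender, smoker, age_band, sbp_band,
    tc_band-or-None) to a :class:`RiskBand`.  LI tables have
    ``tc_band=None`` in every key.  Totality over the declared band grid
    (128 LI cells, 640 HI cells) is enforced at construction.
    """

    region: str
    variant: str
    cells: Mapping[ChartKey, RiskBand]

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ChartError(f"unknown chart variant {self.variant!r}")
        missing = [k for k in iter_chart_keys(self.variant) if k not in self.cells]
        if missing:
            raise ChartError(
                f"{self.variant} chart is missing {len(missing)} cell(s), "
                f"first missing: {missing[0]}"
            )

    def lookup(self, key: ChartKey) -> RiskBand:
        return self.cells[key]


def iter_chart_keys(variant: str):
    """All cell keys of a chart's declared grid, in a stable order."""
    tc_bands: tuple[Optional[str], ...] = TC_BANDS if variant == "HI" else (None,)
    for diabetes in (False, True):
        for gender in ("male", "female"):
            for smoker in (False, True):
                for ab in AGE_BANDS:
                    for sb in SBP_BANDS:
                        for tb in tc_bands:
                            yield (diabetes, gender, smoker, ab, sb, tb)


_CHART_HEADER = [
    "region", "variant", "diabetes", "gender", "smoker",
    "age_band", "sbp_band", "tc_band", "category",
]


def _parse_bool(text: str, row_no: int, col: str) -> bool:
    t = text.strip().lower()
    if t in ("yes", "true", "1"):
        return True
    if t in ("no", "false", "0"):
        return False
    raise ChartError(f"row {row_no}: bad boolean {text!r} in column {col}")


def load_chart(path) -> ChartTable:
    """Load and totality-check a chart CSV.

    Dialect: header ``region,variant,diabetes,gender,smoker,age_band,
    sbp_band,tc_band,category``; LI rows carry ``NA`` in ``tc_band``.
    Duplicate cells, unknown labels and missing cells are load failures
    naming the offending row or cell.
    """
    cells: dict[ChartKey, RiskBand] = {}
    region = variant = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CHART_HEADER:
            raise ChartError(
                f"bad chart header {reader.fieldnames!r}; expected {_CHART_HEADER!r}"
            )
        for row_no, row in enumerate(reader, start=2):
            if region is None:
                region, variant = row["region"], row["variant"]
                if variant not in VARIANTS:
                    raise ChartError(f"row {row_no}: unknown variant {variant!r}")
            elif (row["region"], row["variant"]) != (region, variant):
                raise ChartError(f"row {row_no}: mixed region/variant in one file")
            if row["gender"] not in ("male", "female"):
                raise ChartError(f"row {row_no}: bad gender {row['gender']!r}")
            if row["age_band"] not in AGE_BANDS:
                raise ChartError(f"row {row_no}: bad age_band {row['age_band']!r}")
            if row["sbp_band"] not in SBP_BANDS:
                raise ChartError(f"row {row_no}: bad sbp_band {row['sbp_band']!r}")
            tc: Optional[str] = row["tc_band"]
            if variant == "LI":
                if tc != "NA":
                    raise ChartError(f"row {row_no}: LI chart requires tc_band=NA")
                tc = None
            elif tc not in TC_BANDS:
                raise ChartError(f"row {row_no}: bad tc_band {row['tc_band']!r}")
            try:
                band = RiskBand[row["category"]]
            except KeyError:
                raise ChartError(
                    f"row {row_no}: unknown band label {row['category']!r}"
                ) from None
            key: ChartKey = (
                _parse_bool(row["diabetes"], row_no, "diabetes"),
                row["gender"],
                _parse_bool(row["smoker"], row_no, "smoker"),
                row["age_band"],
                row["sbp_band"],
                tc,
            )
            if key in cells:
                raise ChartError(f"row {row_no}: duplicate cell {key}")
            cells[key] = band
    if region is None:
        raise ChartError("empty chart file")
    return ChartTable(region=region, variant=variant, cells=cells)


def write_chart(chart: ChartTable, path) -> None:
    """Write a chart in the CSV dialect accepted by :func:`load_chart`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CHART_HEADER)
        for key in iter_chart_keys(chart.variant):
            diabetes, gender, smoker, ab, sb, tb = key
            writer.writerow([
                chart.region, chart.variant,
                "yes" if diabetes else "no", gender,
                "yes" if smoker else "no", ab, sb,
                tb if tb is not None else "NA",
                chart.cells[key].name,
            ])


@dataclass(frozen=True)
class RiskAssessment:
    """Outcome of a chart lookup: the band and the variant consulted."""

    band: RiskBand
    chart_variant: str
    warnings: tuple[str, ...] = ()


def assess_risk(
    profile: RiskFactorProfile,
    chart_li: ChartTable,
    chart_hi: ChartTable,
    diabetes: Optional[bool] = None,
) -> RiskAssessment:
    """Categorise a participant's 10-year absolute CVD risk.

    The HI chart is used iff total cholesterol is present, else the LI
    chart; each continuous input is banded per the chart edges.  The SBP
    fed to the chart is the summarised cuff-reading pair when raw
    readings are stored.  Ages below the lowest chart band are clamped
    to it and flagged with an ``age_clamped`` warning rather than
    rejected.  ``diabetes`` may be passed pre-resolved; by default it is
    derived from history and measured glucose
    (:func:`cvdscreen.rules.diabetes_status`).
    """
    result = validate_step(profile, 3)
    if not result.valid:
        raise ValueError(f"profile fails step-3 validation: {result.violations}")
    if diabetes is None:
        from .rules import diabetes_status

        diabetes = diabetes_status(profile)
    sbp, _ = effective_bp(profile)
    if sbp is None:
        raise ValueError("systolic blood pressure required for risk assessment")
    ab, clamped = age_band(profile.demographics.age)
    warnings = ("age_clamped",) if clamped else ()
    sb = sbp_band(sbp)
    if profile.tc is not None:
        key: ChartKey = (
            diabetes, profile.demographics.gender, profile.smoker,
            ab, sb, tc_band_from_mgdl(profile.tc),
        )
        return RiskAssessment(chart_hi.lookup(key), "HI", warnings)
    key = (diabetes, profile.demographics.gender, profile.smoker, ab, sb, None)
    return RiskAssessment(chart_li.lookup(key), "LI", warnings)


#: fields a counterfactual projection may touch
PROJECTABLE_FIELDS = ("sbp", "tc", "smoker", "diabetes")


def apply_modifications(
    profile: RiskFactorProfile, modifications: Mapping[str, tuple[str, object]]
) -> tuple[RiskFactorProfile, Optional[bool]]:
    """Apply counterfactual deltas/replacements to a copy of a profile.

    ``modifications`` maps a field in :data:`PROJECTABLE_FIELDS` to an
    ``("add", delta)`` or ``("set", value)`` pair; booleans accept only
    ``set``.  Returns the modified copy plus a diabetes override (or
    None).  The input profile is never mutated.
    """
    changes: dict = {}
    diabetes_override: Optional[bool] = None
    for fld, (op, value) in modifications.items():
        if fld not in PROJECTABLE_FIELDS:
            raise ValueError(f"cannot project field {fld!r}")
        if fld in ("smoker", "diabetes"):
            if op != "set":
                raise ValueError(f"{fld} supports only 'set' modifications")
            if fld == "diabetes":
                diabetes_override = bool(value)
            else:
                changes["smoker"] = bool(value)
            continue
        if fld == "sbp":
            base, eff_dbp = effective_bp(profile)
        else:
            base = profile.tc
        if op == "add":
            if base is None:
                raise ValueError(f"cannot add delta to missing {fld}")
            new = base + value  # type: ignore[operator]
        elif op == "set":
            new = value
        else:
            raise ValueError(f"unknown modification op {op!r}")
        changes[fld] = new
        if fld == "sbp":
            # the chart consumes the summarised pair; pin the projected
            # value by clearing the raw readings on the copy
            changes["bp_readings"] = ()
            if profile.bp_readings:
                changes["dbp"] = eff_dbp
    modified = replace(profile, **changes)
    result = validate_step(modified, 3)
    if not result.valid:
        raise ValueError(
            f"modification produces invalid profile: {result.violations}"
        )
    return modified, diabetes_override


def project_risk(
    profile: RiskFactorProfile,
    modifications: Mapping[str, tuple[str, object]],
    chart_li: ChartTable,
    chart_hi: ChartTable,
) -> tuple[RiskAssessment, RiskAssessment]:
    """Counterfactual risk projection behind the on-screen risk meter.

    Returns (before, after) assessments; ``after`` is computed on a
    modified copy, so the input profile is unchanged.  This is the
    computation that lets a health worker show a participant how e.g. a
    10 mmHg blood-pressure reduction would move their risk band.
    """
    before = assess_risk(profile, chart_li, chart_hi)
    modified, diabetes_override = apply_modifications(profile, modifications)
    after = assess_risk(modified, chart_li, chart_hi, diabetes=diabetes_override)
    return before, after


__all__ = [
    "RiskBand", "RiskAssessment", "ChartTable", "ChartError", "ChartKey",
    "AGE_BANDS", "SBP_BANDS", "TC_BANDS", "MG_PER_MMOL_CHOL",
    "age_band", "sbp_band", "tc_band_from_mmol", "tc_band_from_mgdl",
    "iter_chart_keys", "load_chart", "write_chart",
    "assess_risk", "project_risk", "apply_modifications", "PROJECTABLE_FIELDS",
]
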