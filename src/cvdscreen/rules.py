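"""Point-of-care decision support: sub-conditions and management plans.

After the chart lookup, the tool derives a set of clinical
sub-conditions from the same profile:

* **clinically high risk (CHR)** — SBP >=160 mmHg or DBP >=100 mmHg or
  TC >=320 mg/dL or LDL >=240 mg/dL or TC/HDL > 8;
* **impaired fasting glucose (IFG)** — fasting glucose in the
  110-<126 mg/dL band *or a history of diabetes* (the source decision
  table folds diabetes history into this flag; implemented literally —
  see docs/methods.md);
* **weight status** — obese if BMI >= 30, overweight if 25 <= BMI < 30;
* **hypertension** — SBP >=140 or DBP >=90 or a history of hypertension;
* **diabetes** — history of diabetes, fasting glucose >=126 mg/dL, or
  random glucose >=200 mg/dL.

The management plan (referral, screening interval, medication classes,
lifestyle advice) is driven by a data-driven decision table keyed on an
*effective risk tier*: the chart band, escalated to the high tier when
the band is >=30%, the participant has prior CVD, or CHR holds.  The
full table ships as YAML (``data/default_rules.yaml``) and can be
replaced by the user; completeness is validated at load.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import yaml

from .encounter import RiskFactorProfile, compute_bmi, effective_bp
from .risk import RiskAssessment, RiskBand

WEIGHT_STATUSES = ("normal", "overweight", "obese")
MEDICATIONS = ("bp_lowering", "lipid_lowering", "antiplatelet")
REFERRAL_REASONS = ("high_cvd_risk", "ifg")
ADVICE = ("smoking_cessation", "nutrition", "lifestyle")


# ---------------------------------------------------------------------------
# sub-conditions

def clinically_high_risk(profile: RiskFactorProfile) -> bool:
    """Severely elevated single risk factor, independent of the chart.

    SBP >=160 or DBP >=100 mmHg, TC >=320 or LDL >=240 mg/dL, or a
    TC/HDL ratio above 8.  Missing lipids never trigger an arm.
    """
    sbp, dbp = effective_bp(profile)
    if sbp is not None and sbp >= 160:
        return True
    if dbp is not None and dbp >= 100:
        return True
    if profile.tc is not None and profile.tc >= 320:
        return True
    if profile.ldl is not None and profile.ldl >= 240:
        return True
    if (
        profile.tc is not None
        and profile.hdl is not None
        and profile.hdl > 0
        and profile.tc / profile.hdl > 8
    ):
        return True
    return False


def impaired_fasting_glucose(profile: RiskFactorProfile) -> bool:
    """Fasting glucose in the 110-<126 mg/dL band, or diabetes history.

    The band is half-open: 110 triggers, 126 does not (126 is the
    diabetes cut-off).  Random glucose never triggers this flag.
    """
    if profile.history.past_diabetes:
        return True
    if (
        profile.glucose_value is not None
        and profile.glucose_type == "fasting"
        and 110 <= profile.glucose_value < 126
    ):
        return True
    return False


def weight_status(bmi: float) -> str:
    """Categorise an (unrounded) BMI: obese >=30, overweight 25-<30."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi!r}")
    if bmi >= 30:
        return "obese"
    if bmi >= 25:
        return "overweight"
    return "normal"


def hypertension(profile: RiskFactorProfile) -> bool:
    """SBP >=140 or DBP >=90 mmHg, or a history of hypertension."""
    sbp, dbp = effective_bp(profile)
    if sbp is not None and sbp >= 140:
        return True
    if dbp is not None and dbp >= 90:
        return True
    return bool(profile.history.hypertension_history)


def diabetes_status(profile: RiskFactorProfile) -> bool:
    """Diabetes input to the risk chart.

    History of diabetes, or measured fasting glucose >=126 mg/dL, or
    random glucose >=200 mg/dL.
    """
    if profile.history.past_diabetes:
        return True
    if profile.glucose_value is not None:
        if profile.glucose_type == "fasting" and profile.glucose_value >= 126:
            return True
        if profile.glucose_type == "random" and profile.glucose_value >= 200:
            return True
    return False


@dataclass(frozen=True)
class SubConditions:
    clinically_high_risk: bool
    ifg: bool
    weight_status: Optional[str]
    hypertension: bool
    diabetes: bool


def sub_conditions(profile: RiskFactorProfile) -> SubConditions:
    """Derive every sub-condition from one profile, deterministically."""
    ws = None
    if profile.height is not None and profile.weight is not None:
        ws = weight_status(compute_bmi(profile.height, profile.weight, decimals=None))
    return SubConditions(
        clinically_high_risk=clinically_high_risk(profile),
        ifg=impaired_fasting_glucose(profile),
        weight_status=ws,
        hypertension=hypertension(profile),
        diabetes=diabetes_status(profile),
    )


# ---------------------------------------------------------------------------
# decision table

class RulesError(ValueError):
    """Raised when a rules file is incomplete or malformed."""


_TIER_NAMES = ("high", "R20_30", "R10_20", "R0_10")

_CONDITION_FLAGS = (
    "diabetes", "ifg", "past_diabetes", "past_cvd",
    "clinically_high_risk", "hypertension", "smoker",
)
_CONDITION_FIELDS = ("sbp", "dbp", "tc", "ldl", "hdl", "glucose")
_OPS = {"ge": lambda a, b: a >= b, "gt": lambda a, b: a > b,
        "le": lambda a, b: a <= b, "lt": lambda a, b: a < b}


def _validate_condition(cond, where: str) -> None:
    if not isinstance(cond, dict) or len(cond) != 1:
        raise RulesError(f"{where}: condition must be a single-key mapping")
    key, body = next(iter(cond.items()))
    if key == "always":
        if not isinstance(body, bool):
            raise RulesError(f"{where}: 'always' takes a boolean")
    elif key in ("any", "all"):
        if not isinstance(body, list) or not body:
            raise RulesError(f"{where}: '{key}' takes a non-empty list")
        for sub in body:
            _validate_condition(sub, where)
    elif key == "flag":
        if body not in _CONDITION_FLAGS:
            raise RulesError(f"{where}: unknown flag {body!r}")
    elif key == "field":
        if (
            not isinstance(body, dict)
            or body.get("name") not in _CONDITION_FIELDS
            or body.get("op") not in _OPS
            or not isinstance(body.get("value"), (int, float))
        ):
            raise RulesError(f"{where}: bad field condition {body!r}")
    else:
        raise RulesError(f"{where}: unknown condition key {key!r}")


def _eval_condition(cond: dict, ctx: dict) -> bool:
    key, body = next(iter(cond.items()))
    if key == "always":
        return body
    if key == "any":
        return any(_eval_condition(sub, ctx) for sub in body)
    if key == "all":
        return all(_eval_condition(sub, ctx) for sub in body)
    if key == "flag":
        return bool(ctx["flags"][body])
    # field comparison; a missing measurement never satisfies an arm
    value = ctx["fields"][body["name"]]
    if value is None:
        return False
    return _OPS[body["op"]](value, body["value"])


def validate_rules(rules: dict) -> dict:
    """Check a decision-table mapping for completeness; returns it."""
    if not isinstance(rules, dict) or "tiers" not in rules:
        raise RulesError("rules file must contain a 'tiers' mapping")
    tiers = rules["tiers"]
    for name in _TIER_NAMES:
        if name not in tiers:
            raise RulesError(f"missing tier {name!r}")
        tier = tiers[name]
        interval = tier.get("interval_months")
        if not isinstance(interval, int) or interval <= 0:
            raise RulesError(f"tier {name}: interval_months must be a positive int")
        _validate_condition(tier.get("referral"), f"tier {name} referral")
        meds = tier.get("medications")
        if not isinstance(meds, dict):
            raise RulesError(f"tier {name}: missing medications mapping")
        for med in MEDICATIONS:
            if med not in meds:
                raise RulesError(f"tier {name}: missing medication rule {med!r}")
            _validate_condition(meds[med], f"tier {name} medication {med}")
    esc = rules.get("high_tier_escalation", {})
    if not isinstance(esc, dict):
        raise RulesError("high_tier_escalation must be a mapping")
    return rules


def load_rules(path) -> dict:
    """Load and validate a YAML decision table."""
    with open(path, "r", encoding="utf-8") as fh:
        return validate_rules(yaml.safe_load(fh))


def default_rules() -> dict:
    """The shipped decision table (referral/medication/next-visit)."""
    ref = resources.files("cvdscreen.data").joinpath("default_rules.yaml")
    with resources.as_file(ref) as p:
        return load_rules(p)


@dataclass(frozen=True)
class ManagementPlan:
    referral: bool
    referral_reasons: frozenset[str]
    cvd_screening_interval: int  # months to next CVD risk screening
    diabetes_screening_flag: bool
    medications: frozenset[str]
    general_advice: frozenset[str]
    effective_tier: str


def effective_tier(
    risk: RiskAssessment, sub: SubConditions, profile: RiskFactorProfile,
    rules: Optional[dict] = None,
) -> str:
    """Tier driving the plan: the band, escalated to 'high' when the
    band is >=30%, there is prior CVD, or the CHR flag holds."""
    esc = (rules or {}).get("high_tier_escalation", {})
    min_band = RiskBand[esc.get("min_band", "R30_40")]
    if risk.band >= min_band:
        return "high"
    if esc.get("past_cvd", True) and profile.history.past_cvd:
        return "high"
    if esc.get("clinically_high_risk", True) and sub.clinically_high_risk:
        return "high"
    return risk.band.name


def management_plan(
    risk: RiskAssessment,
    sub: SubConditions,
    profile: RiskFactorProfile,
    rules: Optional[dict] = None,
) -> ManagementPlan:
    """Referral, next-visit interval, medications and advice for one
    participant.

    Deterministic in its inputs.  An IFG flag always forces a referral
    (reason ``ifg``); tier-driven referrals carry reason
    ``high_cvd_risk``.  Detailed smoking-cessation advice goes only to
    smokers; nutrition and lifestyle advice go to everyone.
    """
    if rules is None:
        rules = default_rules()
    tier_name = effective_tier(risk, sub, profile, rules)
    tier = rules["tiers"][tier_name]
    sbp, dbp = effective_bp(profile)
    ctx = {
        "flags": {
            "diabetes": sub.diabetes,
            "ifg": sub.ifg,
            "past_diabetes": bool(profile.history.past_diabetes),
            "past_cvd": profile.history.past_cvd,
            "clinically_high_risk": sub.clinically_high_risk,
            "hypertension": sub.hypertension,
            "smoker": profile.smoker,
        },
        "fields": {
            "sbp": sbp, "dbp": dbp, "tc": profile.tc, "ldl": profile.ldl,
            "hdl": profile.hdl, "glucose": profile.glucose_value,
        },
    }
    reasons: set[str] = set()
    if _eval_condition(tier["referral"], ctx):
        # glucose-driven referrals in the low tiers are reported under
        # the IFG bucket; everything tier-driven is a CVD-risk referral
        if tier_name in ("high", "R20_30"):
            reasons.add("high_cvd_risk")
        elif sub.diabetes or sub.ifg:
            reasons.add("ifg")
        else:
            reasons.add("high_cvd_risk")
    if sub.ifg:
        reasons.add("ifg")
    medications = frozenset(
        med for med in MEDICATIONS if _eval_condition(tier["medications"][med], ctx)
    )
    advice = {"nutrition", "lifestyle"}
    if profile.smoker:
        advice.add("smoking_cessation")
    return ManagementPlan(
        referral=bool(reasons),
        referral_reasons=frozenset(reasons),
        cvd_screening_interval=tier["interval_months"],
        diabetes_screening_flag=sub.ifg,
        medications=medications,
        general_advice=frozenset(advice),
        effective_tier=tier_name,
    )


__all__ = [
    "SubConditions", "ManagementPlan", "clinically_high_risk",
    "impaired_fasting_glucose", "weight_status", "hypertension",
    "diabetes_status", "sub_conditions", "management_plan",
    "effective_tier", "default_rules", "load_rules", "validate_rules",
    "RulesError", "MEDICATIONS", "REFERRAL_REASONS", "ADVICE",
]
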