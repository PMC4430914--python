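"""Synthetic cohorts, click streams and glucometer memories.

No field dataset is distributed with this package, so every analysis is
exercised against synthetic data carrying the statistical structure the
analyses assume:

* **Cohorts** are a two-stratum mixture — a high-risk stratum (elevated
  blood pressure and cholesterol, frequent diabetes and prior CVD) and
  a low-risk stratum — mixed to approximate a target fraction of
  participants who are chart-high-risk, clinically high risk, or have
  prior CVD.  This reproduces the bimodal risk distribution typical of
  rural screening cohorts (defaults: n=292, 34% high-risk, ages 40+
  with mean ~51 y).
* **Click streams** emulate one health worker screening a slice of the
  cohort: per-step durations are lognormal with a geometric learning
  decay of the median, Bluetooth BP transmission is adopted along a
  logistic curve in the procedure index, management screens are opened
  with per-section probabilities, one manually entered glucose value
  per procedure is corrupted with a digit transposition/slip error at a
  configured probability, and each procedure ends with a 1-4 Likert
  usability rating.
* **Glucometer memories** hold the true (uncorrupted) glucose value for
  every entry, timestamped within the procedure window, so the
  entry-error reconciliation can be tested against exact ground truth.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .analytics import ClickEvent
from .encounter import (
    Demographics,
    MedicalHistory,
    RiskFactorProfile,
    summarize_bp,
)
from .risk import ChartTable, RiskBand, assess_risk
from .rules import clinically_high_risk

# per-stratum risk-factor distributions: (mean, sd) for continuous,
# bare probability for flags
HIGH_STRATUM = {
    "sbp": (178, 14), "dbp": (98, 10), "tc": (250, 40), "hdl": (44, 8),
    "ldl": (150, 30), "tg": (180, 50), "glucose": (140, 40),
    "smoker": 0.45, "past_diabetes": 0.35, "past_cvd": 0.12,
    "hypertension_history": 0.5,
}
LOW_STRATUM = {
    "sbp": (122, 10), "dbp": (78, 8), "tc": (180, 25), "hdl": (50, 10),
    "ldl": (110, 25), "tg": (140, 40), "glucose": (106, 13),
    "smoker": 0.20, "past_diabetes": 0.02, "past_cvd": 0.0,
    "hypertension_history": 0.08,
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the two-stratum screening-cohort generator."""

    n: int = 292
    seed: int = 0
    target_high_fraction: float = 0.34
    age_mean: float = 51.4
    age_sd: float = 13.1
    age_min: float = 40.0
    age_max: float = 90.0
    female_fraction: float = 0.55
    high_stratum: dict = field(default_factory=lambda: dict(HIGH_STRATUM))
    low_stratum: dict = field(default_factory=lambda: dict(LOW_STRATUM))
    tolerance: float = 0.05
    max_retries: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >=1")
        if not 0 <= self.target_high_fraction <= 1:
            raise ValueError("target_high_fraction must be in [0,1]")


def is_high_risk(
    profile: RiskFactorProfile, chart_li: ChartTable, chart_hi: ChartTable
) -> bool:
    """Chart band >=30%, or clinically high risk, or prior CVD."""
    band = assess_risk(profile, chart_li, chart_hi).band
    return (
        band >= RiskBand.R30_40
        or clinically_high_risk(profile)
        or profile.history.past_cvd
    )


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (cheap at these sizes)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def _draw_profile(rng, params: CohortParams, stratum: dict, idx: int) -> RiskFactorProfile:
    def cont(name, lo, hi):
        m, s = stratum[name]
        return float(_truncnorm(rng, m, s, lo, hi))

    age = int(round(float(_truncnorm(
        rng, params.age_mean, params.age_sd, params.age_min, params.age_max))))
    gender = "female" if rng.random() < params.female_fraction else "male"
    sbp = cont("sbp", 85, 260)
    dbp = min(cont("dbp", 45, 160), sbp - 15)
    # three cuff readings: the first runs high (acclimatisation)
    readings = tuple(
        (round(sbp + off + rng.normal(0, 2)), round(dbp + off / 2 + rng.normal(0, 2)))
        for off in (6.0, 0.0, 0.0)
    )
    s_sum, d_sum = summarize_bp(readings)
    height = float(_truncnorm(rng, 160, 9, 140, 195))
    bmi = float(_truncnorm(rng, 24.5, 4, 16, 42))
    weight = round(bmi * (height / 100.0) ** 2, 1)
    history = MedicalHistory(
        past_mi_angina=bool(rng.random() < stratum["past_cvd"] / 2),
        past_stroke=bool(rng.random() < stratum["past_cvd"] / 2),
        past_pvd=bool(rng.random() < stratum["past_cvd"] / 4),
        past_diabetes=bool(rng.random() < stratum["past_diabetes"]),
        family_mi_angina=bool(rng.random() < 0.1),
        family_stroke=bool(rng.random() < 0.08),
        family_diabetes=bool(rng.random() < 0.15),
        hypertension_history=bool(rng.random() < stratum["hypertension_history"]),
    )
    return RiskFactorProfile(
        demographics=Demographics(
            patient_id=f"P{idx:04d}", age=age, gender=gender, location="village",
        ),
        history=history,
        sbp=float(s_sum), dbp=float(d_sum), bp_readings=readings,
        glucose_value=round(cont("glucose", 45, 480)),
        glucose_type="fasting",
        tc=round(cont("tc", 80, 460)),
        hdl=round(cont("hdl", 20, 120)),
        ldl=round(cont("ldl", 40, 360)),
        tg=round(cont("tg", 40, 800)),
        height=round(height, 1), weight=weight,
        smoker=bool(rng.random() < stratum["smoker"]),
    )


def generate_cohort(
    params: CohortParams,
    chart_li: Optional[ChartTable] = None,
    chart_hi: Optional[ChartTable] = None,
) -> list[RiskFactorProfile]:
    """Generate a screening cohort approximating the target high-risk mix.

    The number of high-stratum draws is ``round(n * target)``; the
    realised high-or-CHR-or-CVD fraction is then measured against the
    supplied charts (the synthetic fixture charts by default) and the
    cohort is redrawn up to ``max_retries`` times if it misses the
    target by more than ``tolerance``, keeping the closest draw and
    warning if the target remains unreached.  Fully reproducible given
    the seed.
    """
    if chart_li is None or chart_hi is None:
        from .fixtures import fixture_charts

        chart_li, chart_hi = fixture_charts()
    rng = np.random.default_rng(params.seed)
    n_high = int(round(params.n * params.target_high_fraction))
    best: Optional[list[RiskFactorProfile]] = None
    best_gap = math.inf
    for _attempt in range(max(1, params.max_retries)):
        cohort = [
            _draw_profile(
                rng, params,
                params.high_stratum if i < n_high else params.low_stratum,
                idx=i,
            )
            for i in range(params.n)
        ]
        achieved = sum(
            is_high_risk(p, chart_li, chart_hi) for p in cohort
        ) / params.n
        gap = abs(achieved - params.target_high_fraction)
        if gap < best_gap:
            best, best_gap = cohort, gap
        if gap <= params.tolerance:
            break
    else:
        warnings.warn(
            f"target high-risk fraction {params.target_high_fraction:.2f} "
            f"not reached; best achieved gap {best_gap:.3f}",
            stacklevel=2,
        )
    # shuffle so strata are not positionally ordered
    order = np.random.default_rng(params.seed + 1).permutation(params.n)
    assert best is not None
    return [best[i] for i in order]


# ---------------------------------------------------------------------------
# click streams

@dataclass(frozen=True)
class SyntheticWorkerProfile:
    """Behavioural parameters of one simulated health worker."""

    worker_id: str
    seed: int
    n_procedures: int = 20
    #: lognormal medians of the four step durations, seconds
    step_median_s: tuple[float, float, float, float] = (157.0, 68.0, 633.0, 90.0)
    #: lognormal shape (sigma of log-duration)
    sigma: float = 0.5
    #: multiplicative decay of the median per procedure, centred on the
    #: study midpoint so the whole-study median stays near step_median_s
    learning_decay: float = 0.985
    #: idle gap between steps (participant repositioning etc.)
    gap_median_s: float = 107.0
    gap_sigma: float = 0.4
    #: logistic Bluetooth adoption curve in the 1-based procedure index
    bt_p_min: float = 0.2
    bt_p_max: float = 0.8
    bt_midpoint: float = 10.0
    bt_scale: float = 3.0
    #: BP acquisition-time medians, seconds
    bt_acq_median_s: float = 320.0
    manual_acq_median_s: float = 460.0
    acq_sigma: float = 0.5
    #: probability of opening each management section
    section_probs: dict = field(default_factory=lambda: {
        "risk_meter": 0.8, "recommendations": 0.9, "next_visit": 0.9,
    })
    #: probability a manually entered glucose value is corrupted
    glucose_error_prob: float = 0.06
    #: distribution of the 1-4 usability rating
    likert_probs: dict = field(default_factory=lambda: {3: 0.28, 4: 0.72})
    start_time: datetime = datetime(2013, 6, 1, 9, 0, 0)
    inter_procedure_gap_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.n_procedures < 1:
            raise ValueError("n_procedures must be >=1")
        if not 0 < self.learning_decay <= 1:
            raise ValueError("learning_decay must be in (0,1]")
        for p in (self.bt_p_min, self.bt_p_max, self.glucose_error_prob,
                  *self.section_probs.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0,1]")

    def bluetooth_prob(self, index: int) -> float:
        """Adoption probability at 1-based procedure ``index``."""
        z = (index - self.bt_midpoint) / self.bt_scale
        return self.bt_p_min + (self.bt_p_max - self.bt_p_min) / (1 + math.exp(-z))


@dataclass(frozen=True)
class GlucoseTruth:
    encounter_id: str
    timestamp: datetime
    true_value: float
    entered_value: float
    corrupted: bool


@dataclass(frozen=True)
class StreamTruth:
    """Ground-truth sidecar emitted with every generated stream."""

    worker: SyntheticWorkerProfile
    glucose: tuple[GlucoseTruth, ...]
    n_corrupted: int


def corrupt_glucose(rng, value: float) -> float:
    """Simulate a manual transcription error on a glucose value.

    With equal odds either two adjacent digits are transposed or one
    digit slips by +/-1-5; the corrupted value always differs from the
    truth and stays in a plausible range.
    """
    true_int = int(round(value))
    for _ in range(50):
        digits = list(str(true_int))
        if len(digits) >= 2 and rng.random() < 0.5:
            i = int(rng.integers(0, len(digits) - 1))
            digits[i], digits[i + 1] = digits[i + 1], digits[i]
        else:
            i = int(rng.integers(0, len(digits)))
            slip = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
            digits[i] = str((int(digits[i]) + slip) % 10)
        if digits[0] == "0":
            continue
        candidate = int("".join(digits))
        if candidate != true_int and 20 <= candidate <= 600:
            return float(candidate)
    return float(true_int + 10)  # pathological digits; any non-zero error


def _lognormal(rng, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def generate_event_stream(
    worker: SyntheticWorkerProfile,
    cohort: Sequence[RiskFactorProfile],
) -> tuple[list[ClickEvent], StreamTruth]:
    """Emit one worker's click stream over a slice of the cohort.

    Per procedure: four step start/complete pairs with lognormal
    durations whose median decays geometrically with experience, a BP
    sub-step (Bluetooth with the adoption-curve probability, otherwise
    manual), one glucose entry (possibly corrupted), management-section
    opens, and a Likert rating.  Returns the events plus the ground
    truth needed to audit the glucose entries.
    """
    if len(cohort) < worker.n_procedures:
        raise ValueError(
            f"cohort slice ({len(cohort)}) smaller than n_procedures "
            f"({worker.n_procedures})"
        )
    rng = np.random.default_rng(worker.seed)
    events: list[ClickEvent] = []
    glucose_truth: list[GlucoseTruth] = []
    t = worker.start_time
    mid = (worker.n_procedures - 1) / 2.0
    likert_vals = sorted(worker.likert_probs)
    likert_p = np.array([worker.likert_probs[v] for v in likert_vals], dtype=float)
    likert_p = likert_p / likert_p.sum()

    def emit(ts, enc, step, element, value=None):
        events.append(ClickEvent(ts, worker.worker_id, enc, step, element, value))

    for i in range(worker.n_procedures):
        enc = f"{worker.worker_id}-{i + 1:03d}"
        profile = cohort[i]
        decay = worker.learning_decay ** (i - mid)
        cursor = t
        durations = [
            max(5.0, _lognormal(rng, m * decay, worker.sigma))
            for m in worker.step_median_s
        ]
        bluetooth = rng.random() < worker.bluetooth_prob(i + 1)
        for k in (1, 2, 3, 4):
            d = durations[k - 1]
            emit(cursor, enc, k, "step_start")
            if k == 3:
                bp_t0 = cursor + timedelta(seconds=2)
                emit(bp_t0, enc, 3, "bp_start")
                median = worker.bt_acq_median_s if bluetooth else worker.manual_acq_median_s
                acq = min(_lognormal(rng, median, worker.acq_sigma), 0.8 * d)
                emit(
                    bp_t0 + timedelta(seconds=acq), enc, 3,
                    "bp_bluetooth_receive" if bluetooth else "bp_manual_entry",
                )
                true_glucose = float(profile.glucose_value or 100.0)
                corrupted = rng.random() < worker.glucose_error_prob
                entered = corrupt_glucose(rng, true_glucose) if corrupted else true_glucose
                g_ts = cursor + timedelta(seconds=0.9 * d)
                emit(g_ts, enc, 3, "glucose_entry", str(int(entered)))
                glucose_truth.append(GlucoseTruth(enc, g_ts, true_glucose, entered, corrupted))
            if k == 4:
                sections = [
                    ("riskmeter_open", 0.25), ("recs_open", 0.45), ("nextvisit_open", 0.65),
                ]
                for (element, frac), name in zip(
                    sections, ("risk_meter", "recommendations", "next_visit")
                ):
                    if rng.random() < worker.section_probs.get(name, 0.0):
                        emit(cursor + timedelta(seconds=frac * d), enc, 4, element)
                rating = int(rng.choice(likert_vals, p=likert_p))
                emit(cursor + timedelta(seconds=0.9 * d), enc, 4, "likert_rating", str(rating))
            cursor += timedelta(seconds=d)
            emit(cursor, enc, k, "step_complete")
            if k < 4:
                cursor += timedelta(seconds=_lognormal(
                    rng, worker.gap_median_s * decay, worker.gap_sigma))
        t = cursor + timedelta(
            seconds=worker.inter_procedure_gap_s * (0.5 + rng.random())
        )
    truth = StreamTruth(
        worker=worker,
        glucose=tuple(glucose_truth),
        n_corrupted=sum(g.corrupted for g in glucose_truth),
    )
    return events, truth


def generate_glucometer_memory(
    truth: StreamTruth, offset_s: float = 120.0
) -> list[tuple[datetime, float]]:
    """Meter records for a generated stream: the true value per entry,
    timestamped shortly before the manual entry."""
    return [
        (g.timestamp - timedelta(seconds=offset_s), g.true_value)
        for g in truth.glucose
    ]


def entered_glucose(events: Sequence[ClickEvent]) -> list[tuple[datetime, float]]:
    """(timestamp, value) pairs of manual glucose entries in a stream."""
    return [
        (e.timestamp, float(e.value))
        for e in events
        if e.element_id == "glucose_entry" and e.value is not None
    ]


def scripted_event_stream(
    worker_id: str,
    n_procedures: int,
    bluetooth_procedures: Sequence[int] = (),
    section_visits: Optional[dict] = None,
    likert: int = 4,
    start_time: datetime = datetime(2013, 6, 1, 9, 0, 0),
    step_seconds: float = 300.0,
) -> list[ClickEvent]:
    """Deterministic stream with exact per-feature counts.

    ``bluetooth_procedures`` and each ``section_visits[section]`` list
    the 1-based procedure indices in which the feature occurs; every
    procedure is complete and sequential with fixed step durations.
    Used to rebuild published per-worker usage counts exactly.
    """
    section_visits = section_visits or {}
    events: list[ClickEvent] = []
    t = start_time
    for i in range(1, n_procedures + 1):
        enc = f"{worker_id}-{i:03d}"
        cursor = t
        for k in (1, 2, 3, 4):
            events.append(ClickEvent(cursor, worker_id, enc, k, "step_start"))
            if k == 3:
                bp_t0 = cursor + timedelta(seconds=2)
                events.append(ClickEvent(bp_t0, worker_id, enc, 3, "bp_start"))
                element = (
                    "bp_bluetooth_receive" if i in bluetooth_procedures else "bp_manual_entry"
                )
                events.append(ClickEvent(
                    bp_t0 + timedelta(seconds=step_seconds / 2), worker_id, enc, 3, element,
                ))
            if k == 4:
                for element, name in (
                    ("riskmeter_open", "risk_meter"),
                    ("recs_open", "recommendations"),
                    ("nextvisit_open", "next_visit"),
                ):
                    if i in section_visits.get(name, ()):
                        events.append(ClickEvent(
                            cursor + timedelta(seconds=step_seconds / 3),
                            worker_id, enc, 4, element,
                        ))
                events.append(ClickEvent(
                    cursor + timedelta(seconds=step_seconds * 0.9),
                    worker_id, enc, 4, "likert_rating", str(likert),
                ))
            cursor += timedelta(seconds=step_seconds)
            events.append(ClickEvent(cursor, worker_id, enc, k, "step_complete"))
        t = cursor + timedelta(seconds=600)
    return events


__all__ = [
    "CohortParams", "SyntheticWorkerProfile", "StreamTruth", "GlucoseTruth",
    "HIGH_STRATUM", "LOW_STRATUM", "generate_cohort", "is_high_risk",
    "generate_event_stream", "generate_glucometer_memory", "entered_glucose",
    "corrupt_glucose", "scripted_event_stream",
]
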