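"""Field-evaluation analytics over click-event streams.

During field use every tap in the screening app is logged with a
timestamp.  This module reconstructs screening procedures from those
click streams and computes the evaluation measures used to study a
deployment: per-procedure and per-step timing (median/IQR), sequential
bootstrap confidence intervals for the mean procedure time (at each
procedure index k, resampling from all procedures up to and including
k), Bluetooth blood-pressure adoption rates, dissemination rates of the
management screens, manual glucose-entry error reconciliation against
glucometer memory dumps, Likert usability summaries, and glucose unit
conversion.

Event-log CSV dialect: ``timestamp,user_id,encounter_id,step,
element_id,value`` with ISO-8601 timestamps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: documented click-event vocabulary
ELEMENT_IDS = frozenset({
    "step_start", "step_complete",
    "bp_start", "bp_bluetooth_receive", "bp_manual_entry",
    "glucose_entry",
    "riskmeter_open", "recs_open", "nextvisit_open",
    "likert_rating",
})

#: management sections tracked for dissemination
SECTIONS = ("risk_meter", "recommendations", "next_visit")
_SECTION_EVENTS = {
    "riskmeter_open": "risk_meter",
    "recs_open": "recommendations",
    "nextvisit_open": "next_visit",
}

#: mg/dL of glucose per mmol/L (molar mass / 10)
GLUCOSE_MG_PER_MMOL = 18.016

EVENT_LOG_HEADER = ["timestamp", "user_id", "encounter_id", "step", "element_id", "value"]


@dataclass(frozen=True)
class ClickEvent:
    timestamp: datetime
    user_id: str
    encounter_id: str
    step: int
    element_id: str
    value: Optional[str] = None


@dataclass(frozen=True)
class MalformedRow:
    line_no: int
    reason: str
    raw: str


def parse_event_log(path) -> tuple[list[ClickEvent], list[MalformedRow]]:
    """Read an event-log CSV.

    Returns events sorted chronologically plus every malformed row with
    its line number; bad rows are collected, never fatal.
    """
    events: list[ClickEvent] = []
    malformed: list[MalformedRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != EVENT_LOG_HEADER:
            raise ValueError(
                f"bad event-log header {reader.fieldnames!r}; "
                f"expected {EVENT_LOG_HEADER!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            raw = ",".join(str(row.get(c) or "") for c in EVENT_LOG_HEADER)
            try:
                ts = datetime.fromisoformat(row["timestamp"])
            except (ValueError, TypeError):
                malformed.append(MalformedRow(line_no, "unparseable timestamp", raw))
                continue
            try:
                step = int(row["step"])
            except (ValueError, TypeError):
                malformed.append(MalformedRow(line_no, "non-integer step", raw))
                continue
            if step not in (1, 2, 3, 4):
                malformed.append(MalformedRow(line_no, "step outside 1-4", raw))
                continue
            element = row["element_id"]
            if element not in ELEMENT_IDS:
                malformed.append(MalformedRow(line_no, f"unknown element {element!r}", raw))
                continue
            value = row["value"] or None
            if element == "likert_rating":
                try:
                    rating = int(value)  # type: ignore[arg-type]
                except (ValueError, TypeError):
                    malformed.append(MalformedRow(line_no, "non-integer likert rating", raw))
                    continue
                if rating not in (1, 2, 3, 4):
                    malformed.append(MalformedRow(line_no, "likert rating outside 1-4", raw))
                    continue
            events.append(ClickEvent(ts, row["user_id"], row["encounter_id"], step, element, value))
    events.sort(key=lambda e: (e.timestamp, e.encounter_id))
    return events, malformed


def write_event_log(events: Iterable[ClickEvent], path) -> None:
    """Write events in the CSV dialect accepted by :func:`parse_event_log`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_LOG_HEADER)
        for e in events:
            writer.writerow([
                e.timestamp.isoformat(), e.user_id, e.encounter_id,
                e.step, e.element_id, e.value if e.value is not None else "",
            ])


@dataclass
class ProcedureRecord:
    """One reconstructed screening procedure (encounter)."""

    encounter_id: str
    user_id: str
    start: datetime
    end: datetime
    step_seconds: dict = field(default_factory=dict)
    complete: bool = True
    sequential: bool = True
    bluetooth_used: bool = False
    bp_acquisition_seconds: Optional[float] = None
    sections_visited: frozenset = frozenset()
    likert: Optional[int] = None

    @property
    def total_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


def build_procedures(events: Sequence[ClickEvent]) -> list[ProcedureRecord]:
    """Reconstruct one procedure per encounter from sorted events.

    A procedure is *complete* when its step-4 completion event exists;
    incomplete procedures are flagged and excluded from timing.  Two
    procedures of the same user whose time spans overlap are both
    flagged non-sequential.  Bluetooth use is any
    ``bp_bluetooth_receive`` event; BP acquisition time is the span
    from ``bp_start`` to the first BP receipt (Bluetooth or manual).
    """
    by_encounter: dict[str, list[ClickEvent]] = {}
    for e in events:
        by_encounter.setdefault(e.encounter_id, []).append(e)
    records: list[ProcedureRecord] = []
    for enc_id, evs in by_encounter.items():
        evs = sorted(evs, key=lambda e: e.timestamp)
        start = evs[0].timestamp
        end = evs[-1].timestamp
        step_seconds: dict[int, float] = {}
        for k in (1, 2, 3, 4):
            starts = [e.timestamp for e in evs if e.step == k and e.element_id == "step_start"]
            completes = [e.timestamp for e in evs if e.step == k and e.element_id == "step_complete"]
            if starts and completes:
                step_seconds[k] = (max(completes) - min(starts)).total_seconds()
        complete = any(e.step == 4 and e.element_id == "step_complete" for e in evs)
        if complete:
            end = max(
                e.timestamp for e in evs
                if e.step == 4 and e.element_id == "step_complete"
            )
        bluetooth = any(e.element_id == "bp_bluetooth_receive" for e in evs)
        bp_acq: Optional[float] = None
        bp_starts = [e.timestamp for e in evs if e.element_id == "bp_start"]
        if bp_starts:
            t0 = min(bp_starts)
            receipts = [
                e.timestamp for e in evs
                if e.element_id in ("bp_bluetooth_receive", "bp_manual_entry")
                and e.timestamp >= t0
            ]
            if receipts:
                bp_acq = (min(receipts) - t0).total_seconds()
        sections = frozenset(
            _SECTION_EVENTS[e.element_id] for e in evs if e.element_id in _SECTION_EVENTS
        )
        likert = None
        for e in evs:
            if e.element_id == "likert_rating" and e.value is not None:
                likert = int(e.value)
        records.append(ProcedureRecord(
            encounter_id=enc_id, user_id=evs[0].user_id, start=start, end=end,
            step_seconds=step_seconds, complete=complete, bluetooth_used=bluetooth,
            bp_acquisition_seconds=bp_acq, sections_visited=sections, likert=likert,
        ))
    # non-sequential flagging: overlapping spans within a user
    records.sort(key=lambda r: (r.user_id, r.start))
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if b.user_id != a.user_id:
                break
            if b.start < a.end and a.start < b.end:
                a.sequential = False
                b.sequential = False
    records.sort(key=lambda r: r.start)
    return records


def _timed(procedures: Sequence[ProcedureRecord]) -> list[ProcedureRecord]:
    return [p for p in procedures if p.complete and p.sequential]


def _median_iqr(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def duration_summary(
    procedures: Sequence[ProcedureRecord], by_step: bool = False
) -> pd.DataFrame:
    """Median and IQR (Q3-Q1, linear interpolation) of procedure times.

    Seconds; non-sequential and incomplete procedures are excluded.
    With ``by_step`` the per-step durations are summarised instead of
    totals.
    """
    timed = _timed(procedures)
    if not timed:
        raise ValueError("no complete sequential procedures to summarise")
    rows = []
    if by_step:
        for k in (1, 2, 3, 4):
            vals = [p.step_seconds[k] for p in timed if k in p.step_seconds]
            if vals:
                med, iqr = _median_iqr(vals)
                rows.append({"which": f"step{k}", "n": len(vals),
                             "median_s": med, "iqr_s": iqr})
    else:
        med, iqr = _median_iqr([p.total_seconds for p in timed])
        rows.append({"which": "total", "n": len(timed), "median_s": med, "iqr_s": iqr})
    return pd.DataFrame(rows).set_index("which")


def sequential_bootstrap_ci(
    durations: Sequence[float],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Bootstrap mean and percentile CI at every procedure index.

    At index k (1-based) the sample is durations[0:k] — every procedure
    up to and including the k-th — resampled with replacement ``n_boot``
    times.  The point estimate is the mean of bootstrap means; the
    interval is the *expanded* percentile interval at ``level``
    (Hesterberg's small-sample adjustment: the percentile tail
    probability alpha/2 is widened to Phi(sqrt(k/(k-1)) * t_{alpha/2,
    k-1}), which restores near-nominal coverage of the mean at the
    small k typical of per-worker series; at large k it converges to
    the plain percentile interval).  Bit-for-bit reproducible given
    ``seed``.
    """
    from scipy import stats as _st

    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >=1")
    arr = np.asarray(durations, dtype=float)
    if arr.size == 0:
        raise ValueError("empty duration series")
    if seed is None:
        raise ValueError("seed is required for reproducible bootstrapping")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, arr.size + 1):
        alpha = (1 - level) / 2
        if k >= 2:
            alpha = float(_st.norm.cdf(
                np.sqrt(k / (k - 1)) * _st.t.ppf(alpha, df=k - 1)))
        sample = arr[:k]
        idx = rng.integers(0, k, size=(n_boot, k))
        means = sample[idx].mean(axis=1)
        lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
        rows.append({"n": k, "mean_s": float(means.mean()),
                     "ci_low_s": float(lo), "ci_high_s": float(hi)})
    return pd.DataFrame(rows).set_index("n")


@dataclass(frozen=True)
class BluetoothUsage:
    n_used: int
    n_procedures: int
    fraction: float
    rate_percent: int
    mean_acquisition_s: Optional[float]
    sd_acquisition_s: Optional[float]
    split_index: Optional[int] = None
    fraction_before: Optional[float] = None
    fraction_after: Optional[float] = None


def bluetooth_usage(
    procedures: Sequence[ProcedureRecord], split_index: Optional[int] = None
) -> BluetoothUsage:
    """Bluetooth BP adoption rate and acquisition-time moments.

    Denominator: the user's complete, sequential procedures (same
    denominator as dissemination rates).  Acquisition times are over
    Bluetooth procedures only.  ``split_index`` additionally reports
    rates before (indices < split) and from the split onward, mirroring
    before/after-the-Nth-procedure comparisons.  Percentages are
    rounded to the nearest integer for display; the raw fraction is
    authoritative.
    """
    timed = sorted(_timed(procedures), key=lambda p: p.start)
    if not timed:
        raise ValueError("no procedures to analyse")
    used = [p for p in timed if p.bluetooth_used]
    times = [p.bp_acquisition_seconds for p in used if p.bp_acquisition_seconds is not None]
    frac = len(used) / len(timed)
    before = after = None
    if split_index is not None:
        head, tail = timed[:split_index], timed[split_index:]
        before = sum(p.bluetooth_used for p in head) / len(head) if head else None
        after = sum(p.bluetooth_used for p in tail) / len(tail) if tail else None
    return BluetoothUsage(
        n_used=len(used), n_procedures=len(timed), fraction=frac,
        rate_percent=int(round(frac * 100)),
        mean_acquisition_s=float(np.mean(times)) if times else None,
        sd_acquisition_s=float(np.std(times)) if times else None,
        split_index=split_index, fraction_before=before, fraction_after=after,
    )


def dissemination_rates(procedures: Sequence[ProcedureRecord]) -> pd.DataFrame:
    """Per-user, per-section fraction of procedures with >=1 visit.

    How often each management screen (risk meter, recommendations,
    next visit) was actually opened; nearest-integer percent for
    display plus the raw fraction.
    """
    timed = _timed(procedures)
    if not timed:
        raise ValueError("no procedures to analyse")
    rows = []
    for user in sorted({p.user_id for p in timed}):
        mine = [p for p in timed if p.user_id == user]
        for section in SECTIONS:
            n_vis = sum(section in p.sections_visited for p in mine)
            frac = n_vis / len(mine)
            rows.append({
                "user_id": user, "section": section, "n_visited": n_vis,
                "n_procedures": len(mine), "fraction": frac,
                "percent": int(round(frac * 100)),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlucoseErrorReport:
    n_matched: int
    n_errors: int
    errors: tuple[float, ...]          # non-zero |entered - meter|, mg/dL
    median_error: Optional[float]
    iqr_error: Optional[float]
    unmatched_entered: tuple[datetime, ...]


def glucose_entry_errors(
    entered: Sequence[tuple[datetime, float]],
    meter: Sequence[tuple[datetime, float]],
    tolerance_minutes: float = 10.0,
) -> GlucoseErrorReport:
    """Reconcile manually entered glucose values with glucometer memory.

    Each entered value is matched one-to-one to the nearest-in-time
    meter reading within the tolerance window (greedy by time gap);
    the error is |entered - meter| mg/dL.  ``n_errors`` counts non-zero
    discrepancies; median/IQR are over the non-zero errors.  Entered
    values with no meter reading in the window are reported separately.
    """
    if tolerance_minutes <= 0:
        raise ValueError("tolerance must be positive")
    tol_s = tolerance_minutes * 60.0
    candidates = []
    for i, (te, _ve) in enumerate(entered):
        for j, (tm, _vm) in enumerate(meter):
            gap = abs((te - tm).total_seconds())
            if gap <= tol_s:
                candidates.append((gap, i, j))
    candidates.sort()
    used_e: set[int] = set()
    used_m: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _gap, i, j in candidates:
        if i in used_e or j in used_m:
            continue
        used_e.add(i)
        used_m.add(j)
        pairs.append((i, j))
    errors = tuple(
        abs(entered[i][1] - meter[j][1]) for i, j in pairs
        if entered[i][1] != meter[j][1]
    )
    med = iqr = None
    if errors:
        med, iqr = _median_iqr(errors)
    unmatched = tuple(entered[i][0] for i in range(len(entered)) if i not in used_e)
    return GlucoseErrorReport(
        n_matched=len(pairs), n_errors=len(errors), errors=errors,
        median_error=med, iqr_error=iqr, unmatched_entered=unmatched,
    )


@dataclass(frozen=True)
class LikertSummary:
    counts: dict
    n: int
    fraction_at_or_above: float
    threshold: int
    minimum: int


def likert_summary(
    procedures_or_ratings, threshold: int = 3
) -> LikertSummary:
    """Distribution of 1-4 usability ratings and fraction >= threshold."""
    ratings: list[int] = []
    for item in procedures_or_ratings:
        if isinstance(item, ProcedureRecord):
            if item.likert is not None:
                ratings.append(item.likert)
        else:
            ratings.append(int(item))
    if not ratings:
        raise ValueError("no ratings present")
    if any(r not in (1, 2, 3, 4) for r in ratings):
        raise ValueError("ratings must be in 1-4")
    counts = {r: ratings.count(r) for r in (1, 2, 3, 4)}
    frac = sum(1 for r in ratings if r >= threshold) / len(ratings)
    return LikertSummary(
        counts=counts, n=len(ratings), fraction_at_or_above=frac,
        threshold=threshold, minimum=min(ratings),
    )


def convert_glucose(value: float, direction: str) -> tuple[float, float]:
    """Convert glucose between mg/dL and mmol/L.

    Divisor 18.016 (glucose molar mass / 10).  Returns (rounded to two
    decimals for reporting, raw unrounded value).
    """
    if value < 0:
        raise ValueError("glucose cannot be negative")
    if direction == "mgdl_to_mmol":
        raw = value / GLUCOSE_MG_PER_MMOL
    elif direction == "mmol_to_mgdl":
        raw = value * GLUCOSE_MG_PER_MMOL
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return round(raw, 2), raw


__all__ = [
    "ClickEvent", "MalformedRow", "ProcedureRecord", "BluetoothUsage",
    "GlucoseErrorReport", "LikertSummary", "ELEMENT_IDS", "SECTIONS",
    "EVENT_LOG_HEADER", "GLUCOSE_MG_PER_MMOL",
    "parse_event_log", "write_event_log", "build_procedures",
    "duration_summary", "sequential_bootstrap_ci", "bluetooth_usage",
    "dissemination_rates", "glucose_entry_errors", "likert_summary",
    "convert_glucose",
]
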