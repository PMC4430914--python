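"""Independent brute-force oracles used by the unit and acceptance tests.

These re-code the decision logic in the most literal straight-line way
possible, separately from the package's data-driven implementations, so
the two routes can be compared exhaustively.
"""

from __future__ import annotations

import csv


def oracle_sub_conditions(sbp, dbp, tc, hdl, ldl, glucose, glucose_type,
                          past_diabetes):
    """Straight-line transcription of the sub-condition definitions."""
    chr_ = False
    if sbp is not None and sbp >= 160:
        chr_ = True
    if dbp is not None and dbp >= 100:
        chr_ = True
    if tc is not None and tc >= 320:
        chr_ = True
    if ldl is not None and ldl >= 240:
        chr_ = True
    if tc is not None and hdl not in (None, 0) and tc / hdl > 8:
        chr_ = True
    fasting = glucose is not None and glucose_type == "fasting"
    ifg = past_diabetes or (fasting and 110 <= glucose < 126)
    diabetes = past_diabetes or (fasting and glucose >= 126) or (
        glucose is not None and glucose_type == "random" and glucose >= 200
    )
    return chr_, ifg, diabetes


def oracle_plan(band_index, past_cvd, chr_, diabetes, ifg, past_diabetes,
                sbp, dbp, tc, ldl, smoker):
    """Hand-coded management decision table.

    band_index: 0..4 for the five chart bands.  Returns (referral,
    interval_months, medications set, advice set).
    """
    sbp = sbp if sbp is not None else -1
    dbp = dbp if dbp is not None else -1
    bp_ge = sbp >= 140 or dbp >= 90
    high = band_index >= 3 or past_cvd or chr_
    meds: set[str] = set()
    if high:
        referral, interval = True, 3
        meds = {"bp_lowering", "lipid_lowering", "antiplatelet"}
    elif band_index == 2:
        referral, interval = True, 12
        if bp_ge:
            meds.add("bp_lowering")
        if (diabetes or sbp >= 160 or (tc is not None and tc > 200)
                or (ldl is not None and ldl > 120)):
            meds.add("lipid_lowering")
    else:
        interval = 24 if band_index == 1 else 60
        referral = bool(diabetes or ifg or (past_diabetes and sbp >= 160))
        if (diabetes and bp_ge) or sbp >= 160:
            meds.add("bp_lowering")
        if diabetes or sbp >= 160:
            meds.add("lipid_lowering")
    if ifg:
        referral = True
    advice = {"nutrition", "lifestyle"}
    if smoker:
        advice.add("smoking_cessation")
    return referral, interval, meds, advice


def read_chart_cells(path):
    """Independent chart-CSV walk: key-string tuple -> band label."""
    cells = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["diabetes"], row["gender"], row["smoker"],
                   row["age_band"], row["sbp_band"], row["tc_band"])
            cells[key] = row["category"]
    return cells


#: representative raw measurements that band to each chart column
AGE_REPS = {"40-49": 45, "50-59": 55, "60-69": 65, "70+": 75}
SBP_REPS = {"lt140": 120, "140-159": 150, "160-179": 170, "180+": 190}
TC_REPS_MGDL = {  # band midpoints in mmol/L converted at 38.67 mg/dL per mmol/L
    "lt5": round(4.5 * 38.67, 1),
    "5-6": round(5.5 * 38.67, 1),
    "6-7": round(6.5 * 38.67, 1),
    "7-8": round(7.5 * 38.67, 1),
    "8+": round(8.5 * 38.67, 1),
}
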