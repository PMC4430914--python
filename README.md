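# cvdscreen

Chart-based 10-year cardiovascular disease (CVD) risk screening,
point-of-care decision support, and field-evaluation analytics for
community health worker programmes.

In many rural low-resource settings, door-to-door CVD screening is
done by minimally trained health workers using mobile decision-support
tools rather than by physicians. `cvdscreen` is a tested, reusable
implementation of the computational core of such a tool, plus the
analytics needed to evaluate its use in the field:

* **Risk engine** — categorical lookup of 10-year absolute CVD risk in
  WHO/ISH-style colour charts: five bands (<10% … ≥40%) indexed by
  diabetes, gender, smoking, age band, systolic BP band and, when
  cholesterol is known, a total-cholesterol band (High-Information
  chart); the Low-Information chart is used otherwise. Includes the
  counterfactual "risk projection meter" computation (e.g. what band
  would this participant be in after a 10 mmHg SBP reduction?).
* **Decision support** — clinical sub-conditions (clinically high
  risk, impaired fasting glucose, weight status, hypertension,
  diabetes) and a data-driven referral/medication/next-visit decision
  table shipped as editable YAML.
* **Encounter model** — the four-step screening record (demographics,
  history, risk factors, decision support) with on-screen-style
  validation, BMI, three-reading BP summarisation, and age estimation
  from remembered historical events.
* **Analytics** — click-stream parsing, procedure reconstruction,
  timing medians/IQRs, sequential bootstrap confidence intervals for
  mean procedure time, Bluetooth-adoption and management-screen
  dissemination rates, glucose entry-error reconciliation against
  glucometer memory, Likert usability summaries, unit conversion.
* **Synthetic data** — seeded generators for screening cohorts
  (bimodal risk mixture), per-worker click streams with learning-curve
  timing and injected transcription errors, and matching glucometer
  memories, so everything is testable without field data.

The shipped charts are **synthetic fixtures** (see
`docs/methods.md`): for clinical use, transcribe the appropriate
regional WHO/ISH chart into the documented CSV dialect and check it
with `cvdscreen validate-chart`.

## Worked example

Assess a 33-year-old male smoker with diabetes, BP 160/89 mmHg, total
cholesterol 176 mg/dL, and project the effect of a 10 mmHg SBP
reduction:

```python
from cvdscreen.encounter import Demographics, MedicalHistory, RiskFactorProfile, profile_to_json
import pathlib
p = RiskFactorProfile(
    demographics=Demographics(patient_id="P0001", age=33, gender="male"),
    history=MedicalHistory(past_diabetes=True),
    sbp=160.0, dbp=89.0, tc=176.0, smoker=True,
)
pathlib.Path("encounter.json").write_text(profile_to_json(p))
```

```text
$ cvdscreen assess encounter.json --project sbp:-10
risk band: R40_PLUS (>= 40%), chart: HI
warning: age_clamped
sub-conditions: {'clinically_high_risk': True, 'ifg': True, 'weight_status': None, 'hypertension': True, 'diabetes': True}
effective tier: high
referral: yes (high_cvd_risk, ifg)
next CVD screening: 3 months
diabetes screening flag: yes
medications: antiplatelet, bp_lowering, lipid_lowering
advice: lifestyle, nutrition, smoking_cessation
projection: R40_PLUS -> R20_30
```

Reading this: cholesterol is known, so the High-Information chart was
used; the participant lands in the top (≥40%) band and is also
clinically high risk (SBP ≥160), so he is referred, gets a 3-month
re-screening interval and all three medication classes, and the
projection shows that a 10 mmHg SBP reduction alone would move him
down to the 20–<30% band. (Age 33 is below the lowest chart band,
hence the clamp warning.)

Batch screening and simulation from the shell:

```sh
cvdscreen simulate cohort --n 292 --seed 1 --out cohort.csv
cvdscreen batch-screen cohort.csv --out results.csv
cvdscreen simulate events --seed 5 --n-procedures 20 --out-dir sim/
cvdscreen analytics timing sim/events.csv --by-step
cvdscreen analytics bootstrap sim/events.csv --seed 1
cvdscreen analytics glucose-errors sim/events.csv --meter sim/meter.csv
```

## Layout

```
src/cvdscreen/
  encounter.py   four-step record, validation, BMI/BP/age derivations
  risk.py        chart model, loader, assessment, projection
  fixtures.py    synthetic fixture charts
  rules.py       sub-conditions and the management decision table
  analytics.py   click-stream evaluation framework
  synth.py       cohort / event-stream / glucometer generators
  cli.py         command-line interface
  data/          synthetic charts (CSV) and default rules (YAML)
docs/methods.md  models, parameters, numerical choices, limitations
```
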