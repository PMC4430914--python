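# Methods

This note documents the models, rules and numerical choices behind
`cvdscreen`: a chart-based 10-year cardiovascular-disease (CVD) risk
screening engine with point-of-care decision support, an analytics
framework for evaluating field use from click-event streams, and a
synthetic-data generator that stands in for field data.

## Risk categorisation

Ten-year absolute CVD risk is assessed by categorical lookup in a
WHO/ISH-style colour chart: five ordered bands (<10%, 10–<20%, 20–<30%,
30–<40%, ≥40%) indexed by diabetes status, gender, smoking status, age
band (40–49, 50–59, 60–69, 70+), systolic blood pressure band (<140,
140–159, 160–179, ≥180 mmHg) and, in the High-Information (HI)
variant, a total-cholesterol band (<5, 5–<6, 6–<7, 7–<8, ≥8 mmol/L).
The Low-Information (LI) variant omits cholesterol and is selected
automatically whenever total cholesterol is unknown.

Numerical conventions:

* **Half-open bands.** Lower edges inclusive, upper edges exclusive,
  topmost band closed above (SBP 159 → 140–159; 160 → 160–179).
* **Units.** The data model stores cholesterol in mg/dL (the format
  point-of-care analysers report); chart edges are mmol/L. Conversion
  uses the molar factor 38.67 mg/dL per mmol/L at lookup time.
  Glucose conversion for reporting uses 18.016 mg/dL per mmol/L
  (molar mass/10). Note the second decimal of a converted IQR can
  differ from sources that divide by 18.0.
* **BP input.** The chart consumes a single representative pair: the
  mean of the last two of three cuff readings (the first reading is
  discarded as an acclimatisation artefact), rounded half-up to integer
  mmHg; with fewer than three readings, the mean of all.
* **Under-age participants.** Screening programmes occasionally enrol
  adults younger than the lowest chart band; these are clamped to the
  40–49 band and the result carries an `age_clamped` warning rather
  than failing.
* **Diabetes input.** History of diabetes, or measured fasting glucose
  ≥126 mg/dL, or random glucose ≥200 mg/dL.

The engine is chart-agnostic. Published chart cell values are not
redistributed; users transcribe their regional chart into the CSV
dialect (`region,variant,diabetes,gender,smoker,age_band,sbp_band,
tc_band,category`). The loader enforces totality over the full grid —
128 LI cells and 640 HI cells (2 diabetes × 2 gender × 2 smoking ×
4 age × 4 SBP × [5 TC]) — and rejects duplicate or mislabelled rows
naming the offending row. The repository ships *synthetic* fixture
charts built from an additive score monotone in every factor
(`cvdscreen.fixtures`); they are labelled synthetic, are not clinical
tables, and exist so that tests and examples are self-contained. The
HI fixture is constructed so the worked projection example (young male
smoker with diabetes, 160/89 mmHg, TC 176 mg/dL) sits in the top band
and falls to 20–<30% when SBP drops by one band.

### Counterfactual projection

`project_risk` re-assesses a modified copy of the profile (additive
deltas or replacements on SBP, total cholesterol, smoking, diabetes)
and returns (before, after); the input is immutable. When raw cuff
readings are present an SBP delta is applied to the summarised value
and the readings are cleared on the copy, so the projected value is
exactly what the chart sees.

## Sub-conditions and management plan

Sub-conditions derived from the same profile:

| flag | definition |
|---|---|
| clinically high risk (CHR) | SBP ≥160 or DBP ≥100 mmHg, or TC ≥320 or LDL ≥240 mg/dL, or TC/HDL > 8 |
| impaired fasting glucose (IFG) | fasting glucose in 110–<126 mg/dL, **or history of diabetes** |
| weight status | obese BMI ≥30; overweight 25–<30 (thresholds applied to unrounded BMI) |
| hypertension | SBP ≥140 or DBP ≥90 mmHg, or history of hypertension |
| diabetes | history, or fasting ≥126, or random ≥200 mg/dL |

The IFG definition deliberately folds in diabetes history — that is how
the source decision table was specified, even though it conflates IFG
with frank diabetes. It is implemented literally; consumers who need
"pure" IFG can test the glucose band directly.

The management plan is driven by an *effective tier*: the chart band,
escalated to the high tier when the band is ≥30%, the participant has
prior CVD (MI/angina, stroke or PVD), or CHR holds. The full decision
table ships as `data/default_rules.yaml` and is validated for
completeness at load; every threshold and conditional can be
overridden by pointing the tools at a different rules file.

Default table: high tier — refer, re-screen at 3 months (3–6
configurable), all three medication classes (BP-lowering,
lipid-lowering, antiplatelet). 20–<30% — refer, 12 months,
BP-lowering if BP ≥140/90, lipid-lowering if diabetes or SBP ≥160 or
TC >200 or LDL >120 mg/dL. 10–<20% and <10% — 24 / 60 months; refer
if diabetes or IFG, or history of diabetes with SBP ≥160;
BP-lowering if (diabetes and BP ≥140/90) or SBP ≥160; lipid-lowering
if diabetes or SBP ≥160. An IFG flag always forces a referral and
sets the diabetes-screening flag. Detailed smoking-cessation advice is
issued only to smokers; nutrition and lifestyle advice to everyone.

Referral reasons use a two-bucket vocabulary, `high_cvd_risk` and
`ifg`, matching how screening outcomes are reported (referred for high
CVD risk vs for glucose abnormality). Tier-driven referrals are
bucketed under `high_cvd_risk`; diabetes/IFG-conditional referrals in
the low tiers under `ifg`.

Design note: whether CHR alone should trigger all three medication
classes is an interpretation — the high-tier escalation treats
CHR-positive participants identically to band-≥30% participants, which
is consistent with reporting that groups "band >30% or CHR or CVD" as
one high-risk class. The rules file makes the escalation configurable.

## Field-evaluation analytics

Every tap in the screening app is logged as
`timestamp,user_id,encounter_id,step,element_id,value`. Procedures are
reconstructed per encounter; a procedure is *complete* when its step-4
completion event exists, and two procedures of the same worker whose
time spans overlap are both flagged *non-sequential*. Timing analyses
use complete, sequential procedures only; rates use the same
denominator (that worker's complete procedures), so Bluetooth and
dissemination percentages are directly comparable.

* **Timing.** Median and IQR (Q3−Q1, linear interpolation between
  order statistics) of total or per-step durations, in seconds.
* **Sequential bootstrap CI.** At procedure index k the sample is all
  durations up to and including k, resampled with replacement
  (default 2000 resamples; a seed is mandatory). The point estimate is
  the mean of bootstrap means. Intervals are *expanded percentile*
  intervals (Hesterberg's small-sample adjustment: the tail
  probability α/2 is widened to Φ(√(k/(k−1))·t₍α/2,k−1₎)). The plain
  percentile interval was measured to cover the true mean only ~91% of
  the time at n=20 on normal data; the expanded interval restores
  ~94–95% and converges to the plain interval as k grows.
* **Bluetooth adoption.** Fraction of procedures with a Bluetooth BP
  transmission event; acquisition time is the span from the BP
  sub-step start to the first receipt. An optional split index reports
  adoption before/after the Nth procedure.
* **Dissemination.** Per worker and management section (risk meter,
  recommendations, next visit), the fraction of procedures with at
  least one open event. Displayed percentages are rounded to the
  nearest integer; raw fractions are always retained and are the
  authoritative values.
* **Glucose-entry reconciliation.** Entered values are matched
  one-to-one to the nearest-in-time glucometer record within a
  tolerance window (default ±10 minutes), greedily by time gap; the
  error is |entered − meter| and any non-zero discrepancy counts as an
  error. Median/IQR are over non-zero errors. Matching is per
  worker/meter — pooling meters across workers creates spurious
  cross-matches.
* **Likert.** Counts per 1–4 rating, fraction at or above a threshold
  (default 3), minimum rating; out-of-scale ratings are rejected at
  parse.

## Synthetic-data generator

The generator defines the study conditions for all stochastic tests.

**Cohort.** A two-stratum mixture with `round(n × target)` high-risk
draws; defaults n=292, target 34%, ages truncated-normal with mean
51.4, SD 13.1 on [40, 90]. The high stratum draws SBP ~ N(178, 14),
TC ~ N(250, 40) mg/dL, diabetes history 35%, prior CVD ~12%, smoking
45%; the low stratum SBP ~ N(122, 10), TC ~ N(180, 25), fasting
glucose ~ N(106, 13) (placing ~30% of low-stratum draws in the IFG
band, so the referral rate lands near the high-50s percent that
door-to-door screening of this kind reports), diabetes history 2%,
smoking 20%. The realised high-or-CHR-or-CVD fraction is measured
against the fixture charts and the cohort redrawn (bounded retries)
if it misses the target by more than 5 points, warning if it cannot be
reached. Heights/BMI are normal; all draws are clipped to the
validation ranges.

**Click streams.** Per-step durations are lognormal (positive,
right-skewed, matching the wide observed IQRs) with medians
(157, 68, 633, 90) s for steps 1–4 and inter-step idle gaps of median
107 s, giving a whole-procedure median near 21 minutes. Learning is a
geometric decay of every median, `decay^(i − (n−1)/2)`, centred on the
study midpoint so the study-wide median is decay-invariant; because
every duration component scales by the same factor, the
across-replicate median of total time is exactly proportional to
`decay^i`, which is what the log-linear recovery fit assumes.
Bluetooth adoption follows a logistic curve in the procedure index
(default 0.2 → 0.8, midpoint 10); BP acquisition-time medians are
320 s (Bluetooth) / 460 s (manual). Management-section opens are
independent Bernoulli draws per section; one glucose entry per
procedure is corrupted with configured probability by transposing two
adjacent digits or slipping one digit by ±1–5 (always producing a
different, plausible value, so injected error counts are exact);
ratings are drawn from a configurable Likert distribution (default
72% rating 4, 28% rating 3, so no rating below 3).

**Glucometer memory.** One record per entry at the true value,
timestamped 120 s before the entry — well inside the matching window.

**What the generator does not emulate:** household/geographic
structure, repeat visits, inter-worker correlation, drift in device
behaviour, missingness patterns, or any demographic realism beyond the
moments above. Passing tests therefore demonstrate that the analytics
recover known generating parameters under these idealised conditions,
not that field data of any particular deployment would behave this
way.

## Problem sizes and degenerate inputs

Tests and the acceptance script run at desk scale: exhaustive oracle
grids of 768 chart cells and ~3000 decision-table cases, bootstrap
calibration with 1000 replicates of n=20 (1000 resamples each),
learning-decay recovery from 200 replicate 28-procedure streams, and a
simulated 11-worker, 227-procedure deployment. Degenerate inputs are
defined rather than accidental: empty BP reading lists, empty duration
series, empty rating lists and empty cohorts raise `ValueError`;
constant bootstrap input collapses its intervals to the point;
missing lipids never trigger rule arms; unknown (tri-state) history
flags act as "no" in rules but are preserved in storage.

## Known limitations

* Shipped charts are synthetic; clinical use requires transcribing the
  appropriate regional chart and validating it with `validate-chart`.
* The IFG flag includes diabetes history by specification (see above).
* The non-sequential heuristic is span overlap within a worker; it
  cannot distinguish a genuinely interleaved pair from a paused and
  resumed encounter.
* The greedy time-gap glucose matcher is not a globally optimal
  assignment; with the default 10-minute window and per-worker meters
  this makes no practical difference.
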