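# Default point-of-care decision table: referral, medication and
# next-visit rules per effective CVD risk tier.
#
# Tiers: "high" (band >=30%, or prior CVD, or clinically-high-risk —
# see high_tier_escalation), then the chart bands R20_30 / R10_20 /
# R0_10.  Conditions are single-key mappings: {always: bool},
# {flag: name}, {field: {name, op, value}}, {any: [...]}, {all: [...]}.
# Flags: diabetes, ifg, past_diabetes, past_cvd, clinically_high_risk,
# hypertension, smoker.  Fields (mg/dL, mmHg): sbp, dbp, tc, ldl, hdl,
# glucose.

high_tier_escalation:
  min_band: R30_40
  past_cvd: true
  clinically_high_risk: true

tiers:
  high:
    interval_months: 3          # follow-up every 3-6 months; 3 by default
    interval_range_months: [3, 6]
    referral: {always: true}
    medications:
      bp_lowering: {always: true}
      lipid_lowering: {always: true}
      antiplatelet: {always: true}

  R20_30:
    interval_months: 12
    referral: {always: true}
    medications:
      bp_lowering:
        any:
          - {field: {name: sbp, op: ge, value: 140}}
          - {field: {name: dbp, op: ge, value: 90}}
      lipid_lowering:
        any:
          - {flag: diabetes}
          - {field: {name: sbp, op: ge, value: 160}}
          - {field: {name: tc, op: gt, value: 200}}
          - {field: {name: ldl, op: gt, value: 120}}
      antiplatelet: {always: false}

  R10_20:
    interval_months: 24
    referral:
      any:
        - {flag: diabetes}
        - {flag: ifg}
        - all:
            - {flag: past_diabetes}
            - {field: {name: sbp, op: ge, value: 160}}
    medications:
      bp_lowering:
        any:
          - all:
              - {flag: diabetes}
              - any:
                  - {field: {name: sbp, op: ge, value: 140}}
                  - {field: {name: dbp, op: ge, value: 90}}
          - {field: {name: sbp, op: ge, value: 160}}
      lipid_lowering:
        any:
          - {flag: diabetes}
          - {field: {name: sbp, op: ge, value: 160}}
      antiplatelet: {always: false}

  R0_10:
    interval_months: 60
    referral:
      any:
        - {flag: diabetes}
        - {flag: ifg}
        - all:
            - {flag: past_diabetes}
            - {field: {name: sbp, op: ge, value: 160}}
    medications:
      bp_lowering:
        any:
          - all:
              - {flag: diabetes}
              - any:
                  - {field: {name: sbp, op: ge, value: 140}}
                  - {field: {name: dbp, op: ge, value: 90}}
          - {field: {name: sbp, op: ge, value: 160}}
      lipid_lowering:
        any:
          - {flag: diabetes}
          - {field: {name: sbp, op: ge, value: 160}}
      antiplatelet: {always: false}
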