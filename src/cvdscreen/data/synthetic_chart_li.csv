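region,variant,diabetes,gender,smoker,age_band,sbp_band,tc_band,category
synthetic,LI,no,male,no,40-49,lt140,NA,R0_10
synthetic,LI,no,male,no,40-49,140-159,NA,R0_10
synthetic,LI,no,male,no,40-49,160-179,NA,R20_30
synthetic,LI,no,male,no,40-49,180+,NA,R40_PLUS
synthetic,LI,no,male,no,50-59,lt140,NA,R0_10
synthetic,LI,no,male,no,50-59,140-159,NA,R10_20
synthetic,LI,no,male,no,50-59,160-179,NA,R30_40
synthetic,LI,no,male,no,50-59,180+,NA,R40_PLUS
synthetic,LI,no,male,no,60-69,lt140,NA,R0_10
synthetic,LI,no,male,no,60-69,140-159,NA,R20_30
synthetic,LI,no,male,no,60-69,160-179,NA,R40_PLUS
synthetic,LI,no,male,no,60-69,180+,NA,R40_PLUS
synthetic,LI,no,male,no,70+,lt140,NA,R10_20
synthetic,LI,no,male,no,70+,140-159,NA,R30_40
synthetic,LI,no,male,no,70+,160-179,NA,R40_PLUS
synthetic,LI,no,male,no,70+,180+,NA,R40_PLUS
synthetic,LI,no,male,yes,40-49,lt140,NA,R0_10
synthetic,LI,no,male,yes,40-49,140-159,NA,R10_20
synthetic,LI,no,male,yes,40-49,160-179,NA,R30_40
synthetic,LI,no,male,yes,40-49,180+,NA,R40_PLUS
synthetic,LI,no,male,yes,50-59,lt140,NA,R0_10
synthetic,LI,no,male,yes,50-59,140-159,NA,R20_30
synthetic,LI,no,male,yes,50-59,160-179,NA,R40_PLUS
synthetic,LI,no,male,yes,50-59,180+,NA,R40_PLUS
synthetic,LI,no,male,yes,60-69,lt140,NA,R10_20
synthetic,LI,no,male,yes,60-69,140-159,NA,R30_40
synthetic,LI,no,male,yes,60-69,160-179,NA,R40_PLUS
synthetic,LI,no,male,yes,60-69,180+,NA,R40_PLUS
synthetic,LI,no,male,yes,70+,lt140,NA,R20_30
synthetic,LI,no,male,yes,70+,140-159,NA,R40_PLUS
synthetic,LI,no,male,yes,70+,160-179,NA,R40_PLUS
synthetic,LI,no,male,yes,70+,180+,NA,R40_PLUS
synthetic,LI,no,female,no,40-49,lt140,NA,R0_10
synthetic,LI,no,female,no,40-49,140-159,NA,R0_10
synthetic,LI,no,female,no,40-49,160-179,NA,R10_20
synthetic,LI,no,female,no,40-49,180+,NA,R30_40
synthetic,LI,no,female,no,50-59,lt140,NA,R0_10
synthetic,LI,no,female,no,50-59,140-159,NA,R0_10
synthetic,LI,no,female,no,50-59,160-179,NA,R20_30
synthetic,LI,no,female,no,50-59,180+,NA,R40_PLUS
synthetic,LI,no,female,no,60-69,lt140,NA,R0_10
synthetic,LI,no,female,no,60-69,140-159,NA,R10_20
synthetic,LI,no,female,no,60-69,160-179,NA,R30_40
synthetic,LI,no,female,no,60-69,180+,NA,R40_PLUS
synthetic,LI,no,female,no,70+,lt140,NA,R0_10
synthetic,LI,no,female,no,70+,140-159,NA,R20_30
synthetic,LI,no,female,no,70+,160-179,NA,R40_PLUS
synthetic,LI,no,female,no,70+,180+,NA,R40_PLUS
synthetic,LI,no,female,yes,40-49,lt140,NA,R0_10
synthetic,LI,no,female,yes,40-49,140-159,NA,R0_10
synthetic,LI,no,female,yes,40-49,160-179,NA,R20_30
synthetic,LI,no,female,yes,40-49,180+,NA,R40_PLUS
synthetic,LI,no,female,yes,50-59,lt140,NA,R0_10
synthetic,LI,no,female,yes,50-59,140-159,NA,R10_20
synthetic,LI,no,female,yes,50-59,160-179,NA,R30_40
synthetic,LI,no,female,yes,50-59,180+,NA,R40_PLUS
synthetic,LI,no,female,yes,60-69,lt140,NA,R0_10
synthetic,LI,no,female,yes,60-69,140-159,NA,R20_30
synthetic,LI,no,female,yes,60-69,160-179,NA,R40_PLUS
synthetic,LI,no,female,yes,60-69,180+,NA,R40_PLUS
synthetic,LI,no,female,yes,70+,lt140,NA,R10_20
synthetic,LI,no,female,yes,70+,140-159,NA,R30_40
synthetic,LI,no,female,yes,70+,160-179,NA,R40_PLUS
synthetic,LI,no,female,yes,70+,180+,NA,R40_PLUS
synthetic,LI,yes,male,no,40-49,lt140,NA,R0_10
synthetic,LI,yes,male,no,40-49,140-159,NA,R20_30
synthetic,LI,yes,male,no,40-49,160-179,NA,R40_PLUS
synthetic,LI,yes,male,no,40-49,180+,NA,R40_PLUS
synthetic,LI,yes,male,no,50-59,lt140,NA,R10_20
synthetic,LI,yes,male,no,50-59,140-159,NA,R30_40
synthetic,LI,yes,male,no,50-59,160-179,NA,R40_PLUS
synthetic,LI,yes,male,no,50-59,180+,NA,R40_PLUS
synthetic,LI,yes,male,no,60-69,lt140,NA,R20_30
synthetic,LI,yes,male,no,60-69,140-159,NA,R40_PLUS
synthetic,LI,yes,male,no,60-69,160-179,NA,R40_PLUS
synthetic,LI,yes,male,no,60-69,180+,NA,R40_PLUS
synthetic,LI,yes,male,no,70+,lt140,NA,R30_40
synthetic,LI,yes,male,no,70+,140-159,NA,R40_PLUS
synthetic,LI,yes,male,no,70+,160-179,NA,R40_PLUS
synthetic,LI,yes,male,no,70+,180+,NA,R40_PLUS
synthetic,LI,yes,male,yes,40-49,lt140,NA,R10_20
synthetic,LI,yes,male,yes,40-49,140-159,NA,R30_40
synthetic,LI,yes,male,yes,40-49,160-179,NA,R40_PLUS
synthetic,LI,yes,male,yes,40-49,180+,NA,R40_PLUS
synthetic,LI,yes,male,yes,50-59,lt140,NA,R20_30
synthetic,LI,yes,male,yes,50-59,140-159,NA,R40_PLUS
synthetic,LI,yes,male,yes,50-59,160-179,NA,R40_PLUS
synthetic,LI,yes,male,yes,50-59,180+,NA,R40_PLUS
synthetic,LI,yes,male,yes,60-69,lt140,NA,R30_40
synthetic,LI,yes,male,yes,60-69,140-159,NA,R40_PLUS
synthetic,LI,yes,male,yes,60-69,160-179,NA,R40_PLUS
synthetic,LI,yes,male,yes,60-69,180+,NA,R40_PLUS
synthetic,LI,yes,male,yes,70+,lt140,NA,R40_PLUS
synthetic,LI,yes,male,yes,70+,140-159,NA,R40_PLUS
synthetic,LI,yes,male,yes,70+,160-179,NA,R40_PLUS
synthetic,LI,yes,male,yes,70+,180+,NA,R40_PLUS
synthetic,LI,yes,female,no,40-49,lt140,NA,R0_10
synthetic,LI,yes,female,no,40-49,140-159,NA,R10_20
synthetic,LI,yes,female,no,40-49,160-179,NA,R30_40
synthetic,LI,yes,female,no,40-49,180+,NA,R40_PLUS
synthetic,LI,yes,female,no,50-59,lt140,NA,R0_10
synthetic,LI,yes,female,no,50-59,140-159,NA,R20_30
synthetic,LI,yes,female,no,50-59,160-179,NA,R40_PLUS
synthetic,LI,yes,female,no,50-59,180+,NA,R40_PLUS
synthetic,LI,yes,female,no,60-69,lt140,NA,R10_20
synthetic,LI,yes,female,no,60-69,140-159,NA,R30_40
synthetic,LI,yes,female,no,60-69,160-179,NA,R40_PLUS
synthetic,LI,yes,female,no,60-69,180+,NA,R40_PLUS
synthetic,LI,yes,female,no,70+,lt140,NA,R20_30
synthetic,LI,yes,female,no,70+,140-159,NA,R40_PLUS
synthetic,LI,yes,female,no,70+,160-179,NA,R40_PLUS
synthetic,LI,yes,female,no,70+,180+,NA,R40_PLUS
synthetic,LI,yes,female,yes,40-49,lt140,NA,R0_10
synthetic,LI,yes,female,yes,40-49,140-159,NA,R20_30
synthetic,LI,yes,female,yes,40-49,160-179,NA,R40_PLUS
synthetic,LI,yes,female,yes,40-49,180+,NA,R40_PLUS
synthetic,LI,yes,female,yes,50-59,lt140,NA,R10_20
synthetic,LI,yes,female,yes,50-59,140-159,NA,R30_40
synthetic,LI,yes,female,yes,50-59,160-179,NA,R40_PLUS
synthetic,LI,yes,female,yes,50-59,180+,NA,R40_PLUS
synthetic,LI,yes,female,yes,60-69,lt140,NA,R20_30
synthetic,LI,yes,female,yes,60-69,140-159,NA,R40_PLUS
synthetic,LI,yes,female,yes,60-69,160-179,NA,R40_PLUS
synthetic,LI,yes,female,yes,60-69,180+,NA,R40_PLUS
synthetic,LI,yes,female,yes,70+,lt140,NA,R30_40
synthetic,LI,yes,female,yes,70+,140-159,NA,R40_PLUS
synthetic,LI,yes,female,yes,70+,160-179,NA,R40_PLUS
synthetic,LI,yes,female,yes,70+,180+,NA,R40_PLUS
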