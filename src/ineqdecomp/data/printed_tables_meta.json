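{
 "disability_by_wave": {
  "row_variable": "disability_type",
  "col_variable": "wave",
  "row_labels": [
   "physical",
   "intellectual",
   "vision",
   "hearing",
   "speech",
   "multiple"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 129.517
 },
 "gender_by_wave": {
  "row_variable": "gender",
  "col_variable": "wave",
  "row_labels": [
   "male",
   "female"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 11.793
 },
 "age_by_wave": {
  "row_variable": "age_band",
  "col_variable": "wave",
  "row_labels": [
   "45-59",
   "60-74",
   "75+"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 89.041
 },
 "self_rated_health_by_wave": {
  "row_variable": "self_rated_health",
  "col_variable": "wave",
  "row_labels": [
   "good",
   "general",
   "poor"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 6.025
 },
 "chronic_by_wave": {
  "row_variable": "chronic_disease",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 224.418
 },
 "adl_by_wave": {
  "row_variable": "adl_limited",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 2.218
 },
 "iadl_by_wave": {
  "row_variable": "iadl_limited",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 20.159
 },
 "expenditure_quintile_by_wave": {
  "row_variable": "expenditure_quintile",
  "col_variable": "wave",
  "row_labels": [
   "low",
   "low_middle",
   "average",
   "high_middle",
   "high"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 1.185
 },
 "smoking_by_wave": {
  "row_variable": "smoking",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 76.277
 },
 "drinking_by_wave": {
  "row_variable": "drinking",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 10.159
 },
 "marital_by_wave": {
  "row_variable": "married",
  "col_variable": "wave",
  "row_labels": [
   "other",
   "married"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 31.029
 },
 "education_by_wave": {
  "row_variable": "education",
  "col_variable": "wave",
  "row_labels": [
   "illiterate",
   "below_primary",
   "primary",
   "junior_plus"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 80.633
 },
 "social_by_wave": {
  "row_variable": "social_activity",
  "col_variable": "wave",
  "row_labels": [
   "none",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 53.084
 },
 "child_support_by_wave": {
  "row_variable": "child_support",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 882.255
 },
 "region_by_wave": {
  "row_variable": "region",
  "col_variable": "wave",
  "row_labels": [
   "western",
   "central",
   "eastern"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 22.723
 },
 "insurance_by_wave": {
  "row_variable": "insured",
  "col_variable": "wave",
  "row_labels": [
   "no",
   "yes"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 80.253
 },
 "outpatient_by_wave": {
  "row_variable": "outpatient",
  "col_variable": "wave",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 36.087
 },
 "inpatient_by_wave": {
  "row_variable": "inpatient",
  "col_variable": "wave",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 194.602
 },
 "self_treatment_by_wave": {
  "row_variable": "self_treatment",
  "col_variable": "wave",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015",
   "2018"
  ],
  "printed_chi2": 95.511
 },
 "forgone_outpatient_by_wave": {
  "row_variable": "forgone_outpatient",
  "col_variable": "wave",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015"
  ],
  "printed_chi2": 12.274
 },
 "forgone_hospitalization_by_wave": {
  "row_variable": "forgone_hospitalization",
  "col_variable": "wave",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "2011",
   "2013",
   "2015"
  ],
  "printed_chi2": 17.68
 },
 "outpatient_by_type": {
  "row_variable": "outpatient",
  "col_variable": "disability_type",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "physical",
   "intellectual",
   "vision",
   "hearing",
   "speech",
   "multiple"
  ],
  "printed_chi2": 27.393
 },
 "inpatient_by_type": {
  "row_variable": "inpatient",
  "col_variable": "disability_type",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "physical",
   "intellectual",
   "vision",
   "hearing",
   "speech",
   "multiple"
  ],
  "printed_chi2": 104.217
 },
 "forgone_outpatient_by_type": {
  "row_variable": "forgone_outpatient",
  "col_variable": "disability_type",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "physical",
   "intellectual",
   "vision",
   "hearing",
   "speech",
   "multiple"
  ],
  "printed_chi2": 1.943
 },
 "forgone_hospitalization_by_type": {
  "row_variable": "forgone_hospitalization",
  "col_variable": "disability_type",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "physical",
   "intellectual",
   "vision",
   "hearing",
   "speech",
   "multiple"
  ],
  "printed_chi2": 62.364
 },
 "self_treatment_by_type": {
  "row_variable": "self_treatment",
  "col_variable": "disability_type",
  "row_labels": [
   "yes",
   "no"
  ],
  "col_labels": [
   "physical",
   "intellectual",
   "vision",
   "hearing",
   "speech",
   "multiple"
  ],
  "printed_chi2": 9.861
 }
}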