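name: ami
provenance: >
  Claims-phenotyping algorithm for acute myocardial infarction.  A single
  matching diagnosis code in any position and any healthcare setting is
  sufficient for case identification.  Subsequent-episode-of-care codes
  (410.x2), old myocardial infarction, intermediate coronary syndrome,
  angina pectoris and chronic ischaemic heart disease are deliberately
  excluded.  ICD-9-CM codes apply before 2015-10-01, ICD-10-CM codes on or
  after that date.
patterns:
  - pattern: "410.x0"
    version: icd9cm
    description: AMI, episode of care unspecified
  - pattern: "410.x1"
    version: icd9cm
    description: AMI, initial episode of care
  - pattern: "I21.xx"
    version: icd10cm
    description: Acute myocardial infarction
  - pattern: "I22.x"
    version: icd10cm
    description: Subsequent STEMI and NSTEMI myocardial infarction
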