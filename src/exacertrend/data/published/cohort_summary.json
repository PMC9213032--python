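{
  "database_patients": 9949387,
  "asthma_patients": 571166,
  "exacerbator_patients": 100362,
  "patient_years": 502669,
  "episodes_total": 298390,
  "episodes_primary_care": 263120,
  "episodes_hospital": 35270,
  "stayers_cohort": 58776,
  "young_cohort": 27095,
  "males": 38922,
  "females": 59990,
  "missing_sex": 1450,
  "missing_birth_year": 146
}
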