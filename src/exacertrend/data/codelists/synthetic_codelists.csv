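code,description,role
H33..,Asthma,asthma_diagnosis
H330.,Extrinsic (atopic) asthma,asthma_diagnosis
H331.,Intrinsic asthma,asthma_diagnosis
H33z.,Asthma unspecified,asthma_diagnosis
663m.,Asthma A&E attendance since last visit,ae_attendance
663n.,Asthma treated in casualty,ae_attendance
8H2P.,Emergency hospital admission for asthma,hospital_admission
662L.,Hospital admission,hospital_admission
66YJ.,Asthma annual review,respiratory_review
663U.,Asthma management plan review,respiratory_review
66YK.,Respiratory disease monitoring,respiratory_review
ocs_prednisolone,Prednisolone oral corticosteroid course,ocs
ocs_dexamethasone,Dexamethasone oral corticosteroid course,ocs
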