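# Expert-rule (El-Serag-style) configuration: an exam is screening iff the
# patient has NO claim matching any of the 28 disqualifying symptom/condition
# code entries within their windows AND no colonoscopy procedure code in the
# past 4 years.
#
# The original rule names 28 ICD-9 symptoms/conditions; the concrete code list
# is not public, so the default entries below are named placeholders (a
# superset of the claim categories the synthetic generator emits, plus
# additional lower-GI symptoms/conditions an expert panel would disqualify).
# Codes for categories the generator does not emit never match synthetic data
# but keep the rule's structure editable for real code inventories.
#
# The diagnosis-code window is not documented for the original rule; it
# defaults to 4 years to mirror the colonoscopy clause, and is configurable
# per entry.
colonoscopy_lookback_days: 1460
colonoscopy_codes:
  - {system: billing-procedure, code: PROC-COLON-01}
  - {system: CCP, code: PROC-COLON-02}
disqualifying:
  - {name: rectal_bleeding, lookback_days: 1460, codes: [{system: ICD-9, code: DX-RBLEED-01}, {system: ICD-10, code: DX-RBLEED-02}]}
  - {name: diarrhea, lookback_days: 1460, codes: [{system: ICD-9, code: DX-DIARR-01}, {system: ICD-10, code: DX-DIARR-02}]}
  - {name: vomiting, lookback_days: 1460, codes: [{system: ICD-9, code: DX-VOMIT-01}, {system: ICD-10, code: DX-VOMIT-02}]}
  - {name: weight_loss, lookback_days: 1460, codes: [{system: ICD-9, code: DX-WTLOSS-01}, {system: ICD-10, code: DX-WTLOSS-02}]}
  - {name: anemia, lookback_days: 1460, codes: [{system: ICD-9, code: DX-ANEMIA-01}, {system: ICD-10, code: DX-ANEMIA-02}]}
  - {name: colorectal_cancer, lookback_days: 1460, codes: [{system: ICD-9, code: DX-CRC-01}, {system: ICD-10, code: DX-CRC-02}]}
  - {name: colorectal_polyps, lookback_days: 1460, codes: [{system: ICD-9, code: DX-POLYP-01}, {system: ICD-10, code: DX-POLYP-02}]}
  - {name: inflammatory_bowel_disease, lookback_days: 1460, codes: [{system: ICD-9, code: DX-IBD-01}, {system: ICD-10, code: DX-IBD-02}]}
  - {name: large_bowel_disease_hospitalization, lookback_days: 1460, codes: [{system: ICD-9, code: HOSP-LBD-01}, {system: ICD-10, code: HOSP-LBD-02}]}
  - {name: large_bowel_surgery, lookback_days: 1460, codes: [{system: CCI, code: SURG-LB-01}, {system: CCP, code: SURG-LB-02}]}
  - {name: abdominal_pain, lookback_days: 1460, codes: [{system: ICD-9, code: DX-ABDPAIN-01}]}
  - {name: constipation, lookback_days: 1460, codes: [{system: ICD-9, code: DX-CONSTIP-01}]}
  - {name: change_in_bowel_habit, lookback_days: 1460, codes: [{system: ICD-9, code: DX-CBH-01}]}
  - {name: melena, lookback_days: 1460, codes: [{system: ICD-9, code: DX-MELENA-01}]}
  - {name: positive_occult_blood, lookback_days: 1460, codes: [{system: ICD-9, code: DX-FOBT-01}]}
  - {name: hemorrhoids, lookback_days: 1460, codes: [{system: ICD-9, code: DX-HEMRD-01}]}
  - {name: diverticulosis, lookback_days: 1460, codes: [{system: ICD-9, code: DX-DIVOS-01}]}
  - {name: diverticulitis, lookback_days: 1460, codes: [{system: ICD-9, code: DX-DIVIT-01}]}
  - {name: irritable_bowel_syndrome, lookback_days: 1460, codes: [{system: ICD-9, code: DX-IBS-01}]}
  - {name: intestinal_obstruction, lookback_days: 1460, codes: [{system: ICD-9, code: DX-OBSTR-01}]}
  - {name: ischemic_colitis, lookback_days: 1460, codes: [{system: ICD-9, code: DX-ISCHCOL-01}]}
  - {name: infectious_colitis, lookback_days: 1460, codes: [{system: ICD-9, code: DX-INFCOL-01}]}
  - {name: celiac_disease, lookback_days: 1460, codes: [{system: ICD-9, code: DX-CELIAC-01}]}
  - {name: abdominal_mass, lookback_days: 1460, codes: [{system: ICD-9, code: DX-ABDMASS-01}]}
  - {name: nausea, lookback_days: 1460, codes: [{system: ICD-9, code: DX-NAUSEA-01}]}
  - {name: anorexia, lookback_days: 1460, codes: [{system: ICD-9, code: DX-ANOREX-01}]}
  - {name: other_gi_malignancy, lookback_days: 1460, codes: [{system: ICD-9, code: DX-GIMAL-01}]}
  - {name: gi_fistula, lookback_days: 1460, codes: [{system: ICD-9, code: DX-FISTULA-01}]}
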