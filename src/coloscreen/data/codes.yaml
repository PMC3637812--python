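# Code dictionary mapping predictor categories to claim codes and lookback
# windows (days before the index colonoscopy; windows are half-open,
# [index - lookback, index), so the index day itself never counts).
#
# The codes below are synthetic placeholders: real provincial inventories
# (RAMQ billing, CCP/CCI procedure, ICD-9/ICD-10 diagnosis codes) are not in
# the public domain in usable form, and the classification logic only needs a
# consistent mapping.  Edit this file to plug in real code lists.
#
# Lookback conventions: procedures 4 y (1460 d), symptoms 1 y (365 d),
# conditions / hospitalizations / surgeries 5 y (1825 d).  Years are fixed
# day counts; leap days are deliberately ignored.
categories:
  colonoscopy:
    record_type: procedure
    lookback_days: 1460
    codes:
      - {system: billing-procedure, code: PROC-COLON-01}
      - {system: CCP, code: PROC-COLON-02}
  polypectomy:
    record_type: procedure
    lookback_days: 1460
    codes:
      - {system: billing-procedure, code: PROC-POLYP-01}
      - {system: CCP, code: PROC-POLYP-02}
  sigmoidoscopy:
    record_type: procedure
    lookback_days: 1460
    codes:
      - {system: billing-procedure, code: PROC-SIGMO-01}
      - {system: CCP, code: PROC-SIGMO-02}
  dcbe:
    record_type: procedure
    lookback_days: 1460
    codes:
      - {system: billing-procedure, code: PROC-DCBE-01}
      - {system: CCP, code: PROC-DCBE-02}
  rectal_bleeding:
    record_type: diagnosis
    lookback_days: 365
    codes:
      - {system: ICD-9, code: DX-RBLEED-01}
      - {system: ICD-10, code: DX-RBLEED-02}
  diarrhea:
    record_type: diagnosis
    lookback_days: 365
    codes:
      - {system: ICD-9, code: DX-DIARR-01}
      - {system: ICD-10, code: DX-DIARR-02}
  vomiting:
    record_type: diagnosis
    lookback_days: 365
    codes:
      - {system: ICD-9, code: DX-VOMIT-01}
      - {system: ICD-10, code: DX-VOMIT-02}
  weight_loss:
    record_type: diagnosis
    lookback_days: 365
    codes:
      - {system: ICD-9, code: DX-WTLOSS-01}
      - {system: ICD-10, code: DX-WTLOSS-02}
  anemia:
    record_type: diagnosis
    lookback_days: 365
    codes:
      - {system: ICD-9, code: DX-ANEMIA-01}
      - {system: ICD-10, code: DX-ANEMIA-02}
  crc:
    record_type: diagnosis
    lookback_days: 1825
    codes:
      - {system: ICD-9, code: DX-CRC-01}
      - {system: ICD-10, code: DX-CRC-02}
  colorectal_polyps:
    record_type: diagnosis
    lookback_days: 1825
    codes:
      - {system: ICD-9, code: DX-POLYP-01}
      - {system: ICD-10, code: DX-POLYP-02}
  ibd:
    record_type: diagnosis
    lookback_days: 1825
    codes:
      - {system: ICD-9, code: DX-IBD-01}
      - {system: ICD-10, code: DX-IBD-02}
  large_bowel_hospitalization:
    record_type: hospitalization
    lookback_days: 1825
    codes:
      - {system: ICD-9, code: HOSP-LBD-01}
      - {system: ICD-10, code: HOSP-LBD-02}
  large_bowel_surgery:
    record_type: surgery
    lookback_days: 1825
    codes:
      - {system: CCI, code: SURG-LB-01}
      - {system: CCP, code: SURG-LB-02}
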