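"""Published summary counts from the motivating two-city validation cohort.

The cohort itself (Montreal + Calgary, January-March 2007) is not public;
only summary tables are.  These counts calibrate the synthetic generator and
let in-table arithmetic (percentages from counts) be recomputed exactly.
"""

APPROACHED = 1411
ELIGIBLE_PARTICIPATING = 1230

#: patient characteristics: name -> count out of ELIGIBLE_PARTICIPATING
COHORT_COUNTS = {
    "montreal": 689,
    "calgary": 541,
    "male_sex": 597,
    "patient_reported_symptoms": 573,
    "patient_reported_gi_conditions": 350,
    "positive_fobt_past_year": 71,
    "endoscopist_screening": 576,
    "patient_indication_1_screening": 627,
    "patient_indication_2_screening": 478,
}

#: claims-code frequencies: category -> count out of ELIGIBLE_PARTICIPATING
CLAIMS_CODE_COUNTS = {
    "colonoscopy": 267,
    "sigmoidoscopy": 76,
    "polypectomy": 114,
    "dcbe": 65,
    "rectal_bleeding": 95,
    "diarrhea": 50,
    "vomiting": 7,
    "weight_loss": 8,
    "anemia": 86,
    "crc": 65,
    "colorectal_polyps": 205,
    "ibd": 48,
    "large_bowel_hospitalization": 32,
    "large_bowel_surgery": 26,
}

#: latent class reference standard: screening calls out of the cohort
LATENT_SCREENING_COUNT = 554
#: expert rule screening calls out of the cohort
EL_SERAG_SCREENING_COUNT = 395


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded as printed in the study's tables."""
    return round(100.0 * numerator / denominator, digits)
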