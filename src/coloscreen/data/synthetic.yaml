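# Default synthetic-cohort configuration.
#
# The generator emulates a two-city colonoscopy cohort of 1,230 patients aged
# 50-75 with a latent screening indication (prevalence ~46%) measured by three
# imperfect indicators: the endoscopist's stated indication (informative, high
# sensitivity/specificity) and two patient questionnaire indications (noisier).
# Indicator operating characteristics are chosen so the implied marginal
# screening frequencies match the observed ones (endoscopist 46.8%, patient
# indication 1 51.0%, patient indication 2 38.9%):
#   pi*S_j + (1-pi)*(1-C_j) = 0.464 / 0.510 / 0.392 under the defaults below.
n_patients: 1230
prevalence: 0.46
indicator_sens: [0.95, 0.85, 0.70]
indicator_spec: [0.95, 0.78, 0.87]
# Within-class covariance between the two patient indications (0 = the
# conditional-independence model; set nonzero to exercise the dependence
# variant).
dep_cov_pos: 0.0
dep_cov_neg: 0.0
age_range: [50, 75]
sex_ratio: 0.485          # probability male
index_period: ["2007-01-01", "2007-03-31"]
# Per-category P(flag | screening) / P(flag | non-screening).  Calibrated so
# that at prevalence 0.46 the marginal flag frequency matches the observed
# claims-code frequencies (colonoscopy 21.7%, sigmoidoscopy 6.2%, ...) and the
# conditional odds ratio (screening vs non-screening) matches the reported
# adjusted OR where one was reported (all < 1: history codes are more common
# before non-screening exams) and 0.5 otherwise.  Conditional values are a
# generator choice: real data constrain only the marginals and OR directions.
feature_probs:
  colonoscopy:                 {screening: 0.0754, non_screening: 0.3376}
  sigmoidoscopy:               {screening: 0.0282, non_screening: 0.0908}
  polypectomy:                 {screening: 0.0376, non_screening: 0.1402}
  dcbe:                        {screening: 0.0170, non_screening: 0.0836}
  rectal_bleeding:             {screening: 0.0209, non_screening: 0.1248}
  diarrhea:                    {screening: 0.0136, non_screening: 0.0644}
  vomiting:                    {screening: 0.0039, non_screening: 0.0078}
  weight_loss:                 {screening: 0.0046, non_screening: 0.0091}
  anemia:                      {screening: 0.0189, non_screening: 0.1136}
  crc:                         {screening: 0.0353, non_screening: 0.0681}
  colorectal_polyps:           {screening: 0.1170, non_screening: 0.2096}
  ibd:                         {screening: 0.0044, non_screening: 0.0685}
  large_bowel_hospitalization: {screening: 0.0171, non_screening: 0.0336}
  large_bowel_surgery:         {screening: 0.0138, non_screening: 0.0272}
seed: 20070101
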