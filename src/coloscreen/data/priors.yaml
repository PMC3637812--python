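# Prior distributions and MCMC settings for the latent class model.
#
# Test 1 (endoscopist indication): informative Beta(10.67, 1.06) on both
# sensitivity and specificity — ~97% of its mass lies above 0.70, encoding the
# expert judgement that the endoscopist states the true indication at least
# 70% of the time.  Tests 2-3 (patient questionnaire indications): flat
# Beta(1, 1).  Prevalence of screening: Beta(6, 7.6), ~95% of its mass on
# [0.20, 0.70].
prevalence: {a: 6.0, b: 7.6}
tests:
  - name: endoscopist
    sens: {a: 10.67, b: 1.06}
    spec: {a: 10.67, b: 1.06}
  - name: patient_1
    sens: {a: 1.0, b: 1.0}
    spec: {a: 1.0, b: 1.0}
  - name: patient_2
    sens: {a: 1.0, b: 1.0}
    spec: {a: 1.0, b: 1.0}
mcmc:
  chains: 3
  iterations: 20000
  burn_in: 5000
  thin: 5
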