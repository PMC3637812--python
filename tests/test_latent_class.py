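"""Latent class model: likelihood arithmetic, priors, Gibbs sampler,
pattern posteriors and the dichotomised reference standard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coloscreen as cs
from coloscreen.features import ConfigError
from coloscreen.latent_class import BetaPrior, LcaPriors, McmcConfig, PatternCounts

HAND_PARAMS = cs.LcaParams(0.44, [0.9, 0.8, 0.7], [0.9, 0.7, 0.8])


def test_cell_probability_hand_arithmetic():
    # 0.44*0.9*0.8*0.7 + 0.56*0.1*0.3*0.2 = 0.22512
    assert cs.cell_probability((1, 1, 1), HAND_PARAMS) == pytest.approx(0.22512, abs=1e-12)


def test_cell_probability_perfect_tests():
    p = cs.LcaParams(0.5, [1, 1, 1], [1, 1, 1])
    assert cs.cell_probability((1, 1, 1), p) == pytest.approx(0.5)
    assert cs.cell_probability((0, 0, 0), p) == pytest.approx(0.5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    pi=st.floats(0.01, 0.99),
    s=st.lists(st.floats(0.05, 0.99), min_size=3, max_size=3),
    c=st.lists(st.floats(0.05, 0.99), min_size=3, max_size=3),
    u=st.floats(0.0, 1.0),
    v=st.floats(0.0, 1.0),
)
def test_cell_probabilities_normalise_including_dependence(pi, s, c, u, v):
    lo, hi = -min(s[1] * s[2], (1 - s[1]) * (1 - s[2])), min(
        s[1] * (1 - s[2]), s[2] * (1 - s[1])
    )
    cov_pos = lo + u * (hi - lo)
    lo, hi = -min(c[1] * c[2], (1 - c[1]) * (1 - c[2])), min(
        c[1] * (1 - c[2]), c[2] * (1 - c[1])
    )
    cov_neg = lo + v * (hi - lo)
    params = cs.LcaParams(pi, s, c, cov_pos=cov_pos, cov_neg=cov_neg)
    probs = cs.cell_probabilities(params)
    assert np.all(probs >= -1e-12)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_dependence_with_zero_covariance_equals_independence():
    base = cs.cell_probabilities(HAND_PARAMS)
    dep = cs.LcaParams(0.44, [0.9, 0.8, 0.7], [0.9, 0.7, 0.8], cov_pos=0.0, cov_neg=0.0)
    assert np.allclose(cs.cell_probabilities(dep), base)


def test_covariance_outside_valid_range_is_rejected():
    with pytest.raises(ConfigError, match="cov_pos"):
        cs.LcaParams(0.4, [0.9, 0.8, 0.7], [0.9, 0.7, 0.8], cov_pos=0.5)


def test_log_likelihood_arithmetic_and_symmetry():
    counts = PatternCounts([2, 0, 0, 0, 0, 0, 0, 2])  # {000: 2, 111: 2}
    ll = cs.log_likelihood(counts, HAND_PARAMS)
    p111 = cs.cell_probability((1, 1, 1), HAND_PARAMS)
    p000 = cs.cell_probability((0, 0, 0), HAND_PARAMS)
    assert ll == pytest.approx(2 * np.log(p111) + 2 * np.log(p000), abs=1e-12)
    # label switching: (pi, S, C) -> (1 - pi, 1 - C, 1 - S) leaves it invariant
    flipped = cs.LcaParams(
        1 - HAND_PARAMS.prevalence, 1 - HAND_PARAMS.spec, 1 - HAND_PARAMS.sens
    )
    assert cs.log_likelihood(counts, flipped) == pytest.approx(ll, abs=1e-12)


def test_log_likelihood_perfect_tests():
    counts = PatternCounts([0, 0, 0, 0, 0, 0, 0, 10])
    p = cs.LcaParams(0.5, [1, 1, 1], [1, 1, 1])
    assert cs.log_likelihood(counts, p) == pytest.approx(10 * np.log(0.5))
    # observed cell with probability zero -> -inf
    zeros = PatternCounts([10, 0, 0, 0, 0, 0, 0, 0])
    assert cs.log_likelihood(zeros, cs.LcaParams(1.0, [1, 1, 1], [1, 1, 1])) == -np.inf


@pytest.mark.parametrize(
    "a, b, lo, hi, expected",
    [
        (10.67, 1.06, 0.70, 1.00, 0.9751),
        (6.0, 7.6, 0.20, 0.70, 0.9499),
        (2.5, 3.5, 0.0, 1.0, 1.0),
    ],
)
def test_prior_coverage_values(a, b, lo, hi, expected):
    assert cs.prior_coverage(a, b, lo, hi) == pytest.approx(expected, abs=5e-5)


def test_prior_coverage_rejects_bad_range():
    with pytest.raises(ConfigError):
        cs.prior_coverage(2, 2, 0.8, 0.2)


def test_prior_only_run_recovers_prevalence_prior():
    """With no data the Gibbs chain samples the Beta(6, 7.6) prior for pi:
    mean 6/13.6 = 0.441."""
    counts = PatternCounts([0] * 8)
    draws = cs.gibbs_sample(
        counts, mcmc=McmcConfig(chains=2, iterations=6000, burn_in=500, thin=2), seed=3
    )
    pi = draws.draws["pi"].to_numpy()
    assert pi.mean() == pytest.approx(6 / 13.6, abs=0.01)


def test_retained_draw_count_matches_schedule():
    counts = PatternCounts([5, 0, 0, 0, 0, 0, 0, 5])
    mcmc = McmcConfig(chains=2, iterations=1000, burn_in=200, thin=4)
    draws = cs.gibbs_sample(counts, mcmc=mcmc, seed=0)
    assert len(draws.draws) == 2 * (1000 - 200) // 4
    # every draw satisfies the parameter constraints
    d = draws.draws
    for j in (1, 2, 3):
        assert ((d[f"sens_{j}"] + d[f"spec_{j}"]) > 1).all()


def test_gibbs_is_deterministic_given_seed():
    counts = PatternCounts([50, 5, 8, 10, 7, 9, 20, 60])
    mcmc = McmcConfig(chains=2, iterations=800, burn_in=100, thin=2)
    a = cs.gibbs_sample(counts, mcmc=mcmc, seed=42).draws
    b = cs.gibbs_sample(counts, mcmc=mcmc, seed=42).draws
    pd.testing.assert_frame_equal(a, b)


def test_pattern_posterior_hand_arithmetic():
    """For a single draw at the hand-checked parameters,
    P(screening | 111) = 0.22176 / 0.22512 = 0.98508."""
    row = {
        "chain": 0, "pi": 0.44,
        "sens_1": 0.9, "sens_2": 0.8, "sens_3": 0.7,
        "spec_1": 0.9, "spec_2": 0.7, "spec_3": 0.8,
    }
    draws = cs.PosteriorDraws(pd.DataFrame([row]), n_tests=3)
    pp = cs.pattern_posterior(draws)
    assert pp.prob_of((1, 1, 1)) == pytest.approx(0.98508, abs=1e-5)
    assert pp.label_of((1, 1, 1)) == 1


def test_pattern_posterior_tie_counts_as_screening():
    # pi = 0.5 and a completely uninformative test battery -> posterior 0.5
    row = {
        "chain": 0, "pi": 0.5,
        "sens_1": 0.5, "sens_2": 0.5, "sens_3": 0.5,
        "spec_1": 0.5, "spec_2": 0.5, "spec_3": 0.5,
    }
    draws = cs.PosteriorDraws(pd.DataFrame([row]), n_tests=3)
    pp = cs.pattern_posterior(draws)
    assert pp.prob_of((0, 1, 0)) == pytest.approx(0.5)
    assert pp.label_of((0, 1, 0)) == 1


def test_latent_reference_label_consistency(study_cohort):
    """Patients sharing an indicator pattern always share a label, and the
    screening fraction lands near the generator's prevalence."""
    _, ind, _ = study_cohort
    counts = cs.pattern_counts(ind)
    draws = cs.gibbs_sample(
        counts, mcmc=McmcConfig(chains=2, iterations=4000, burn_in=1000, thin=5), seed=8
    )
    labels = cs.latent_reference(ind, draws)
    merged = ind.merge(labels, on="patient_id")
    grouped = merged.groupby(["endoscopist", "patient_1", "patient_2"])["label"].nunique()
    assert (grouped == 1).all()
    assert labels["label"].mean() == pytest.approx(0.46, abs=0.06)


def test_dependence_and_independence_agree_with_small_covariance():
    """Echo of the study's robustness check: with mild within-class
    dependence, the two models label patterns virtually identically."""
    # cov 0.01 on these margins is a within-class correlation of ~0.06
    cfg = cs.SyntheticConfig(n_patients=1230, dep_cov_pos=0.01, dep_cov_neg=0.01, seed=17)
    _, ind, _ = cs.generate_cohort(cfg)
    counts = cs.pattern_counts(ind)
    mcmc = McmcConfig(chains=2, iterations=3000, burn_in=1000, thin=4)
    ind_draws = cs.gibbs_sample(counts, mcmc=mcmc, dependence=False, seed=5)
    dep_draws = cs.gibbs_sample(counts, mcmc=mcmc, dependence=True, seed=5)
    lab_i = cs.latent_reference(ind, ind_draws)
    lab_d = cs.latent_reference(ind, dep_draws)
    agree = (lab_i["label"].to_numpy() == lab_d["label"].to_numpy()).mean()
    assert agree > 0.95
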