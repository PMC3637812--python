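"""Confusion metrics, Wald/Wilson intervals and Cohen's kappa."""

import numpy as np
import pandas as pd
import pytest

import coloscreen as cs
from coloscreen.evaluation import ConfusionTable


def test_confusion_trivial_cases():
    ref = [1] * 10 + [0] * 5
    ct = cs.confusion(ref, ref)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (10, 0, 0, 5)
    flipped = [1 - v for v in ref]
    ct2 = cs.confusion(flipped, ref)
    assert ct2.tp == 0 and ct2.tn == 0


def test_confusion_random_fixture_matches_hand_count(rng):
    pred = rng.integers(0, 2, 50)
    ref = rng.integers(0, 2, 50)
    ct = cs.confusion(pred, ref)
    assert ct.tp == int(np.sum((pred == 1) & (ref == 1)))
    assert ct.fp == int(np.sum((pred == 1) & (ref == 0)))
    assert ct.fn == int(np.sum((pred == 0) & (ref == 1)))
    assert ct.tn == int(np.sum((pred == 0) & (ref == 0)))
    assert ct.n == 50


def test_confusion_joins_on_patient_id():
    pred = pd.DataFrame({"patient_id": ["b", "a"], "label": [1, 0]})
    ref = pd.DataFrame({"patient_id": ["a", "b"], "label": [0, 0]})
    ct = cs.confusion(pred, ref)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (0, 1, 0, 1)
    with pytest.raises(cs.InputError):
        cs.confusion(pred, pd.DataFrame({"patient_id": ["a", "c"], "label": [0, 0]}))


def test_accuracy_report_reproduces_published_row():
    """Counts back-derived from the published tree-vs-latent row (554 latent
    positives): sensitivity 84.5 (81.5-87.5), PPV 65.4."""
    rep = cs.accuracy_report(ConfusionTable(tp=468, fp=248, fn=86, tn=428))
    assert rep.sensitivity.value == pytest.approx(84.5, abs=0.05)
    assert rep.sensitivity.ci_low == pytest.approx(81.5, abs=0.05)
    assert rep.sensitivity.ci_high == pytest.approx(87.5, abs=0.05)
    assert rep.ppv.value == pytest.approx(65.4, abs=0.05)
    assert rep.specificity.value == pytest.approx(63.3, abs=0.05)
    assert rep.npv.value == pytest.approx(83.3, abs=0.05)


def test_accuracy_report_perfect_and_undefined():
    rep = cs.accuracy_report(ConfusionTable(1, 0, 0, 1))
    for m in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
        assert m.value == 100.0
    # no predicted positives -> PPV undefined, not zero
    rep2 = cs.accuracy_report(ConfusionTable(0, 0, 3, 7))
    assert rep2.ppv.value is None
    assert rep2.npv.value == pytest.approx(70.0)


def test_ci_width_shrinks_with_square_root_of_n():
    small = cs.accuracy_report(ConfusionTable(30, 20, 10, 40))
    big = cs.accuracy_report(ConfusionTable(3000, 2000, 1000, 4000))
    w_small = small.sensitivity.ci_high - small.sensitivity.ci_low
    w_big = big.sensitivity.ci_high - big.sensitivity.ci_low
    assert w_big == pytest.approx(w_small / 10, rel=1e-6)


def test_swapping_pred_and_ref_swaps_metric_pairs(rng):
    pred = rng.integers(0, 2, 200)
    ref = rng.integers(0, 2, 200)
    fwd = cs.accuracy_report(cs.confusion(pred, ref))
    rev = cs.accuracy_report(cs.confusion(ref, pred))
    assert fwd.sensitivity.value == pytest.approx(rev.ppv.value)
    assert fwd.specificity.value == pytest.approx(rev.npv.value)


def test_wilson_interval_available():
    rep = cs.accuracy_report(ConfusionTable(9, 0, 1, 0), method="wilson")
    assert rep.sensitivity.ci_low > 0  # Wilson never collapses to the Wald bound
    assert rep.sensitivity.ci_high <= 100


def test_kappa_perfect_agreement():
    labels = [0, 1] * 10
    k = cs.cohens_kappa(labels, labels)
    assert k.kappa == pytest.approx(1.0)


def test_kappa_hand_arithmetic():
    """2x2 agreement (470, 106, 84, 570) on n = 1,230: Po = 0.8455,
    Pe = 0.5031, kappa = 0.689."""
    a = [1] * 470 + [1] * 106 + [0] * 84 + [0] * 570
    b = [1] * 470 + [0] * 106 + [1] * 84 + [0] * 570
    k = cs.cohens_kappa(a, b)
    assert k.observed_agreement == pytest.approx(1040 / 1230, abs=1e-12)
    assert k.expected_agreement == pytest.approx(0.50315, abs=1e-4)
    assert k.kappa == pytest.approx(0.6891, abs=1e-3)
    assert k.ci_low < k.kappa < k.ci_high


def test_kappa_matches_sklearn(rng):
    from sklearn.metrics import cohen_kappa_score

    a = rng.integers(0, 2, 500)
    b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 2, 500))
    k = cs.cohens_kappa(a, b)
    assert k.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_kappa_near_zero_for_independent_labels(rng):
    a = rng.integers(0, 2, 10_000)
    b = rng.integers(0, 2, 10_000)
    assert abs(cs.cohens_kappa(a, b).kappa) < 0.05


def test_kappa_undefined_when_both_raters_constant():
    with pytest.raises(cs.InputError):
        cs.cohens_kappa([1, 1, 1], [1, 1, 1])
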