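"""Logistic regression, BIC subset selection, ROC/AUC and the Gini tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coloscreen as cs
from coloscreen.classifiers import TreeConfig


def _frame(**cols):
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# logistic regression


def test_intercept_only_closed_form():
    y = np.array([1] * 30 + [0] * 70)
    feats = _frame(dummy=np.zeros(100))
    m = cs.fit_logistic(feats, y, [])
    ybar = 0.3
    assert m.coefficients["intercept"] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)
    expected_ll = 100 * (ybar * np.log(ybar) + 0.7 * np.log(0.7))
    assert m.log_likelihood == pytest.approx(expected_ll, abs=1e-8)
    assert m.bic == pytest.approx(np.log(100) - 2 * expected_ll, abs=1e-8)


def test_single_binary_predictor_equals_two_by_two_log_odds_ratio():
    # cells: a=exposed cases, b=exposed non-cases, c=unexposed cases, d=unexposed
    a, b, c, d = 40, 25, 15, 60
    x = np.array([1] * (a + b) + [0] * (c + d))
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    m = cs.fit_logistic(_frame(x=x), y, ["x"])
    assert m.coefficients["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)
    assert m.coefficients["intercept"] == pytest.approx(np.log(c / d), abs=1e-8)


def test_irls_matches_statsmodels_on_multivariable_fit(study_features, study_cohort):
    import statsmodels.api as sm

    truth, _, _ = study_cohort
    y = truth["latent_indication"].to_numpy()
    variables = ["age", "colonoscopy", "rectal_bleeding", "ibd", "colorectal_polyps"]
    m = cs.fit_logistic(study_features, y, variables)
    X = sm.add_constant(study_features[variables].astype(float))
    ref = sm.Logit(y, X).fit(disp=0)
    assert m.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
    for v in variables:
        assert m.coefficients[v] == pytest.approx(ref.params[v], abs=1e-6)


def test_complete_separation_is_flagged_and_capped():
    y = np.array([0] * 20 + [1] * 20)
    m = cs.fit_logistic(_frame(x=y.astype(float)), y, ["x"])
    assert not m.converged
    assert abs(m.coefficients["x"]) <= 60  # capped, finite


def test_bic_identity_recomputes_from_parts(study_features, study_cohort):
    truth, _, _ = study_cohort
    y = truth["latent_indication"].to_numpy()
    m = cs.fit_logistic(study_features, y, ["colonoscopy", "anemia"])
    k = 3
    assert m.bic == pytest.approx(k * np.log(m.n) - 2 * m.log_likelihood, rel=1e-12)


# ---------------------------------------------------------------------------
# best subset / BIC


def test_single_strong_candidate_beats_intercept_by_delta_bic(rng):
    n = 2000
    x = rng.integers(0, 2, n)
    p = np.where(x == 1, 0.8, 0.2)
    y = (rng.random(n) < p).astype(int)
    feats = _frame(x=x)
    best = cs.best_subset_by_bic(feats, y, ["x"])
    null = cs.fit_logistic(feats, y, [])
    alt = cs.fit_logistic(feats, y, ["x"])
    assert alt.bic < null.bic
    assert best.variables == ["x"]
    assert best.bic == pytest.approx(alt.bic)


def test_null_outcome_selects_intercept_only(rng):
    n = 5000
    feats = _frame(**{f"x{j}": rng.integers(0, 2, n) for j in range(6)})
    y = rng.integers(0, 2, n)
    best = cs.best_subset_by_bic(feats, y, list(feats.columns))
    assert best.variables == []


def test_predict_prob_trivia():
    feats = _frame(x=np.array([0, 1, 0, 1]))
    m = cs.LogisticModel(
        variables=["x"], coefficients={"intercept": 0.0, "x": 0.0},
        log_likelihood=0.0, n=4, bic=0.0,
    )
    assert np.allclose(cs.predict_prob(m, feats), 0.5)
    m2 = cs.LogisticModel(
        variables=[], coefficients={"intercept": np.log(3.0)},
        log_likelihood=0.0, n=4, bic=0.0,
    )
    assert np.allclose(cs.predict_prob(m2, feats), 0.75)
    m3 = cs.LogisticModel(
        variables=["x"], coefficients={"intercept": 0.4, "x": -1.2},
        log_likelihood=0.0, n=4, bic=0.0,
    )
    p = cs.predict_prob(m3, feats)
    assert (p[feats["x"] == 1] < p[feats["x"] == 0]).all()


def test_predict_prob_missing_variable_errors():
    m = cs.LogisticModel(
        variables=["ghost"], coefficients={"intercept": 0.0, "ghost": 1.0},
        log_likelihood=0.0, n=1, bic=0.0,
    )
    with pytest.raises(cs.InputError, match="ghost"):
        cs.predict_prob(m, _frame(x=np.array([1.0])))


# ---------------------------------------------------------------------------
# AUC


def _auc_brute_force(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example():
    r = cs.auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
    assert r.auc == pytest.approx(0.75)


def test_auc_degenerate_scores():
    assert cs.auc([0.3] * 10, [1, 0] * 5).auc == pytest.approx(0.5)
    assert cs.auc([1, 1, 0, 0], [1, 1, 0, 0]).auc == pytest.approx(1.0)
    with pytest.raises(cs.InputError):
        cs.auc([0.3, 0.4], [1, 1])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_auc_equals_brute_force_pair_concordance(data):
    n = data.draw(st.integers(4, 60))
    scores = data.draw(
        st.lists(st.sampled_from([0.1, 0.2, 0.2, 0.5, 0.7, 0.9]), min_size=n, max_size=n)
    )
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if 0 < sum(labels) < n:
        r = cs.auc(scores, labels)
        assert r.auc == pytest.approx(_auc_brute_force(scores, labels), abs=1e-12)
        assert r.ci_low <= r.auc <= r.ci_high


def test_auc_matches_sklearn(study_features, study_cohort):
    from sklearn.metrics import roc_auc_score

    truth, _, _ = study_cohort
    y = truth["latent_indication"].to_numpy()
    m = cs.fit_logistic(study_features, y, ["colonoscopy", "anemia", "ibd"])
    scores = cs.predict_prob(m, study_features)
    assert cs.auc(scores, y).auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# recursive partitioning


def test_outcome_equal_to_flag_gives_single_pure_split():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 200)
    feats = _frame(a=x, b=rng.integers(0, 2, 200))
    tree = cs.fit_tree(feats, x, ["a", "b"])
    assert tree.split == "a"
    assert tree.left.is_leaf and tree.right.is_leaf
    assert tree.left.label == 0 and tree.right.label == 1
    pred = cs.tree_classify(tree, feats)
    assert (pred == x).all()


def test_constant_outcome_gives_single_leaf():
    feats = _frame(a=np.array([0, 1, 0, 1] * 10))
    tree = cs.fit_tree(feats, np.ones(40), ["a"])
    assert tree.is_leaf and tree.label == 1


def test_root_split_maximises_gini_decrease(study_features, study_cohort):
    """The root split equals the arg-max of a brute-force Gini search."""
    truth, _, _ = study_cohort
    y = truth["latent_indication"].to_numpy()
    flags = [c for c in study_features.columns if c not in ("patient_id", "age", "sex")]
    tree = cs.fit_tree(study_features, y, flags)

    def gini(y_):
        if len(y_) == 0:
            return 0.0
        p = y_.mean()
        return 1 - p**2 - (1 - p) ** 2

    gains = {}
    for v in flags:
        mask = study_features[v].to_numpy() == 1
        if mask.all() or (~mask).any() == 0:
            continue
        gains[v] = gini(y) - (
            mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])
        ) / len(y)
    assert tree.split == max(gains, key=gains.get) == "colonoscopy"


def test_deeper_trees_never_increase_training_error(study_features, study_cohort):
    truth, _, _ = study_cohort
    y = truth["latent_indication"].to_numpy()
    flags = [c for c in study_features.columns if c not in ("patient_id", "age", "sex")]
    errs = []
    for depth in (1, 2, 4, 8, None):
        tree = cs.fit_tree(study_features, y, flags, TreeConfig(max_depth=depth))
        errs.append((cs.tree_classify(tree, study_features) != y).mean())
    assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


def test_leaf_tie_labels_screening():
    feats = _frame(a=np.array([0, 0, 1, 1]))
    tree = cs.fit_tree(feats, np.array([0, 1, 0, 1]), ["a"], TreeConfig(min_node_size=1))
    # no split improves Gini; 2-2 tie at the root -> screening leaf
    assert tree.is_leaf and tree.label == 1


def test_routing_ignores_variables_off_the_path():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 300)
    feats = _frame(a=x, b=rng.integers(0, 2, 300))
    tree = cs.fit_tree(feats, x, ["a", "b"])
    flipped = feats.assign(b=1 - feats["b"])
    assert (cs.tree_classify(tree, feats) == cs.tree_classify(tree, flipped)).all()


def test_pruning_collapses_noise_splits():
    rng = np.random.default_rng(4)
    n = 600
    signal = rng.integers(0, 2, n)
    noise = {f"n{j}": rng.integers(0, 2, n) for j in range(5)}
    y = np.where(rng.random(n) < 0.85, signal, 1 - signal)
    feats = _frame(signal=signal, **noise)
    grown = cs.fit_tree(feats, y, list(feats.columns), TreeConfig(min_node_size=5))
    pruned = cs.fit_tree(
        feats, y, list(feats.columns), TreeConfig(min_node_size=5, prune=True)
    )
    assert pruned.leaves() <= grown.leaves()
    assert pruned.split == "signal"


def test_tree_cross_checks_sklearn_on_pure_fixture():
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(2)
    a = rng.integers(0, 2, 400)
    b = rng.integers(0, 2, 400)
    y = a & b
    feats = _frame(a=a, b=b)
    tree = cs.fit_tree(feats, y, ["a", "b"], TreeConfig(min_node_size=2))
    sk = DecisionTreeClassifier(criterion="gini", random_state=0).fit(feats, y)
    assert (cs.tree_classify(tree, feats) == sk.predict(feats)).all()
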