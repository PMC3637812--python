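"""Model-based indication classifiers.

Two families, both trained against a binary reference label (the latent class
reference standard or the endoscopist indication):

* multivariate logistic regression fit by Newton/IRLS, with exhaustive
  best-subset selection under BIC (k*ln(n) - 2*loglik, intercept always
  included) and discrimination summarised by the ROC AUC with a DeLong
  95% confidence interval;
* a recursive-partitioning classification tree on the binary claims flags,
  grown greedily by Gini impurity decrease, with optional cost-complexity
  pruning selected by cross-validation.

Determinism rules: subsets are enumerated by size then lexicographic
candidate order with strict-improvement updates (ties keep the smaller,
earlier subset); tree splits break ties by fixed variable order; leaf
majority ties label screening.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import InputError

logger = logging.getLogger(__name__)

_COEF_CAP = 30.0  # |log-odds| beyond this is treated as separation


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticModel:
    variables: list
    coefficients: dict        # name -> log-odds coefficient, incl. "intercept"
    log_likelihood: float
    n: int
    bic: float
    converged: bool = True

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in features.columns]
        if missing:
            raise InputError(f"features missing model variables: {missing}")
        eta = np.full(len(features), self.coefficients["intercept"], dtype=float)
        for v in self.variables:
            eta += self.coefficients[v] * features[v].to_numpy(dtype=float)
        return eta


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100,
          beta0: np.ndarray | None = None):
    """Newton-Raphson (IRLS) maximum likelihood for logistic regression.

    Returns (beta, loglik, converged).  Separation is detected as runaway
    coefficients; they are capped at +/-30 and the fit flagged.
    """
    n, p = X.shape
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.zeros(p)
        # intercept warm start
        ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
        beta[0] = np.log(ybar / (1 - ybar))

    def loglik(b):
        eta = X @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = (X * np.maximum(w, 1e-12)[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(25):
            cand = beta + t * step
            llc = loglik(cand)
            if llc >= ll - 1e-12:
                beta, ll = cand, llc
                break
            t /= 2
        else:
            break
        if np.max(np.abs(beta)) > _COEF_CAP:
            break
    if np.max(np.abs(beta)) > _COEF_CAP or not np.all(np.isfinite(beta)):
        beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
        ll = loglik(beta)
        converged = False
    return beta, ll, converged


def _design(features: pd.DataFrame, variables) -> np.ndarray:
    cols = [np.ones(len(features))]
    for v in variables:
        if v not in features.columns:
            raise InputError(f"unknown model variable: {v}")
        col = features[v]
        if col.dtype == object:
            # sex coded M/F -> 1/0 (male = 1)
            col = col.map({"M": 1, "F": 0, 1: 1, 0: 0})
            if col.isna().any():
                raise InputError(f"variable {v!r} has non-numeric values")
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _check_outcome(outcome) -> np.ndarray:
    y = np.asarray(outcome, dtype=float)
    if np.any(np.isnan(y)) or not np.all(np.isin(y, [0.0, 1.0])):
        raise InputError("outcome must be binary 0/1 with no missing values")
    return y


def fit_logistic(
    features: pd.DataFrame, outcome, variables=None
) -> LogisticModel:
    """Maximum-likelihood logistic fit of the outcome on the named variables
    (``variables=[]`` or None with no columns fits intercept-only)."""
    variables = list(variables or [])
    y = _check_outcome(outcome)
    if len(y) != len(features):
        raise InputError("features and outcome length mismatch")
    X = _design(features, variables)
    beta, ll, converged = _irls(X, y)
    k = X.shape[1]
    n = len(y)
    coef = {"intercept": float(beta[0])}
    coef.update({v: float(b) for v, b in zip(variables, beta[1:])})
    return LogisticModel(
        variables=variables,
        coefficients=coef,
        log_likelihood=ll,
        n=n,
        bic=float(k * np.log(n) - 2.0 * ll),
        converged=converged,
    )


def predict_prob(model: LogisticModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted screening probability: inverse logit of the linear predictor."""
    feats = features.copy()
    if "sex" in model.variables and features["sex"].dtype == object:
        feats["sex"] = features["sex"].map({"M": 1, "F": 0})
    eta = model.linear_predictor(feats)
    return 1.0 / (1.0 + np.exp(-eta))


def best_subset_by_bic(
    features: pd.DataFrame, outcome, candidates
) -> LogisticModel:
    """Exhaustive best-subset logistic regression under BIC.

    All 2^p subsets of ``candidates`` are fitted (intercept always included)
    and the minimum-BIC model returned.  Ties go to fewer variables, then to
    lexicographic position in the candidate order; subsets whose fit fails
    are skipped with a warning.
    """
    candidates = list(candidates)
    if len(candidates) > 20:
        raise InputError("exhaustive search limited to 20 candidates")
    y = _check_outcome(outcome)
    X_full = _design(features, candidates)  # column 0 = intercept
    n = len(y)
    log_n = np.log(n)
    best_bic, best_combo = np.inf, None
    prev_level: dict = {}
    for size in range(len(candidates) + 1):
        level: dict = {}
        for combo in itertools.combinations(range(1, len(candidates) + 1), size):
            cols = (0,) + combo
            # warm start from the parent subset's solution
            beta0 = None
            parent = prev_level.get(combo[:-1]) if combo else None
            if parent is not None:
                beta0 = np.append(parent, 0.0)
            try:
                beta, ll, _ = _irls(X_full[:, cols], y, beta0=beta0)
            except Exception as exc:  # noqa: BLE001 - contract: skip and log
                logger.warning("subset %s failed: %s",
                               [candidates[i - 1] for i in combo], exc)
                continue
            level[combo] = beta
            bic = (size + 1) * log_n - 2.0 * ll
            if bic < best_bic - 1e-9:
                best_bic, best_combo = bic, combo
        prev_level = level
    if best_combo is None:
        raise InputError("no candidate subset could be fitted")
    return fit_logistic(features, outcome, [candidates[i - 1] for i in best_combo])


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong confidence interval."""
    s = np.asarray(scores, dtype=float)
    y = _check_outcome(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise InputError("AUC needs both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc_hat = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components via midranks
    v10 = (ranks[:m] - stats.rankdata(pos)) / n          # per-positive placement
    v01 = 1.0 - (ranks[m:] - stats.rankdata(neg)) / m    # per-negative placement
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    lo = float(np.clip(auc_hat - z * se, 0.0, 1.0))
    hi = float(np.clip(auc_hat + z * se, 0.0, 1.0))
    return RocResult(float(auc_hat), lo, hi, m, n)


# ---------------------------------------------------------------------------
# recursive partitioning


@dataclass
class TreeConfig:
    min_node_size: int = 20    # smallest node still considered for splitting
    min_gini_decrease: float = 0.0
    prune: bool = False
    cv_folds: int = 5
    max_depth: int | None = None


@dataclass
class TreeNode:
    """Either an internal node (``split`` set, two children) or a leaf
    (``label`` set, with training counts)."""

    n: int
    counts: tuple                 # (n_non_screening, n_screening) at the node
    split: str | None = None
    left: "TreeNode | None" = None   # flag == 0 branch
    right: "TreeNode | None" = None  # flag == 1 branch
    label: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def variables_used(self) -> list:
        if self.is_leaf:
            return []
        seen, order = set(), []
        for v in [self.split] + self.left.variables_used() + self.right.variables_used():
            if v not in seen:
                seen.add(v)
                order.append(v)
        return order

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "label": int(self.label), "n": self.n,
                    "counts": list(self.counts)}
        return {
            "leaf": False,
            "split": self.split,
            "n": self.n,
            "counts": list(self.counts),
            "flag_0": self.left.to_dict(),
            "flag_1": self.right.to_dict(),
        }


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p**2))


def _leaf(y: np.ndarray) -> TreeNode:
    c0 = int(np.sum(y == 0))
    c1 = int(np.sum(y == 1))
    return TreeNode(n=len(y), counts=(c0, c1), label=int(c1 >= c0))  # tie -> screening


def _grow(X: np.ndarray, y: np.ndarray, names, available, cfg: TreeConfig, depth: int) -> TreeNode:
    node_counts = np.array([np.sum(y == 0), np.sum(y == 1)])
    if (
        len(y) < cfg.min_node_size
        or node_counts.min() == 0
        or not available
        or (cfg.max_depth is not None and depth >= cfg.max_depth)
    ):
        return _leaf(y)
    parent_imp = _gini(node_counts)
    best_gain, best_j = 0.0, None
    for j in available:
        mask = X[:, j] == 1
        nr = mask.sum()
        nl = len(y) - nr
        if nr == 0 or nl == 0:
            continue
        cr = np.array([np.sum(y[mask] == 0), np.sum(y[mask] == 1)])
        cl = node_counts - cr
        child_imp = (nl * _gini(cl) + nr * _gini(cr)) / len(y)
        gain = parent_imp - child_imp
        if gain > best_gain + 1e-12:  # ties keep earliest variable order
            best_gain, best_j = gain, j
    if best_j is None or best_gain <= cfg.min_gini_decrease:
        return _leaf(y)
    mask = X[:, best_j] == 1
    remaining = [j for j in available if j != best_j]
    node = TreeNode(n=len(y), counts=(int(node_counts[0]), int(node_counts[1])))
    node.split = names[best_j]
    node.left = _grow(X[~mask], y[~mask], names, remaining, cfg, depth + 1)
    node.right = _grow(X[mask], y[mask], names, remaining, cfg, depth + 1)
    return node


def fit_tree(
    features: pd.DataFrame, outcome, variables=None, config: TreeConfig | None = None
) -> TreeNode:
    """Grow a Gini classification tree on binary claims flags.

    Splits greedily on the flag with the largest impurity decrease, never
    re-splitting a variable on the same path; stops on purity, node size
    below ``min_node_size`` or no positive decrease.  With ``config.prune``
    the tree is cost-complexity pruned at the CV-chosen alpha.
    """
    cfg = config or TreeConfig()
    y = _check_outcome(outcome)
    if len(y) == 0:
        raise InputError("empty training data")
    if variables is None:
        variables = [
            c for c in features.columns
            if c not in ("patient_id", "age", "sex")
        ]
    X = features[list(variables)].to_numpy(dtype=float)
    if not np.all(np.isin(X, [0.0, 1.0])):
        raise InputError("tree predictors must be binary flags")
    X = X.astype(int)
    tree = _grow(X, y.astype(int), list(variables), list(range(len(variables))), cfg, 0)
    if cfg.prune:
        tree = _cv_prune(X, y.astype(int), list(variables), cfg, tree)
    return tree


def tree_classify(tree: TreeNode, features: pd.DataFrame) -> np.ndarray:
    """Route each patient down the tree; returns 0/1 labels."""
    needed = tree.variables_used()
    missing = [v for v in needed if v not in features.columns]
    if missing:
        raise InputError(f"features missing split variables: {missing}")
    out = np.empty(len(features), dtype=int)
    cols = {v: features[v].to_numpy(dtype=int) for v in needed}
    for i in range(len(features)):
        node = tree
        while not node.is_leaf:
            node = node.right if cols[node.split][i] == 1 else node.left
        out[i] = node.label
    return out


# --- cost-complexity pruning -----------------------------------------------


def _misclass(node: TreeNode) -> int:
    """Training misclassifications of the subtree."""
    if node.is_leaf:
        return node.counts[0] if node.label == 1 else node.counts[1]
    return _misclass(node.left) + _misclass(node.right)


def _node_misclass(node: TreeNode) -> int:
    return min(node.counts)


def _weakest_alpha(node: TreeNode) -> tuple:
    """Smallest g(t) = (R(t) - R(T_t)) / (leaves - 1) over internal nodes."""
    best = (np.inf, None)
    if node.is_leaf:
        return best
    g = (_node_misclass(node) - _misclass(node)) / max(node.leaves() - 1, 1)
    best = (g, node)
    for child in (node.left, node.right):
        cg, cn = _weakest_alpha(child)
        if cg < best[0]:
            best = (cg, cn)
    return best


def _collapse(node: TreeNode) -> None:
    node.split = None
    node.left = node.right = None
    node.label = int(node.counts[1] >= node.counts[0])


def _prune_sequence(tree: TreeNode) -> list:
    """Weakest-link sequence [(alpha, tree_copy)] from full tree to root."""
    import copy

    seq = [(0.0, copy.deepcopy(tree))]
    work = copy.deepcopy(tree)
    while not work.is_leaf:
        g, node = _weakest_alpha(work)
        _collapse(node)
        seq.append((float(g), copy.deepcopy(work)))
    return seq


def _prune_at(tree: TreeNode, alpha: float) -> TreeNode:
    import copy

    work = copy.deepcopy(tree)
    while not work.is_leaf:
        g, node = _weakest_alpha(work)
        if g > alpha + 1e-12:
            break
        _collapse(node)
    return work


def _cv_prune(X: np.ndarray, y: np.ndarray, names, cfg: TreeConfig, tree: TreeNode) -> TreeNode:
    seq = _prune_sequence(tree)
    alphas = [a for a, _ in seq]
    # candidate alphas: geometric midpoints of successive thresholds
    cands = [0.0]
    for a1, a2 in zip(alphas[1:], alphas[2:]):
        cands.append(float(np.sqrt(max(a1, 1e-12) * max(a2, 1e-12))))
    if len(alphas) > 1:
        cands.append(alphas[-1] + 1.0)
    folds = np.arange(len(y)) % cfg.cv_folds  # deterministic fold assignment
    errors = np.zeros(len(cands))
    feats = pd.DataFrame(X, columns=names)
    for f in range(cfg.cv_folds):
        tr = folds != f
        if y[tr].min() == y[tr].max():
            continue
        sub = _grow(X[tr], y[tr], names, list(range(len(names))), cfg, 0)
        for ci, a in enumerate(cands):
            pruned = _prune_at(sub, a)
            pred = tree_classify(pruned, feats[~tr])
            errors[ci] += int(np.sum(pred != y[~tr]))
    best_alpha = cands[int(np.argmin(errors))]
    return _prune_at(tree, best_alpha)
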