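"""Bayesian latent class model for colonoscopy indication.

Two-class (screening vs non-screening) latent class analysis of three
imperfect binary indicators — the endoscopist's stated indication and two
patient questionnaire indications — in the absence of a gold standard.  Each
test j has sensitivity S_j = P(test j = screening | truly screening) and
specificity C_j = P(test j = non-screening | truly non-screening); the latent
prevalence of screening is pi.  Under conditional independence the probability
of observing pattern t = (t1, t2, t3) is

    P(t) = pi * prod_j S_j^{t_j} (1 - S_j)^{1 - t_j}
         + (1 - pi) * prod_j (1 - C_j)^{t_j} C_j^{1 - t_j}.

A robustness variant allows a within-class covariance between the two patient
indications: their joint within-class cell probability is the product of the
marginals plus (2*t2 - 1)(2*t3 - 1) * cov, with cov restricted to the range
keeping all four cells non-negative.

Inference is by data-augmentation Gibbs sampling: given parameters, each
pattern's count is split into latent screening/non-screening; given the
latent split, pi, S_j, C_j have conjugate beta full conditionals (truncated
to the identifiability region S_j + C_j > 1, which breaks the label-switching
symmetry (pi, S, C) -> (1 - pi, 1 - C, 1 - S)).  The dependence variant's
non-conjugate within-class parameters are sampled by griddy Gibbs
(inverse-CDF sampling on a fine grid).

The posterior probability that an exam with pattern t is a screening exam,

    P(D = 1 | t) = pi * P(t | D = 1) / P(t),

is summarised by its posterior median per pattern and dichotomised at 50%
(median >= 0.5 -> screening) to form the latent reference standard.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats

from .features import ConfigError, InputError

INDICATOR_COLUMNS = ["endoscopist", "patient_1", "patient_2"]


# ---------------------------------------------------------------------------
# parameters, priors, pattern counts


@dataclass(frozen=True)
class BetaPrior:
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigError(f"beta parameters must be positive, got ({self.a}, {self.b})")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class LcaPriors:
    """Beta priors for prevalence and each test's sensitivity/specificity."""

    prevalence: BetaPrior
    sens: tuple
    spec: tuple
    names: tuple = ()

    def __post_init__(self):
        if len(self.sens) != len(self.spec):
            raise ConfigError("sens and spec priors must have equal length")

    @property
    def n_tests(self) -> int:
        return len(self.sens)

    @classmethod
    def from_mapping(cls, raw: dict) -> "LcaPriors":
        prev = BetaPrior(**raw["prevalence"])
        sens, spec, names = [], [], []
        for t in raw["tests"]:
            sens.append(BetaPrior(**t["sens"]))
            spec.append(BetaPrior(**t["spec"]))
            names.append(t.get("name", f"test_{len(names) + 1}"))
        return cls(prev, tuple(sens), tuple(spec), tuple(names))

    @classmethod
    def from_yaml(cls, path) -> "LcaPriors":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "LcaPriors":
        """Study priors: informative Beta(10.67, 1.06) on the endoscopist
        test's sensitivity and specificity, flat Beta(1, 1) on the patient
        tests, Beta(6, 7.6) on prevalence."""
        ref = resources.files("coloscreen.data") / "priors.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


def _cov_range(p2: float, p3: float) -> tuple:
    """Valid covariance range for two Bernoulli margins p2, p3."""
    return (max(-p2 * p3, -(1 - p2) * (1 - p3)), min(p2 * (1 - p3), p3 * (1 - p2)))


@dataclass
class LcaParams:
    """One point in parameter space: prevalence, per-test accuracies and
    optional within-class covariances between tests 2 and 3."""

    prevalence: float
    sens: np.ndarray
    spec: np.ndarray
    cov_pos: float = 0.0
    cov_neg: float = 0.0

    def __post_init__(self):
        self.sens = np.asarray(self.sens, dtype=float)
        self.spec = np.asarray(self.spec, dtype=float)
        for name, val in [("prevalence", np.array([self.prevalence])),
                          ("sens", self.sens), ("spec", self.spec)]:
            if np.any(val < 0) or np.any(val > 1):
                raise ConfigError(f"{name} outside [0, 1]")
        if self.cov_pos or self.cov_neg:
            if len(self.sens) != 3:
                raise ConfigError("covariance terms require exactly 3 tests")
            lo, hi = _cov_range(self.sens[1], self.sens[2])
            if not lo <= self.cov_pos <= hi:
                raise ConfigError(f"cov_pos {self.cov_pos} outside [{lo}, {hi}]")
            lo, hi = _cov_range(self.spec[1], self.spec[2])
            if not lo <= self.cov_neg <= hi:
                raise ConfigError(f"cov_neg {self.cov_neg} outside [{lo}, {hi}]")

    @property
    def n_tests(self) -> int:
        return len(self.sens)


@dataclass
class PatternCounts:
    """Counts of the 2^J indicator patterns, in lexicographic pattern order
    (for J = 3: 000, 001, 010, 011, 100, 101, 110, 111)."""

    counts: np.ndarray
    n_tests: int = 3

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(-1)
        if len(self.counts) != 2 ** self.n_tests:
            raise InputError(
                f"expected {2 ** self.n_tests} pattern counts, got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise InputError("pattern counts must be non-negative")

    @property
    def patterns(self) -> np.ndarray:
        return np.array(list(itertools.product([0, 1], repeat=self.n_tests)))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict:
        return {
            "".join(map(str, p)): int(c) for p, c in zip(self.patterns, self.counts)
        }


def pattern_counts(indicators: pd.DataFrame) -> PatternCounts:
    """Tabulate the 8 indicator patterns from a per-patient indicator table."""
    cols = [c for c in INDICATOR_COLUMNS if c in indicators.columns]
    if len(cols) != 3:
        raise InputError(f"indicator table must contain columns {INDICATOR_COLUMNS}")
    vals = indicators[cols]
    if vals.isna().any().any():
        bad = indicators.loc[vals.isna().any(axis=1)]
        ids = list(bad.get("patient_id", bad.index)[:10])
        raise InputError(f"missing indicator values for patients: {ids}")
    arr = vals.to_numpy(dtype=int)
    if np.any((arr != 0) & (arr != 1)):
        raise InputError("indicators must be 0/1")
    idx = arr[:, 0] * 4 + arr[:, 1] * 2 + arr[:, 2]
    counts = np.bincount(idx, minlength=8)
    return PatternCounts(counts, n_tests=3)


# ---------------------------------------------------------------------------
# likelihood


def _class_pattern_probs(params: LcaParams) -> tuple:
    """P(pattern | class) for each latent class, over all 2^J patterns."""
    pats = np.array(list(itertools.product([0, 1], repeat=params.n_tests)))
    s, c = params.sens, params.spec
    p1 = np.prod(np.where(pats == 1, s, 1 - s), axis=1)
    p0 = np.prod(np.where(pats == 1, 1 - c, c), axis=1)
    if params.cov_pos or params.cov_neg:
        sign = (2 * pats[:, 1] - 1) * (2 * pats[:, 2] - 1)
        m2 = np.where(pats[:, 1] == 1, s[1], 1 - s[1])
        m3 = np.where(pats[:, 2] == 1, s[2], 1 - s[2])
        t1 = np.where(pats[:, 0] == 1, s[0], 1 - s[0])
        p1 = t1 * (m2 * m3 + sign * params.cov_pos)
        u2 = np.where(pats[:, 1] == 1, 1 - c[1], c[1])
        u3 = np.where(pats[:, 2] == 1, 1 - c[2], c[2])
        t0 = np.where(pats[:, 0] == 1, 1 - c[0], c[0])
        p0 = t0 * (u2 * u3 + sign * params.cov_neg)
    return p1, p0


def cell_probabilities(params: LcaParams) -> np.ndarray:
    """Marginal probability of every pattern; sums to 1."""
    p1, p0 = _class_pattern_probs(params)
    return params.prevalence * p1 + (1 - params.prevalence) * p0


def cell_probability(pattern, params: LcaParams) -> float:
    """Marginal probability of one indicator pattern under the mixture."""
    pats = list(itertools.product([0, 1], repeat=params.n_tests))
    idx = pats.index(tuple(int(t) for t in pattern))
    return float(cell_probabilities(params)[idx])


def log_likelihood(counts: PatternCounts, params: LcaParams) -> float:
    """Multinomial log likelihood of the pattern counts (constant dropped).

    Returns ``-inf`` if an observed cell has probability zero.
    """
    probs = cell_probabilities(params)
    obs = counts.counts > 0
    if np.any(probs[obs] <= 0):
        return float("-inf")
    return float(np.sum(counts.counts[obs] * np.log(probs[obs])))


def prior_coverage(a: float, b: float, lo: float, hi: float) -> float:
    """P(lo <= X <= hi) for X ~ Beta(a, b), via the regularized incomplete
    beta function."""
    if a <= 0 or b <= 0:
        raise ConfigError("beta parameters must be positive")
    if not (0 <= lo < hi <= 1):
        raise ConfigError(f"invalid interval [{lo}, {hi}]")
    return float(special.betainc(a, b, hi) - special.betainc(a, b, lo))


# ---------------------------------------------------------------------------
# Gibbs sampler


@dataclass
class McmcConfig:
    chains: int = 3
    iterations: int = 20000
    burn_in: int = 5000
    thin: int = 5
    grid_points: int = 201  # griddy-Gibbs resolution (dependence model only)
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ConfigError("burn_in must be < iterations")
        if self.thin < 1 or self.chains < 1:
            raise ConfigError("thin and chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def from_mapping(cls, raw: dict) -> "McmcConfig":
        return cls(**raw)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws (one row each) with chain metadata."""

    draws: pd.DataFrame  # columns: chain, pi, sens_j, spec_j[, cov_pos, cov_neg]
    n_tests: int
    meta: dict = field(default_factory=dict)

    @property
    def dependence(self) -> bool:
        return "cov_pos" in self.draws.columns

    def param_at(self, i: int) -> LcaParams:
        row = self.draws.iloc[i]
        return LcaParams(
            prevalence=row["pi"],
            sens=[row[f"sens_{j + 1}"] for j in range(self.n_tests)],
            spec=[row[f"spec_{j + 1}"] for j in range(self.n_tests)],
            cov_pos=row.get("cov_pos", 0.0),
            cov_neg=row.get("cov_neg", 0.0),
        )

    def summary(self) -> pd.DataFrame:
        cols = [c for c in self.draws.columns if c != "chain"]
        rows = []
        for c in cols:
            v = self.draws[c].to_numpy()
            rows.append(
                {
                    "parameter": c,
                    "median": float(np.median(v)),
                    "mean": float(np.mean(v)),
                    "ci_2.5": float(np.quantile(v, 0.025)),
                    "ci_97.5": float(np.quantile(v, 0.975)),
                }
            )
        return pd.DataFrame(rows)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin) for one
    scalar parameter; ``chains`` has shape (n_chains, n_draws)."""
    half = chains.shape[1] // 2
    if half < 2:
        return float("nan")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    b = n * means.var(ddof=1)
    w = split.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _trunc_beta(rng: np.random.Generator, a: float, b: float, lo: float) -> float:
    """Draw X ~ Beta(a, b) conditional on X > lo, by inverse CDF."""
    flo = special.betainc(a, b, max(lo, 0.0))
    if flo >= 1.0 - 1e-14:
        return max(lo, 0.0) + 1e-12
    u = rng.uniform(flo, 1.0)
    return float(special.betaincinv(a, b, u))


def _grid_sample(
    rng: np.random.Generator,
    grid: np.ndarray,
    logdens: np.ndarray,
    lo: float | None = None,
    hi: float | None = None,
) -> float:
    """Categorical draw from an unnormalized log density tabulated on a grid,
    jittered uniformly within the grid cell to avoid a lattice posterior."""
    finite = np.isfinite(logdens)
    if not finite.any():
        raise ConfigError("griddy Gibbs: zero density everywhere on the grid")
    w = np.zeros_like(logdens)
    w[finite] = np.exp(logdens[finite] - logdens[finite].max())
    idx = rng.choice(len(grid), p=w / w.sum())
    step = grid[1] - grid[0] if len(grid) > 1 else 0.0
    x = grid[idx] + rng.uniform(-0.5, 0.5) * step
    valid = grid[finite]
    lo = valid.min() if lo is None else lo
    hi = valid.max() if hi is None else hi
    return float(np.clip(x, lo, hi))


def _dep_cell_loglik(n_ab: np.ndarray, p2, p3, cov) -> np.ndarray:
    """Log multinomial likelihood of the 2x2 (t2, t3) within-class cell
    counts under margins (p2, p3) and covariance ``cov``.

    Any of ``p2``, ``p3``, ``cov`` may be a grid (1-D array); the result is
    broadcast accordingly, with ``-inf`` wherever a cell probability would be
    negative (which also enforces the valid covariance range).
    """
    p2, p3, cov = np.broadcast_arrays(
        np.asarray(p2, float), np.asarray(p3, float), np.asarray(cov, float)
    )
    ll = np.zeros(p2.shape)
    for a in (0, 1):
        for b in (0, 1):
            m2 = p2 if a else 1 - p2
            m3 = p3 if b else 1 - p3
            q = m2 * m3 + (2 * a - 1) * (2 * b - 1) * cov
            bad = q < -1e-12
            qc = np.clip(q, 1e-300, None)
            if n_ab[a, b] > 0:
                term = np.where(q > 0, n_ab[a, b] * np.log(qc), -np.inf)
            else:
                term = np.where(bad, -np.inf, 0.0)
            ll = ll + term
    return ll


def _run_chain_independence(
    rng, counts: PatternCounts, priors: LcaPriors, mcmc: McmcConfig
) -> np.ndarray:
    J = counts.n_tests
    pats = counts.patterns
    n_k = counts.counts
    # init: jittered prior-ish values inside the identifiability region
    pi = float(np.clip(priors.prevalence.mean + rng.normal(0, 0.05), 0.05, 0.95))
    s = np.clip(0.8 + rng.normal(0, 0.05, size=J), 0.55, 0.99)
    c = np.clip(0.8 + rng.normal(0, 0.05, size=J), 0.55, 0.99)
    out = np.empty((mcmc.retained_per_chain, 1 + 2 * J))
    kept = 0
    for it in range(mcmc.iterations):
        p1 = np.prod(np.where(pats == 1, s, 1 - s), axis=1)
        p0 = np.prod(np.where(pats == 1, 1 - c, c), axis=1)
        num = pi * p1
        den = num + (1 - pi) * p0
        prob = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        y = rng.binomial(n_k, prob)  # latent screening count per pattern
        n1, n0 = y.sum(), (n_k - y).sum()
        pi = float(
            rng.beta(priors.prevalence.a + n1, priors.prevalence.b + n0)
        )
        pos1 = (pats * y[:, None]).sum(axis=0)       # class-1 patients with t_j = 1
        neg0 = ((1 - pats) * (n_k - y)[:, None]).sum(axis=0)  # class-0 with t_j = 0
        pos0 = ((n_k - y).sum() - neg0)              # class-0 with t_j = 1
        neg1 = y.sum() - pos1                        # class-1 with t_j = 0
        for j in range(J):
            s[j] = _trunc_beta(
                rng, priors.sens[j].a + pos1[j], priors.sens[j].b + neg1[j], 1 - c[j]
            )
            c[j] = _trunc_beta(
                rng, priors.spec[j].a + neg0[j], priors.spec[j].b + pos0[j], 1 - s[j]
            )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            if kept < out.shape[0]:
                out[kept] = np.concatenate([[pi], s, c])
                kept += 1
    return out[:kept]


def _run_chain_dependence(
    rng, counts: PatternCounts, priors: LcaPriors, mcmc: McmcConfig
) -> np.ndarray:
    if counts.n_tests != 3:
        raise ConfigError("dependence model requires exactly 3 tests")
    pats = counts.patterns
    n_k = counts.counts
    grid = np.linspace(1e-4, 1 - 1e-4, mcmc.grid_points)
    pi = float(np.clip(priors.prevalence.mean + rng.normal(0, 0.05), 0.05, 0.95))
    s = np.clip(0.8 + rng.normal(0, 0.05, size=3), 0.55, 0.99)
    c = np.clip(0.8 + rng.normal(0, 0.05, size=3), 0.55, 0.99)
    cov_p, cov_n = 0.0, 0.0
    out = np.empty((mcmc.retained_per_chain, 9))
    kept = 0
    sign = (2 * pats[:, 1] - 1) * (2 * pats[:, 2] - 1)
    for it in range(mcmc.iterations):
        params = LcaParams(pi, s.copy(), c.copy(), cov_p, cov_n)
        p1, p0 = _class_pattern_probs(params)
        num = pi * p1
        den = num + (1 - pi) * p0
        prob = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        y = rng.binomial(n_k, prob)
        pi = float(rng.beta(priors.prevalence.a + y.sum(),
                            priors.prevalence.b + (n_k - y).sum()))
        # test 1 stays conditionally independent -> conjugate
        pos1 = (pats[:, 0] * y).sum()
        neg1 = y.sum() - pos1
        pos0 = (pats[:, 0] * (n_k - y)).sum()
        neg0 = (n_k - y).sum() - pos0
        s[0] = _trunc_beta(rng, priors.sens[0].a + pos1, priors.sens[0].b + neg1, 1 - c[0])
        c[0] = _trunc_beta(rng, priors.spec[0].a + neg0, priors.spec[0].b + pos0, 1 - s[0])
        # within-class 2x2 cell counts over (t2, t3)
        n1_ab = np.zeros((2, 2))
        n0_ab = np.zeros((2, 2))
        for k, (t1, t2, t3) in enumerate(pats):
            n1_ab[t2, t3] += y[k]
            n0_ab[t2, t3] += n_k[k] - y[k]
        # griddy Gibbs for S2, S3, cov_pos (class 1)
        for jj, other in ((1, 2), (2, 1)):
            counts_ab = n1_ab if jj == 1 else n1_ab.T
            ld = (
                (priors.sens[jj].a - 1) * np.log(grid)
                + (priors.sens[jj].b - 1) * np.log(1 - grid)
                + _dep_cell_loglik(counts_ab, grid, s[other], cov_p)
            )
            ld[grid <= 1 - c[jj]] = -np.inf  # identifiability S_j + C_j > 1
            s[jj] = _grid_sample(rng, grid, ld)
        lo, hi = _cov_range(s[1], s[2])
        cg = np.linspace(lo + 1e-9, hi - 1e-9, mcmc.grid_points)
        cov_p = _grid_sample(rng, cg, _dep_cell_loglik(n1_ab, s[1], s[2], cg), lo, hi)
        # class 0: margins are 1 - C_j
        for jj, other in ((1, 2), (2, 1)):
            counts_ab = n0_ab if jj == 1 else n0_ab.T
            ld = (
                (priors.spec[jj].a - 1) * np.log(grid)
                + (priors.spec[jj].b - 1) * np.log(1 - grid)
                + _dep_cell_loglik(counts_ab, 1 - grid, 1 - c[other], cov_n)
            )
            ld[grid <= 1 - s[jj]] = -np.inf
            c[jj] = _grid_sample(rng, grid, ld)
        lo, hi = _cov_range(1 - c[1], 1 - c[2])
        cg = np.linspace(lo + 1e-9, hi - 1e-9, mcmc.grid_points)
        cov_n = _grid_sample(rng, cg, _dep_cell_loglik(n0_ab, 1 - c[1], 1 - c[2], cg), lo, hi)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            if kept < out.shape[0]:
                out[kept] = np.concatenate([[pi], s, c, [cov_p, cov_n]])
                kept += 1
    return out[:kept]


def gibbs_sample(
    counts: PatternCounts,
    priors: LcaPriors | None = None,
    mcmc: McmcConfig | None = None,
    dependence: bool = False,
    seed: int | None = None,
) -> PosteriorDraws:
    """Posterior sampling for the latent class model.

    Runs ``mcmc.chains`` independent chains of data-augmentation Gibbs,
    discards burn-in, thins, and reports a split-chain potential scale
    reduction diagnostic (R-hat) on the prevalence.  Deterministic for a
    fixed seed.  Non-convergence raises a warning, never an error.
    """
    import warnings

    if priors is None:
        priors = LcaPriors.default()
    if mcmc is None:
        mcmc = McmcConfig()
    if priors.n_tests != counts.n_tests:
        raise ConfigError(
            f"priors specify {priors.n_tests} tests, counts {counts.n_tests}"
        )
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    chain_fn = _run_chain_dependence if dependence else _run_chain_independence
    chains = []
    for ch, child in enumerate(ss.spawn(mcmc.chains)):
        rng = np.random.default_rng(child)
        arr = chain_fn(rng, counts, priors, mcmc)
        chains.append(arr)
    J = counts.n_tests
    cols = ["pi"] + [f"sens_{j + 1}" for j in range(J)] + [f"spec_{j + 1}" for j in range(J)]
    if dependence:
        cols += ["cov_pos", "cov_neg"]
    frames = []
    for ch, arr in enumerate(chains):
        df = pd.DataFrame(arr, columns=cols)
        df.insert(0, "chain", ch)
        frames.append(df)
    draws = pd.concat(frames, ignore_index=True)
    pi_chains = np.stack([a[:, 0] for a in chains])
    rhat = _split_rhat(pi_chains)
    if np.isfinite(rhat) and rhat > mcmc.rhat_threshold:
        warnings.warn(
            f"possible non-convergence: split R-hat on prevalence = {rhat:.3f} "
            f"(threshold {mcmc.rhat_threshold})",
            RuntimeWarning,
        )
    meta = {
        "chains": mcmc.chains,
        "iterations": mcmc.iterations,
        "burn_in": mcmc.burn_in,
        "thin": mcmc.thin,
        "seed": seed,
        "dependence": dependence,
        "rhat_prevalence": rhat,
    }
    return PosteriorDraws(draws=draws, n_tests=J, meta=meta)


# ---------------------------------------------------------------------------
# pattern posteriors and the latent reference standard


@dataclass
class PatternPosterior:
    """Posterior-median screening probability and dichotomised label for each
    indicator pattern."""

    table: pd.DataFrame  # columns: pattern, prob_median, label

    def label_of(self, pattern) -> int:
        key = "".join(str(int(t)) for t in pattern)
        row = self.table.set_index("pattern").loc[key]
        return int(row["label"])

    def prob_of(self, pattern) -> float:
        key = "".join(str(int(t)) for t in pattern)
        return float(self.table.set_index("pattern").loc[key, "prob_median"])


def pattern_posterior(draws: PosteriorDraws) -> PatternPosterior:
    """Per-pattern posterior median of P(screening | pattern), dichotomised
    at 50% (median >= 0.5 -> screening; an exact 0.5 counts as screening)."""
    if len(draws.draws) == 0:
        raise InputError("no retained draws")
    J = draws.n_tests
    pats = np.array(list(itertools.product([0, 1], repeat=J)))
    d = draws.draws
    pi = d["pi"].to_numpy()[:, None]
    s = np.stack([d[f"sens_{j + 1}"].to_numpy() for j in range(J)], axis=1)
    c = np.stack([d[f"spec_{j + 1}"].to_numpy() for j in range(J)], axis=1)
    t = pats[None, :, :]  # (1, K, J)
    p1 = np.prod(np.where(t == 1, s[:, None, :], 1 - s[:, None, :]), axis=2)
    p0 = np.prod(np.where(t == 1, 1 - c[:, None, :], c[:, None, :]), axis=2)
    if draws.dependence:
        cov_p = d["cov_pos"].to_numpy()[:, None]
        cov_n = d["cov_neg"].to_numpy()[:, None]
        sign = ((2 * pats[:, 1] - 1) * (2 * pats[:, 2] - 1))[None, :]
        m2 = np.where(pats[None, :, 1] == 1, s[:, None, 1], 1 - s[:, None, 1])
        m3 = np.where(pats[None, :, 2] == 1, s[:, None, 2], 1 - s[:, None, 2])
        t1 = np.where(pats[None, :, 0] == 1, s[:, None, 0], 1 - s[:, None, 0])
        p1 = t1 * (m2 * m3 + sign * cov_p)
        u2 = np.where(pats[None, :, 1] == 1, 1 - c[:, None, 1], c[:, None, 1])
        u3 = np.where(pats[None, :, 2] == 1, 1 - c[:, None, 2], c[:, None, 2])
        t0 = np.where(pats[None, :, 0] == 1, 1 - c[:, None, 0], c[:, None, 0])
        p0 = t0 * (u2 * u3 + sign * cov_n)
    num = pi * p1
    den = num + (1 - pi) * p0
    post = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    med = np.nanmedian(post, axis=0)
    table = pd.DataFrame(
        {
            "pattern": ["".join(map(str, p)) for p in pats],
            "prob_median": med,
            "label": (med >= 0.5).astype(int),
        }
    )
    return PatternPosterior(table)


def latent_reference(
    indicators: pd.DataFrame, draws: PosteriorDraws
) -> pd.DataFrame:
    """Label every patient by their pattern's dichotomised posterior.

    Returns a table with ``patient_id`` and ``label`` (1 = screening);
    patients sharing a pattern always share a label.
    """
    pp = pattern_posterior(draws)
    counts_check = pattern_counts(indicators)  # validates missingness / 0-1
    del counts_check
    keys = (
        indicators[INDICATOR_COLUMNS].astype(int).astype(str).agg("".join, axis=1)
    )
    lookup = pp.table.set_index("pattern")["label"]
    probs = pp.table.set_index("pattern")["prob_median"]
    return pd.DataFrame(
        {
            "patient_id": indicators["patient_id"].to_numpy(),
            "prob_screening": keys.map(probs).to_numpy(),
            "label": keys.map(lookup).to_numpy(dtype=int),
        }
    )
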