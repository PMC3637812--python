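# Methods

## The problem and the model

A colonoscopy's indication (screening vs non-screening) is not recorded in
administrative databases, and no gold standard exists against which a
claims-based algorithm could be validated. The package's central device is a
**two-class Bayesian latent class model**: the true indication D ∈ {0, 1} is
unobserved; three imperfect binary indicators T₁ (endoscopist's stated
indication), T₂, T₃ (two patient questionnaire indications) each depend on D
through a sensitivity Sⱼ = P(Tⱼ=1 | D=1) and specificity Cⱼ = P(Tⱼ=0 | D=0).
Under conditional independence given D, the marginal probability of an
indicator pattern t is the mixture

P(t) = π ∏ⱼ Sⱼ^tⱼ(1−Sⱼ)^(1−tⱼ) + (1−π) ∏ⱼ (1−Cⱼ)^tⱼ Cⱼ^(1−tⱼ),

and the data reduce to the 8 pattern counts (multinomial likelihood). The
posterior screening probability of a pattern is P(D=1 | t) =
π P(t | D=1)/P(t). Exams are labelled screening when the **posterior median**
of that probability is ≥ 0.5; an exact 0.5 counts as screening (the 50%
cut-off is read as inclusive). The per-pattern posterior-median probability
is used (rather than plugging posterior-median parameters into the formula);
for these monotone summaries the two agree in practice.

### Priors

* Endoscopist test: Beta(10.67, 1.06) on both S₁ and C₁. This places 97.5%
  of its mass above 0.70 — the elicited judgement that the endoscopist
  reports the true indication at least 70% of the time.
* Patient tests: flat Beta(1, 1) on S₂, C₂, S₃, C₃.
* Prevalence: Beta(6, 7.6), which puts 95.0% of its mass on [0.20, 0.70]
  (mean 0.441).

`prior_coverage` recomputes such coverage statements exactly via the
regularized incomplete beta function.

### Sampler

With three tests the model is just identified (7 free parameters, 7
independent cell frequencies); the label-switching symmetry
(π, S, C) → (1−π, 1−C, 1−S) leaves the likelihood invariant, so draws are
constrained to the region Sⱼ + Cⱼ > 1 for every test.

Inference is **data-augmentation Gibbs**: given parameters, each pattern's
count is split into latent screening / non-screening by a binomial draw;
given the split, π and every Sⱼ, Cⱼ have conjugate beta full conditionals,
sampled truncated to the identifiability region by inverse-CDF. Defaults:
3 chains × 20,000 iterations, 5,000 burn-in, thinning 5, a fixed seed
(per-chain streams spawned from one seed sequence), and a split-chain
potential scale reduction diagnostic on π with warning threshold 1.05 —
non-convergence warns, never fails. Tests and the bundled examples run
shorter chains (typically 2 × 2,000–6,000); for this 7-parameter conjugate
sampler the autocorrelation time is a few iterations and those lengths give
Monte-Carlo errors well below the tolerances asserted.

### Conditional dependence variant

As a robustness check the two patient indications may covary within class:
P(t₂=a, t₃=b | D=1) = m₂(a)m₃(b) + (2a−1)(2b−1)·cov⁺, where m are the
Bernoulli margins, and analogously cov⁻ within D=0. Each covariance is
constrained to the range keeping all four cells non-negative
([max(−S₂S₃, −(1−S₂)(1−S₃)), min(S₂(1−S₃), S₃(1−S₂))] for cov⁺). The
margins keep their beta priors; the covariances get uniform priors over
their valid ranges. These full conditionals are not conjugate, so S₂, S₃,
cov⁺ (and the class-0 analogues) are sampled by **griddy Gibbs** —
inverse-CDF sampling of the tabulated conditional on a 201-point grid,
jittered uniformly within the grid cell. With both covariances at 0 the
variant reproduces the independence model exactly. With 9 parameters and 7
degrees of freedom the variant is weakly identified; on data simulated with
small covariance it labels patterns almost identically to the independence
model, echoing the robustness finding it exists to check.

## Synthetic cohorts

The generator is the package's stand-in for the two-city study data, which
cannot be redistributed. Defaults (editable in `data/synthetic.yaml`):

* n = 1,230 patients; ages truncated-normal(60, 7) on [50, 75]; 48.5% male;
  index dates uniform over January–March 2007.
* Latent prevalence π = 0.46. Indicator operating characteristics
  S = (0.95, 0.85, 0.70), C = (0.95, 0.78, 0.87), chosen so the implied
  marginal screening frequencies πSⱼ + (1−π)(1−Cⱼ) = 0.464 / 0.510 / 0.392
  match the observed 46.8% / 51.0% / 38.9%. Indicators 2–3 can be drawn
  with the same within-class covariance parameterization the estimator
  uses (one shared definition, clipped to the valid range).
* Claims: for each of the 14 predictor categories a flag is drawn from
  P(flag | D); when set, 1 + Poisson(0.3) claims with codes from the
  category's dictionary are placed uniformly in the category's window,
  ending the day before the index date. Conditional probabilities are
  calibrated so that (i) the marginal flag frequency matches the published
  code-frequency table (colonoscopy 21.7%, rectal bleeding 7.7%, ...) at
  π = 0.46 and (ii) the conditional odds ratio matches the published
  adjusted OR where one exists (0.06–0.29) and 0.5 otherwise — all below 1,
  i.e. history codes are more common before non-screening exams. Only
  marginals and OR directions are constrained by published evidence; the
  joint distribution of indicators and flags is a generator choice
  (indicators and claims are drawn independently given D).

What the generator does **not** emulate: real code inventories (placeholder
codes ship in `data/codes.yaml`), referral wait-times, repeat-claim
clustering, coding error correlated across categories, and
indicator–claims dependence beyond the shared latent class. Consequently,
passing tests demonstrate the correctness and internal consistency of the
estimators on model-faithful data, not the real-world accuracy of any
algorithm; classifier accuracies on synthetic data land near, but not at,
the published ones (which reflect the real joint distribution).

## Claims features

Windows are half-open: a claim counts iff
index − lookback ≤ date < index. The index day is excluded because a
same-day code is the index exam itself. Years are fixed day counts (365 /
1460 / 1825), ignoring leap days for reproducibility; all windows are
configurable per category.

## Classifiers

* **Logistic regression** is fit by Newton/IRLS with step-halving to the
  maximum-likelihood solution (gradient sup-norm < 1e-10). Complete or
  quasi-complete separation is detected as runaway coefficients, capped at
  |β| = 30 and flagged non-converged. Age enters linearly in years; sex as
  male = 1.
* **Best-subset selection**: all 2^p subsets of the candidates (14 flags +
  age + sex by default, p ≤ 20) are fitted exhaustively, warm-starting each
  subset from its parent's solution; the subset minimizing
  BIC = k·ln(n) − 2·logL (intercept always counted) wins, with ties going
  to fewer variables then lexicographic candidate order.
* **AUC** is the Mann–Whitney concordance probability with ties counted ½,
  computed from midranks; the 95% CI uses the DeLong placement-value
  variance.
* **Recursive partitioning**: greedy binary splits on the claims flags,
  choosing the split with the largest Gini impurity decrease (ties → the
  earliest variable in the fixed candidate order), never re-splitting a
  variable on the same path. Growth stops on purity, node size < 20, or no
  strictly positive decrease. Leaf label is the majority class, ties →
  screening. Pruning is off by default (deterministic, mirrors the
  overfit-prone unpruned analysis); `prune=True` applies weakest-link
  cost-complexity pruning with the penalty chosen by deterministic 5-fold
  cross-validation. Age/sex are excluded from the tree by default but can
  be passed as candidates after binarization by the caller.

## Expert rule

Screening iff no disqualifying diagnosis code within its window and no
colonoscopy procedure code within 4 years. The canonical rule names 28
ICD-9 symptoms/conditions; since the concrete inventory is not public, the
default config carries 28 named placeholder entries (a superset of the
generator's symptom/condition categories). The diagnosis window defaults to
4 years, mirroring the colonoscopy clause, as the original window is
undocumented; both are configurable.

## Evaluation

Sensitivity, specificity, PPV and NPV are reported as percentages with Wald
95% intervals p̂ ± 1.96·√(p̂(1−p̂)/m), truncated to [0, 100] — the method
that reproduces the published accuracy-table intervals; Wilson intervals are
available by flag. Zero-denominator metrics are reported as undefined, not
zero. Cohen's κ uses the large-sample (Fleiss–Cohen–Everitt) variance for
its CI; κ is undefined when both raters are constant.

## Numerical and design notes

* All randomness flows through numpy Generators seeded from explicit seeds;
  chains use spawned child streams, so results are bit-reproducible.
* Pattern probabilities are guarded against zero denominators (patterns
  with zero marginal probability fall back to 0.5 class assignment inside
  the sampler; the log likelihood returns −inf when an observed cell has
  probability zero).
* The pipeline report is JSON with sorted keys and no timestamps, so a
  fixed config yields byte-identical artifacts.
* The pipeline additionally scores every algorithm against the true
  simulated indication — the comparison the original design could never
  run — which is the main scientific payoff of the synthetic substitute.

## Known limitations

* The latent class model assumes the three indicators are (conditionally)
  exchangeable measurements of one binary construct; systematic agreement
  between the two patient indications beyond the modelled covariance would
  bias the reference standard.
* The dependence variant's covariances are weakly identified from 8 cells;
  its posterior leans on the priors, and it is intended as a sensitivity
  analysis, not a primary model.
* Best-subset enumeration is exponential in the candidate count (capped at
  20); beyond that, use a screening step before calling it.
* The tree handles binary predictors only; continuous predictors must be
  discretised by the caller.
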