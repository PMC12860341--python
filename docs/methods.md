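# Methods

## Model

`paintriage` fits, per procedure outcome, a *multistage stacked
classifier*: a chain of identically specified base learners in which each
stage's design matrix is the original referral features augmented with
the predicted-probability vectors of the earlier stages. Writing `x_j`
for the n features and `y_i` for the stage-i probability vector, stage 1
is an ordinary fit on `x`, stage 2 fits on `[x, y_1]`, and stage i on
`[x, y_1, …, y_{i−1}]` (cumulative mode; a `last_only` mode appending
only `y_{i−1}` is available). The previous stage's probability acts as a
compressed score of everything already learned; re-presenting it as a
feature lets the next stage concentrate on the cases the score gets
wrong — the same intuition as cascaded/iterative-refinement
architectures.

The assumptions are those of any stacking scheme: the stage-probability
features used during training must be *out-of-fold* (see Leakage below),
the gain saturates — and eventually reverses into overfitting — as
stages accumulate, and each per-procedure model is an independent binary
problem (a patient may be positive for several procedures; the triage
rule arbitrates at decision time).

## Stage selection (elbow rule)

Stages are trained up to `m_max` (default 4) and the pooled out-of-fold
TPR trajectory `p_1..p_M` is reduced to slope changes
`s_i = |(p_i − p_{i−1}) − (p_{i+1} − p_i)|`, the absolute discrete second
difference, defined for interior stages 2..M−1. The selected stage `i*`
maximises `s_i`; ties break to the smallest stage (fewest stages, least
overfitting risk). Selection is retrospective — all `m_max` stages are
trained first, then the argmax is taken over the whole trajectory —
rather than an online stop-at-first-peak rule, which is what makes the
statistic well-defined at the boundary. `m_max ≥ 3` is enforced because
a shorter trajectory has no interior stage. The statistic is computed on
TPR; the trajectory metric is a config hook but TPR is the default and
the tested path, since the clinical cost of a missed candidate dominates.

## Base learners

The registry holds ten imbalance-aware baselines behind one
`fit`/`predict_proba` contract: Easy Ensemble, Balanced Bagging, RUSBoost
and Balanced Random Forest (resampling ensembles, implemented in-package
on scikit-learn tree and SAMME-boosting primitives, each undersampling
the majority class to the minority size per member/round);
class-weighted random forest, logistic regression (plain, L1, L2) and
SVC (Platt-calibrated); and a one-class SVM fitted on the negative class
only, whose negated decision scores are min-max rescaled to [0, 1] per
scored batch to satisfy the probability contract. Hyperparameters not
fixed by the problem default to the common library defaults and are
exposed through `BaseLearnerSpec.hyperparams`. Linear and kernel models
are wrapped in a standard scaler; tree ensembles are not. Easy Ensemble
is the default base learner for the multistage model — in this setting
(rare positives) its balanced undersample + boosting combination is the
baseline that keeps TPR high without collapsing TNR.

## Cross-validation and metrics

A single stratified k-fold assignment (default k = 10, shuffled,
seed-determined) is fixed per outcome and reused at every stage, keeping
the trajectory comparable stage to stage and preventing information
bleeding through re-randomised folds. All reported stage metrics are
*pooled out-of-fold*: one confusion matrix over all patients, each scored
by the model not trained on their fold. With 10–126 positives, per-fold
TPRs are too unstable to average; pooling is the well-defined choice.
The threshold rule is strict: probability &gt; threshold ⇒ positive call,
equality ⇒ negative (deterministic tie handling at the default 0.5
cut-off). AUC is the Mann–Whitney rank statistic with tie correction.
Folds whose training split contains no positive are skipped with a
warning and excluded from pooled metrics.

The AUC uncertainty convention is the *fold* convention: the k per-fold
AUCs are summarised as mean ± sample SD (k−1 denominator) with the
Student-t interval mean ± t_{(1+level)/2, k−1}·sd/√k. This (and not
DeLong or bootstrap) is the convention that reproduces interval
endpoints from a printed mean ± SD at k = 10, e.g.
0.8944 ± 0.0290 → [0.8737, 0.9151].

## Leakage

The out-of-fold contract is enforced end to end: patient p's probability
at every stage is produced by models trained without p's fold, and the
augmented `stage_prob_j` columns are themselves the pooled out-of-fold
vectors of the earlier stages — never in-sample predictions, which for
boosted trees would be near-degenerate (≈0/1) and distribution-shifted
relative to what the chain sees at inference time. The test suite proves
first-order isolation exactly: a sentinel feature nonzero only inside
p's fold never changes p's own out-of-fold probability at any stage
(tree ensembles cannot split on a column that is constant in their
training data, so the comparison is bitwise). As in any stacking scheme,
second-order coupling remains — other folds' out-of-fold values derive
from models that saw p's fold — which is the accepted trade-off of
out-of-fold stacking; eliminating it would require nested
cross-validation at every stage at k-fold cost per stage.

At inference the chain uses full-data refits of each stage (standard
stacking practice): stage 1's full model scores the new referrals, its
probabilities are appended per the augmentation mode, and so on through
stage i*.

## Synthetic cohort generator

The generator emulates the reference cohort's *shape*, not its content:
3,552 patients; 192 structured features (half binary history flags with
per-column prevalence U(0.02, 0.5), half Poisson visit/medication counts
with rates U(0.3, 3)); 39 binary NLP-concept flags with sparse prevalence
U(0.01, 0.25); and five independent outcomes with exact positive counts
46/126/36/16/10. Each outcome's latent score is a sparse linear
combination of standardised features (default `signal_sparsity` 0.10 ⇒
~23 active features, weights N(0, 1)) plus 5 pairwise interaction terms
(weights N(0, 2)) plus N(0, `noise_scale`²) noise with `noise_scale` 1.0
— values chosen once as a realistic middle ground: strong enough that
ranking models reach AUCs in the high 0.8s/0.9s, as baseline grids on
such cohorts typically do, yet noisy and nonlinear enough that a single
linear stage is suboptimal and stage augmentation has headroom. Labels are assigned by
ranking the latent score and thresholding at the exact positive count
(not Bernoulli draws): reported positive counts are exact integers, and
exact counts make every downstream test deterministic.

What the generator does **not** emulate: real feature correlation
structure (comorbidity clusters, medication co-prescription), the
rule-based NLP extraction itself (negation, family-history context — only
its binary outputs), label noise from clinical-decision variability, and
shared latent drivers across procedures. Passing tests therefore
demonstrate the machinery's correctness and the stacking mechanism's
behaviour under a known generative model — not clinical performance.

## Stage accounting, calibration, probability histograms

Stage accounting reduces the per-patient correctness lattice (patients ×
stages booleans, retained in full) to the marginal counts: captured at
stage 1, newly captured at stage j (wrong at every earlier stage),
lost at stage j (correct at some earlier stage, wrong at j), never
captured, and final-stage correct, separately for positives and
negatives. The lattice is richer than the marginals (e.g. it counts
recaptures — correct, lost, recovered) and every marginal is verified
against per-patient brute-force enumeration in the tests.

Calibration tables use fixed-width bins on [0, 1] (default 10), half-open
with the last bin closed; empty bins are flagged rather than dropped, and
the count-weighted mean of observed fractions equals prevalence by
construction. Fixed-width (not quantile) binning deliberately exposes the
sparsely occupied upper bins characteristic of very low event rates.
Probability histograms export per-stage binned counts with a
positive-case overlay; all evaluation artefacts are export-only
(delimited text) — no plotting in the core.

## Triage rule

`decide` maps a per-procedure probability map to `scheduled(argmax)` when
the top probability exceeds the runner-up's by strictly more than the
review margin, else `manual_review`. The margin defaults to 0.10 but is a
mandatory, logged configuration value — the automation/oversight
trade-off belongs to the deploying clinical service. Raw probabilities
are ranked (no per-model thresholding before the argmax); the 0.5
threshold is used only for confusion metrics. Exact top ties have zero
lead and always go to review; a single-procedure map is always scheduled.

## Numerical and design choices

- Seeds: every stochastic component (cohort, folds, each per-fold
  learner, each ensemble member) derives from explicit integer seeds;
  identical (cohort seed, CV seed, spec) gives bit-identical traces.
- Per-fold learners are seeded `seed + 1000·fold` so folds are
  independent but reproducible.
- One-class SVM rescaling guards the degenerate constant-score batch by
  returning 0.5.
- F1 is defined as 0 when precision + recall = 0; metrics that are
  undefined (no positives, no predicted positives) carry an explicit
  degenerate flag instead of a silent 0, and evaluation with no positive
  labels raises.
- Labels ranked with a stable sort: latent-score ties resolve by patient
  order, deterministically.
- Problem sizes in the test-suite and acceptance runs: unit and property
  tests use cohorts of 80–500 patients; the full-cohort checks (stage-2
  TPR gain, acceptance fits) use the default 3,552-patient cohort with
  the default easy-ensemble configuration, which fits a 4-stage,
  10-fold model per procedure in seconds to tens of seconds each.

## Known limitations

- The reference cohort's clinical results are not reproducible without
  the (undeposited) patient data; the package reproduces the reported
  accounting narratives and the CI and F1 conventions exactly, and
  demonstrates the stacking mechanism on synthetic cohorts.
- Reported per-stage metrics in this setting could in principle be
  pooled or fold-averaged; this package pools and documents it.
- Easy Ensemble members see very small balanced samples when positives
  are rare (e.g. 2×10 patients for the rarest outcome); stage metrics for
  such outcomes are intrinsically high-variance, and AUC estimates can be
  optimistic — mirrored in the generator's smallest outcomes.
- The multistage chain increases inference cost linearly in i* and the
  stage-probability features resist clinical interpretation; the impurity
  importances exported per procedure are a coarse aid, with permutation
  importance behind a flag.
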