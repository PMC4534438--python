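# Methods

## Problem and data model

The package models questionnaire-based diagnostic triage for seven
paediatric pulmonary diagnosis groups (CF, AS, PCD, PM, AB, PBB, CTRL, in
that fixed canonical order). A record is a vector of 45 answers on the
ordinal scale 1–6, optionally labelled with a confirmed diagnosis. The
canonical class order is used for every probability vector, confusion
matrix and tie-break; it is the order in which the study cohort's group
sizes are conventionally listed, and nothing downstream depends on it
beyond determinism.

Answers are treated numerically (1..6) by all classifiers. This is an
assumption, not a theorem: it imposes a metric on an ordinal scale, which
is what makes distance- and covariance-based members (kNN, LDA, SVM)
applicable at all; the categorical members (naive Bayes, fuzzy) ignore the
metric and use level identities only.

### Missing answers

The tabular format admits empty cells. The package imputes them with the
per-question rounded median of the training partition (stored inside every
trained model and applied to queries as well); a question with no observed
training answers falls back to the scale midpoint 3. Median imputation was
chosen because it stays on the ordinal scale and is insensitive to the
skewed answer distributions that peaked class profiles produce. The
frequency-based analyses (heat maps, information gain) instead simply drop
missing answers from the affected question's denominators, which keeps
each frequency row a probability vector.

## The classifier bank

No hyperparameters are prescribed by the problem statement, so the
defaults below are package choices, kept in one overridable block
(`classifiers.DEFAULT_HYPERPARAMETERS`):

| member | implementation | defaults and rationale |
| --- | --- | --- |
| SVM | `sklearn.svm.SVC` | RBF kernel, `C=1`, `gamma="scale"`, `probability=True` (internal Platt calibration) — the standard strong default for small-n tabular data |
| ANN | `sklearn.neural_network.MLPClassifier` | one hidden layer of 16 units, lbfgs solver (deterministic and fast at n≈150), `max_iter=600` |
| FUZZY | own implementation (below) | Laplace `alpha=1` |
| RANDOM_FOREST | `sklearn.ensemble.RandomForestClassifier` | 500 trees — large enough that forest variance is negligible at this n |
| LOGISTIC | `sklearn.linear_model.LogisticRegression` | multinomial, L2, `C=1`, `max_iter=2000` |
| LDA | `sklearn.discriminant_analysis.LinearDiscriminantAnalysis` | `solver="lsqr"`, `shrinkage="auto"` — with 45 features and ~20 records per class the unshrunk covariance is singular |
| NAIVE_BAYES | `sklearn.naive_bayes.CategoricalNB` | per-level categorical model, Laplace `alpha=1`, `min_categories=6` so unseen levels are smoothed rather than crashing |
| NEAREST_NEIGHBOUR | own implementation | `k=5`, Euclidean distance on the numeric levels, inverse-distance-weighted vote fractions as probabilities |

The nearest-neighbour member is hand-written rather than delegated for one
reason: tie-safety. Every training point whose distance equals the k-th
smallest is included in the neighbourhood, so predictions are exactly
invariant under training-record order (library implementations break such
ties by storage index). Exact matches (distance 0) take the whole vote.

The fuzzy rule-based member: for class c and question q the membership of
answer level a is the Laplace-smoothed class-conditional frequency
`(count(a|q,c) + 1) / (n_c + 6)` rescaled so its maximum over the six
levels is 1 (a Mamdani-style histogram membership); a query's rule
strength for class c is the geometric mean of its 45 memberships
(equivalently the exponential of the mean log-membership — smoothing
guarantees strict positivity); posteriors are the strengths normalised to
sum 1. This is the simplest faithful instantiation of a fuzzy rule base
over histogram memberships and is a package design choice.

Classes absent from a training partition receive probability exactly 0
from every member — the fusion stage must not credit a diagnosis no
member could have learned. Single-class training sets short-circuit to a
constant-certainty model for the scikit-learn members (which refuse
single-class fits); the fuzzy and nearest-neighbour members handle the
case natively.

All stochastic members take an explicit seed; no global random state is
touched anywhere in the package.

## Fusion

Scores are the per-class sums of the eight posteriors; the relative score
divides by the total (= number of members, each posterior summing to 1).
Two decisions were genuinely open:

- **What the confidence limit applies to.** The limit is applied to the
  *relative* score (default 0.25 ≈ 1.75× the 1/7 chance level),
  because the relative scale is invariant to the number of members
  configured. Raw scores are reported alongside.
- **Weighting.** Summation is equal-weight: each member's confidence is
  its implicit vote weight. No learned fusion weights, stacking or
  cross-member calibration (explicitly out of scope).

Argmax ties are broken by canonical class order. A below-limit outcome is
a no-call; it is reported with the top-3 ranked shortlist (the tool should
still direct attention even when it abstains), and it counts as a
misclassification in every accuracy and sensitivity figure — the
evaluation keeps a single correct/incorrect tally with no abstention
credit.

Case-level output reports relative scores rounded to whole percentages,
plus a per-member audit trail of all eight posteriors.

## Cross-validated evaluation

Stratified k-fold (default k=10). The fold plan is a deterministic
function of (cohort order, k, seed): classes are visited in canonical
order, records within a class are shuffled by the seed, and all records
are dealt round-robin to folds by a single running fold pointer carried
across classes. This construction guarantees simultaneously (a) per-class
fold counts differ by at most 1, and (b) overall fold sizes differ by at
most 1, with larger folds first when the total is not divisible by k. On
the 170-record study composition with k=10 every fold has exactly 17
records and every training partition 153. If k exceeds the smallest class
count the plan is still built, with a warning (some validation folds then
lack that class).

Per fold, all configured members are retrained on the out-of-fold records
(fold seeds derived deterministically from the base seed) and every
validation record is fused. One-vs-rest ROC curves use the fused relative
scores *pooled across folds* (per-fold curves would rest on ~2–3
positives each for the smaller classes); points are taken at every
distinct score threshold with endpoints (0,0) and (1,1), and AUC is the
trapezoidal area, which equals the concordant-pair statistic with ties
counted 1/2 (the test suite verifies this equivalence against a
brute-force pair count). The stand-alone sensitivity table uses each
member's own argmax (no limit), the fusion row the fused proposals.

## Question-level analyses

Heat maps: `delta[q][a] = relfreq(a|q,d1) − relfreq(a|q,d2)` with
within-class, per-question non-missing denominators; each question row
therefore sums to 0 and entries lie in [−1, 1], with +1/−1 exactly at the
all-versus-none configurations. All 21 unordered pairs are emitted once,
canonically earlier class first; reversing a pair negates the matrix
exactly. Per pair, questions are ranked by `max_a |delta[q][a]|`.

Information gain is the mutual information between class label and answer,
in bits (base 2 — the base affects only scale, never ranking), computed
as `H(class) − Σ_a p(a) H(class|a)` with `0·log 0 ≡ 0`, over labelled
records with a non-missing answer. Ranking ties break by ascending
question index. Gains lie in `[0, log2(7)]`.

## Synthetic cohort generator

The generator emulates class-conditional answer behaviour: each class
answers each question from its own categorical distribution over the six
levels, independently across questions and records. The default spec uses
the study composition (CF 33, AS 27, PCD 24, PM 21, AB 23, PBB 18,
CTRL 24; 170 records total) and a single `separation` knob in [0, 1]:
each class's distribution on a designated question is the mixture
`(1−s)·uniform + s·peaked`, where the peaked distribution is a narrow
triangular kernel (weight 1 at the class's modal level, 0.05 at the
adjacent levels). At s=0 every class answers uniformly (pure chance
level); at s=1 each class is pinned near-degenerately to its modal
profile and the classes are essentially perfectly separable.

Each class carries a distinct modal profile over a designated 42-question
informative panel (questions 43–45 are uninformative filler at every
separation). Profiles are drawn once from a fixed profile seed — separate
from the cohort sampling seed, so the "study conditions" are identical
for every generated cohort — with a guarantee that any two class profiles
differ on at least one question. A broad informative panel was chosen
over a few signature questions per class because in the motivating
setting essentially every questionnaire item carried some diagnostic
signal, and because it gives the generator its intended limiting
behaviour (separable at s=1, chance at s=0).

Sampling consumes one seeded stream in class-canonical, record-major,
question-minor order; missing markers (optional `missing_rate`) are drawn
inline per answer. Generation is a pure function of the spec, so equal
specs give byte-identical cohorts.

**What the generator does not emulate:** correlations between questions
within a record (class-conditional independence is assumed), ordinal
response styles (e.g. end-aversion), label noise, and any resemblance to
the real study's marginals. Passing recovery tests on these cohorts
therefore demonstrates that the pipeline is correct and well-calibrated
on its own terms, not that it attains any particular accuracy on real
questionnaires.

## Problem sizes and determinism

The test suite and the reproduction script run the full pipeline at the
study scale (170 records, 45 questions, 8 members, 10 folds) for the
recovery and chance-level checks, and at 4–24 records for the oracle
equivalences (brute-force AUC, naive-Bayes products, joint-distribution
information gain), which are exhaustive at that size. Every stochastic
path is seeded; reports embed a configuration fingerprint (SHA-256 of the
kinds/k/limit/seed/hyperparameter block) so runs can be matched to their
configuration.

## Known limitations

- The eight members' hyperparameters are fixed defaults; no tuning
  machinery is provided, so reported synthetic accuracies characterise the
  defaults, not the methods' optima.
- The fusion limit 0.25 is a design constant; its operating point on real
  data (no-call rate vs error rate) is unstudied here.
- Model persistence uses Python pickling inside a versioned envelope;
  archives are refused across package versions rather than migrated.
- The question registry ships synthetic placeholder texts for most items;
  texts are display metadata only.
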