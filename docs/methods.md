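# Methods

This note records the statistical models, the defaults, and the design
choices behind `copdtriage`, and what the simulations can and cannot say
about real panels.

## Variable schema and feature space

The schema declares 31 clinical variables — patient profile (age, weight,
height, gender, GOLD stage 1–4, baseline MMRC dyspnea 1–5, recent
exacerbations, lives alone, smoker, long-term oxygen, assisted daily
activity), seven yes/no comorbidities, nine current symptoms, and four
current vitals — plus two baseline vitals (usual oxygen saturation and
usual FEV1 as percent of predicted) used for delta features. `unknown` is
an admissible response for every variable except age, weight, height,
gender, baseline dyspnea and the symptom questions; this mirrors data
collection where stable background facts and current symptoms are always
obtainable but measurements may not be.

Encoding produces ~110 features:

* one-hot level indicators for multi-level categoricals; single 0/1
  indicators for yes/no variables (plus an `_unknown` companion where
  allowed);
* half-open `(a, b]` bin indicators for current vitals. Oxygen-saturation
  cut points 85/87/89/91/93, heart-rate cut points 100/110/120 and FEV1
  delta cut points −15/−5/0/+10 follow the bins the fitted models expose
  in their importance tables; FEV1 percent-of-predicted
  (20/40/60/80/90) and temperature (97/99/100.4 °F) edges are package
  defaults completing the table. Values are clipped into the outer bins.
* delta features against baseline: FEV1 as percent change, oxygen
  saturation as absolute points. The O2-saturation delta bins are
  left-closed `[a, b)` (as their printed names indicate) and are *gated*:
  they activate only when the known baseline saturation is below 93%,
  reflecting that a 2-point drop means something different in a patient
  whose usual saturation is already marginal. When either side of a delta
  is unknown the delta's own unknown indicator fires instead.
* a combined sputum feature counting positive sputum signs (colour change,
  volume increase → levels 0/1/2), emitted alongside the single-sign
  indicators; both sets are kept because the fitted models used both, and
  either can be disabled at encoding time.
* numeric pass-through covariates: age, height, and BMI computed from
  weight (lb) and height (ft+in) by the standard imperial conversion
  703·w/h².

Invariants enforced and property-tested: bin indicators of one source
variable are mutually exclusive and, together with the unknown indicator,
sum to one; the one-hot block decodes back to the original levels;
encoding is deterministic.

## Cohort generation

**Profile design.** Candidate profiles (profile variables + baseline
vitals) are sampled uniformly over the schema's levels and ranges — the
design stage wants coverage, not realism — and coded into a linear
main-effects model matrix (intercept, first-level-dropped dummies,
continuous scaled to [−1, 1]; 19 columns). A Fedorov exchange algorithm
selects the n-point subset maximising log det(X'X): random nonsingular
start, repeated best single swap using the determinant-ratio delta
Δ = d(v) − d(u) − (d(u)d(v) − c(u,v)²), convergence when no swap improves,
best of k restarts (default 3). The selection is deterministic given the
seed, and on all candidate sets small enough to enumerate it attains the
exhaustive optimum (tested). The design needs at least 19 rows — the
number of coded columns — to be nonsingular.

**Completion.** Comorbidities, symptoms and current vitals are drawn from
per-variable marginals coupled through a Gaussian copula. Defaults are
chosen once to be clinically plausible for an older COPD population
(e.g. hypertension 55%, CHF 20%; symptom levels mildly worse-than-usual
skewed; current O2 saturation = baseline − N(1.5, 2.5²) truncated; current
FEV1 = baseline × (1 − N(5, 10²)%/100)) with a sparse latent correlation
structure (breathlessness–wheeze 0.40, sputum colour–volume 0.50,
infection–temperature 0.40, CHF–pulmonary-hypertension 0.40, …). They are
configuration, not estimates from any dataset. Non-PSD correlation inputs
are repaired by eigenvalue clipping with a warning. Unknown responses are
injected independently at a default rate of 5% into the completion
variables that admit them — a rate picked once as a realistic
missing-measurement burden; the schema's own validation bounds everything
else.

**Assembly.** The default shape is 100 design profiles → 2,501 cases →
2,400 training / 101 validation. Each design profile appears at least
once; the remaining cases resample profiles uniformly (how the original
profile set maps onto the larger cohort is not otherwise determined, and
uniform resampling is the least-informative choice). Whether the larger
cohort reuses the first design or a fresh one is an open question in the
source protocol; the generator builds one design per cohort, which
subsumes both readings. The validation subset is drawn uniformly at
random. Generation is bit-reproducible under the config seed.

## The synthetic panel

A rater is a parametric policy: latent severity = Σ w·x + bias + ε,
ε ~ N(0, noise_sd²), cut by thresholds (t₁ < t₂ < t₃) into Ok/Plan/Doc/ER;
a separate weighted rule with one threshold gives the exacerbation call;
confidence = 100·(1 − exp(−d/s)) where d is the distance of the latent
score from the nearest threshold. Bias is an additive shift of the score,
so *positive* bias over-triages. Confidences are generated but never used
in consensus — no published use of them exists, so they are recorded
only.

The reference weights load low oxygen-saturation bins most heavily
(O2 ≤ 85: 4.0) and step down through FEV1 drops, tachycardia, fever and
worse-than-usual symptoms; thresholds (2.0, 4.75, 6.75) were fixed once
against the reference cohort's severity distribution to give a plausible
triage mix. The default 9-rater panel adds per-rater log-normal weight
jitter (σ = 0.15), threshold noise and latent noise (SD 0.35), and two
deliberate outliers — rater 2 over-triages (+1.6 bias, ER-heavy) and
rater 3 under-triages (−2.2 bias) by more than 2 SD of the panel's
category shares, the degree of heterogeneity a real panel has been
observed to show. Policies are a generative stand-in for physician
judgment, not a cognitive model: they exist so that the ground-truth
labelling process is *known*, which is what makes recovery experiments
meaningful.

A separate sparse *recovery* policy (8 features, weights on a 0.5 lattice,
thresholds placed off-lattice so every case clears its nearest threshold
by ≥ 0.25) defines the panel for classifier-recovery experiments: its
noiseless raters label every case identically, so the consensus is the
policy's own labelling and a sufficiently expressive classifier should
reproduce it almost exactly.

## Consensus

Per-case consensus is the modal vote; among categories tied for the
maximal count the *highest* (most conservative) wins — for exacerbation,
"yes" is the conservative side. Votes are unweighted. Three membership
scenarios are supported: all members (algorithm votes included),
physicians only, and leave-self-out (the scored member's votes are
removed; whether the algorithm's votes remain in a physician's
leave-self-out consensus is controlled by passing them or not, since the
protocol leaves it ambiguous). Own votes can only help: agreement with a
self-inclusive consensus is provably ≥ the leave-self-out agreement, and
the property tests check this on simulated panels.

## Classifier harness

Training cases carry one individual rater label each (assigned in
100-case batches rotating through the training raters, as in the original
collection); validation cases carry the full panel. Nine families (GB,
one-vs-rest LR, linear/poly/RBF SVM, RF, ET, naive Bayes, KNN) are tuned
by exhaustive grid search under stratified 5-fold CV accuracy.
Scale-sensitive families (LR, SVMs, KNN) are standardised in-pipeline so
logistic coefficients are comparable across features. Default grids are
deliberately small configuration values — reproducibility is preferred
over fidelity to unknown original grids. Selection scores each family's
best configuration on the validation consensus and keeps the overall top
two; because selecting on the validation set leaks information, selection
can also be run on held-out folds only, but the default replicates the
published protocol. Triage is trained as plain multiclass (matching the
one-vs-rest logistic description); ordinal-aware models are out of scope.

Feature importance: for gradient boosting, each internal split credits its
feature with the fraction of the tree's samples flowing through the node;
per-tree fractions are averaged over the ensemble and normalised to sum
to one. For logistic regression, features are ranked by |coefficient|
within each one-vs-rest binary model and the final score is the average
rank (lower = more important). In a redundant one-hot basis a linear
model may load a bin's complement instead of the bin itself, so recovery
checks are phrased at the level of *source variables* via the encoding's
provenance map.

## Evaluation

Confusion matrices have rows = consensus, columns = prediction, ordered by
urgency, so below-diagonal mass is under-triage. The safety statistics
UTP = 1 − LT/n and EG1 = C_G1/n generalise the fixed 101-case denominators
of the original definitions to the matrix total n (a `denominator`
argument restores the fixed-n behaviour). Emergency one-vs-rest measures
treat category 4 as positive. The medical-attention collapse maps
{1,2} → no attention, {3,4} → attention and evaluates the 2×2 table.
Metrics with zero denominators are reported as undefined (`None`), never
coerced to 0 or 100. Every formula is property-tested for exact equality
against an independent per-case tally oracle on random label vectors; the
oracle shares the formulas' float operation order (100·num/den) so
equality is exact, not approximate.

## Panel robustness

For each base size s from the configured minimum (default 5) to one less
than the member count: every size-s subset's per-case consensus is
computed, each outside member is added in turn, and the fraction of cases
whose consensus changes is averaged over added members; the mean/max/min
over subsets gives one curve point. Enumeration is exhaustive (the
procedure examines "every possible initial combination"), so the curve is
bit-reproducible; addition order is irrelevant by construction. Triage
and exacerbation curves are computed separately; the algorithm's votes
may join the member pool.

## Numerical and degenerate-input choices

* Singular information matrices report −∞ for the log-determinant rather
  than raising; the exchange algorithm re-draws singular starts and raises
  `design infeasible` only when no nonsingular subset is found.
* Bin lookups clip out-of-span values into the outer bins; delta features
  with any unknown operand set their own unknown indicator.
* Consensus ties at every arity resolve by the (count, category)
  lexicographic maximum, verified against exhaustive enumeration of all
  vote multisets of up to six votes.
* All randomness flows from numpy `SeedSequence` spawns of a single seed;
  identical configs and seeds produce byte-identical cohorts, labels and
  reports.

## What the simulations do and do not show

The generator reproduces the *structure* of the study — cohort shape,
label heterogeneity, consensus mechanics, selection protocol — not its
content: marginals are plausible defaults rather than fitted
distributions, candidate profiles are uniform (so the simulated population
is sicker and more varied than a clinic population), and rater policies
are additive scorers without case-order effects, fatigue, or genuine
clinical disagreement about diagnosis. Passing tests therefore certify
the correctness of the machinery (encodings, design optimality, consensus
arithmetic, metric formulas, recovery of a known labeler) and not any
claim about real patients or real physicians. Headline numbers from the
published analysis that depend on the real physician labels are
reproduced only where the published narrative pins the underlying counts
exactly; two printed values (the exacerbation UTP of one model and the
medical-attention NPVs) are mutually inconsistent with the published
counts and are not reproduced.
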