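# copdtriage

A simulation and evaluation harness for consensus-based triage of chronic
obstructive pulmonary disease (COPD) patients.

Patients living with COPD face a daily risk of acute exacerbations, and the
decision they must make at home — do nothing, watch and wait, call the
doctor, or go to the emergency room — has no gold standard. One way to
study machine triage for this setting is to generate statistically diverse
hypothetical patient cases, have a panel of physicians label each case with
a triage action and an exacerbation call, define the panel's majority
opinion as the reference, and ask whether a trained classifier can match
that consensus at least as well as the individual physicians do — and,
crucially, whether it errs on the safe side when it misses.

`copdtriage` implements that entire experimental design as a testable
library:

* **Schema & encoding** — 31 clinical variables (profile, comorbidities,
  symptoms, vitals) plus baseline vitals, with first-class `unknown`
  responses; cases encode to one-hot levels, binned vitals such as
  `O2Sat_(87, 89]`, baseline-delta bins such as `dfev1_(-15, -5]`, a
  combined sputum feature, and numeric covariates (age, BMI, height).
* **Cohort generation** — a D-optimal profile design (`det(X'X)` maximised
  by a Fedorov exchange algorithm over coded candidate profiles) expanded
  to the full cohort by Gaussian-copula Monte Carlo completion with
  configurable marginals, correlations and unknown-response rate. The
  default shape is 100 design profiles → 2,501 cases → 2,400 training /
  101 validation.
* **Synthetic physician panel** — each rater is a parametric policy:
  additive severity score over the encoded features, Gaussian latent noise,
  and three thresholds mapping the score to the ordinal actions
  Ok < Plan < Doc < ER; a separate weighted rule produces the binary
  exacerbation call. Panels are heterogeneous by construction, including
  extreme over- and under-triagers.
* **Consensus** — per-case majority vote with the conservative tie-break
  (ties resolve to the more urgent category), under three membership
  scenarios: algorithm votes included, physicians only, and
  leave-self-out.
* **Classifier harness** — nine scikit-learn families tuned by grid search
  with stratified 5-fold cross-validation, selected by validation-consensus
  accuracy; feature importance via gradient-boosting sample fractions and
  one-vs-rest logistic-regression coefficient ranks.
* **Evaluation** — classification accuracy, emergency one-vs-rest
  sensitivity/specificity/PPV/NPV, and two ordinal safety statistics:

  ```
  UTP = 1 − LT/n        (LT = below-diagonal confusion count: under-triage)
  EG1 = C_G1/n          (C_G1 = misclassifications by > 1 category)
  ```

  plus the "medical attention" collapse (categories ≥ 3 vs < 3) and
  per-rater label-distribution outlier flags.
* **Panel robustness** — the exhaustive panel-growth procedure: for every
  subset of each base size, the fraction of cases whose consensus changes
  when one more member is added, reported as mean/max/min per size.

## Worked example

`examples/04_safety_metrics.py` evaluates a 101-case triage confusion
matrix with 12 off-diagonal entries, 4 of them below the diagonal:

```
n = 101 cases, 89 matching consensus
ACC 88.1%   ER one-vs-rest: TPR 86.7%  TNR 98.6%  PPV 96.3%  NPV 94.6%
UTP 96.0%   EG1 0.0%
under-triage: 4.0% of cases, 33.3% of misclassifications
medical attention: ACC 93.1%  TPR 100.0%  TNR 66.7%
```

Read: the triager matched the panel consensus in 88.1% of cases and chose
a *less* urgent action than consensus in only 4% (UTP 96.0%), never by more
than one category (EG1 0.0%); on the binary needs-medical-attention
collapse it never sent home a case the panel wanted seen (TPR 100%).

The other example scripts generate a cohort, simulate the panel and its
consensus, run the training/selection pipeline end to end, and compute the
panel-growth convergence curve. A thin CLI mirrors the stages
(`copdtriage generate | label | consensus | evaluate | robustness |
run-all`).

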