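"""Train triage classifiers and evaluate them against the panel consensus.

Runs the end-to-end experiment at a reduced scale (240 cases, one
classifier family) and prints the selection table, the agreement metrics
(Eqs-style accuracy, ER sensitivity/specificity) and the safety summary.
"""

from copdtriage import CohortConfig, ExperimentConfig, run_pipeline

config = ExperimentConfig(
    seed=7,
    cohort=CohortConfig(
        n_design=20, n_candidates=150, n_total=240, n_validation=40, seed=7
    ),
    n_training_raters=4,
    n_validation_raters=9,
    families=("GB", "LR"),
    grids={"GB": {"clf__n_estimators": [100], "clf__max_depth": [2]},
           "LR": {"clf__estimator__C": [1.0]}},
    outdir=None,
)
report = run_pipeline(config)

print(f"top triage family: {report['top_triage_family']}")
tm = report["triage_metrics"]
print(f"triage vs consensus (n={tm['n']}): "
      f"ACC {tm['ACC']:.1f}%  ER-TPR {tm['TPR']:.1f}%  "
      f"UTP {tm['UTP']:.1f}%  EG1 {tm['EG1']:.1f}%")
mm = report["medical_attention_metrics"]
print(f"medical attention: ACC {mm['ACC']:.1f}%  TPR {mm['TPR']:.1f}%")
sf = report["safety"]
print(f"safety: under-triage {sf['under_triage_rate']:.1f}% of cases, "
      f"{sf['under_triage_share']:.1f}% of misclassifications; "
      f">1-category errors: {sf['gt1_count']}")
# UTP is 1 minus the under-triage fraction: 100% means the model never
# chose a less urgent action than the panel consensus.
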