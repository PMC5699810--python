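"""Policy-recovery experiment: can the harness recover a known labeler?

A cohort is generated at the study scale (2,400 training / 101 validation
cases), labelled by a noiseless panel sharing a sparse threshold policy
(``panel.RECOVERY_WEIGHTS``), and the classifier harness is run end to end.
Because the ground-truth labelling process is known exactly, the experiment
has a right answer: the selected model should reproduce the validation
consensus almost perfectly, and the features the policy actually uses
should head the importance rankings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort
from .consensus import ConsensusScenario, consensus_labels
from .features import encode_cohort
from .models import importance_gb, importance_lr, select_top_models, train_and_tune
from .panel import LabelMatrix, recovery_panel, simulate_panel
from .pipeline import BATCH_SIZE
from .schema import default_schema, encode_features


def true_source_variables() -> set[str]:
    """Schema variables the recovery policy's weighted features derive from."""
    from .panel import RECOVERY_WEIGHTS
    from .schema import PatientCase

    schema = default_schema()
    probe_values = {}
    for spec in schema:
        if spec.kind == "categorical":
            probe_values[spec.name] = spec.levels[0]
        else:
            lo, hi = spec.range
            probe_values[spec.name] = 0.5 * (lo + hi)
    fv = encode_features(PatientCase("probe", probe_values))
    out = set()
    for name in RECOVERY_WEIGHTS:
        out.update(fv.provenance[name])
    return out


def feature_sources(feature_names: list[str]) -> dict[str, tuple[str, ...]]:
    """Map every encoded feature name to its source schema variables."""
    from .schema import PatientCase

    schema = default_schema()
    probe_values = {}
    for spec in schema:
        if spec.kind == "categorical":
            probe_values[spec.name] = spec.levels[0]
        else:
            lo, hi = spec.range
            probe_values[spec.name] = 0.5 * (lo + hi)
    fv = encode_features(PatientCase("probe", probe_values))
    return {name: fv.provenance.get(name, ()) for name in feature_names}


def policy_recovery_experiment(
    seed: int = 0,
    n_raters: int = 9,
    n_training_raters: int = 6,
    families: tuple[str, ...] = ("GB", "LR"),
    cohort: CohortConfig | None = None,
) -> dict:
    """Run the recovery experiment and return its measurements."""
    cohort = cohort or CohortConfig(seed=seed)
    cases = generate_cohort(cohort)
    F = encode_cohort(cases)
    train = [c for c in cases if c.split == "train"]
    val = [c for c in cases if c.split == "validation"]
    F_train = F.loc[[c.case_id for c in train]]
    F_val = F.loc[[c.case_id for c in val]]

    policies = recovery_panel(n_raters)
    frames = []
    for b, start in enumerate(range(0, len(train), BATCH_SIZE)):
        chunk = train[start:start + BATCH_SIZE]
        ids = [c.case_id for c in chunk]
        lm = simulate_panel(
            chunk, [policies[b % n_training_raters]],
            seed=seed + b, features=F_train.loc[ids],
        )
        frames.append(lm.df)
    train_labels = LabelMatrix(pd.concat(frames)).df.reset_index()
    X = F_train.loc[train_labels["case_id"]]

    val_labels = simulate_panel(val, policies, seed=seed + 10_000, features=F_val)
    cons = consensus_labels(val_labels, ConsensusScenario.EXCLUDE_ALGO)
    y_val = cons["consensus_triage"].loc[F_val.index].to_numpy(int)

    records = [
        train_and_tune(X, train_labels["triage"].to_numpy(int), fam,
                       task="triage", seed=seed)
        for fam in families
    ]
    selection = select_top_models(records, F_val, y_val)
    top = selection.top_two[0]

    importances = {}
    for rec in records:
        if rec.family == "GB":
            importances["GB"] = importance_gb(rec)
        elif rec.family == "LR":
            importances["LR"] = importance_lr(rec)

    return {
        "n_train": len(train),
        "n_validation": len(val),
        "top_family": top.family,
        "top_validation_accuracy": top.validation_accuracy,
        "selection_table": selection.table,
        "importances": importances,
        "validation_consensus": y_val,
    }
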