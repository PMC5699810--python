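"""End-to-end experiment: generate, label, reach consensus, train, evaluate.

The pipeline chains the stages into the full study design: a D-optimal
cohort is generated, labelled by a (synthetic or file-based) physician
panel, per-case consensus labels are derived with the conservative
tie-break, classifier families are tuned on the training split and compared
on the validation consensus, and the evaluation suite (agreement and safety
statistics, per-rater comparison, feature importances, panel-robustness
curve) is written to the output directory together with a manifest that
makes the run bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .consensus import ConsensusScenario, consensus_labels, member_agreement
from .features import encode_cohort
from .io import read_labels, write_cases_csv, write_labels_csv
from .metrics import (
    build_confusion,
    label_distributions,
    medical_attention_metrics,
    metrics_to_dict,
    safety_summary,
    triage_metrics,
)
from .models import (
    DEFAULT_GRIDS,
    importance_gb,
    importance_lr,
    select_top_models,
    train_and_tune,
)
from .panel import default_panel, simulate_panel
from .robustness import convergence_curve, curve_frame


@dataclass
class ExperimentConfig:
    """Everything a full run needs; the global seed drives every stage."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_training_raters: int = 6
    n_validation_raters: int = 9
    panel_noise_sd: float = 0.35
    families: tuple[str, ...] = ("GB", "LR")
    grids: dict[str, dict] | None = None
    folds: int = 5
    min_panel: int = 5
    labels_path: str | None = None  # use real labels instead of a synthetic panel
    labels_dialect: str = "csv"
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "cohort": {
                    k: v
                    for k, v in asdict(self.cohort).items()
                    if k in ("n_design", "n_candidates", "n_total", "n_validation",
                             "unknown_rate", "seed", "design_restarts")
                },
                "n_training_raters": self.n_training_raters,
                "n_validation_raters": self.n_validation_raters,
                "panel_noise_sd": self.panel_noise_sd,
                "families": list(self.families),
                "folds": self.folds,
                "min_panel": self.min_panel,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


BATCH_SIZE = 100  # training cases are labelled in batches of this size


def _label_training_batches(train_cases, policies, features, seed):
    """Each 100-case batch is labelled by a single rater, rotating the panel."""
    from .panel import LabelMatrix

    frames = []
    for b, start in enumerate(range(0, len(train_cases), BATCH_SIZE)):
        chunk = train_cases[start:start + BATCH_SIZE]
        policy = policies[b % len(policies)]
        ids = [c.case_id for c in chunk]
        lm = simulate_panel(chunk, [policy], seed=seed + b, features=features.loc[ids])
        frames.append(lm.df)
    return LabelMatrix(pd.concat(frames))


def run_pipeline(config: ExperimentConfig) -> dict:
    """Execute the full experiment; returns the report bundle as a dict."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(4)]
    panel_seed, label_seed, train_seed, _ = seeds

    out = Path(config.outdir) if config.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort -------------------------------------------------
    cohort_cfg = config.cohort
    cases = generate_cohort(cohort_cfg)
    train_cases = [c for c in cases if c.split == "train"]
    val_cases = [c for c in cases if c.split == "validation"]
    if out:
        write_cases_csv(cases, out / "cohort.csv")

    features_all = encode_cohort(cases)
    train_ids = [c.case_id for c in train_cases]
    val_ids = [c.case_id for c in val_cases]
    F_train = features_all.loc[train_ids]
    F_val = features_all.loc[val_ids]

    # --- stage 2: panel labels ------------------------------------------
    # Validation cases are labelled by the whole panel; training cases are
    # individually labelled, one rater per 100-case batch, rotating through
    # the training raters.
    policies = default_panel(
        config.n_validation_raters, seed=panel_seed, noise_sd=config.panel_noise_sd
    )
    train_labels = _label_training_batches(
        train_cases, policies[: config.n_training_raters], F_train, label_seed
    )
    if config.labels_path:
        report = read_labels(config.labels_path, dialect=config.labels_dialect)
        if report.labels is None:
            raise RuntimeError(f"label read failed: {report.errors}")
        val_labels = report.labels
    else:
        val_labels = simulate_panel(
            val_cases, policies, seed=label_seed + 1, features=F_val
        )
    if out:
        write_labels_csv(val_labels, out / "validation_labels.csv")

    # --- stage 3: consensus / training targets ---------------------------
    # Training cases carry one individual rater label each; the validation
    # consensus (physicians only at this point) scores model selection.
    pooled = train_labels.df.reset_index()
    X_pool = F_train.loc[pooled["case_id"]]
    y_pool_tri = pooled["triage"].to_numpy(int)
    y_pool_exa = pooled["exacerbation"].to_numpy(int)

    val_cons = consensus_labels(val_labels, ConsensusScenario.EXCLUDE_ALGO).loc[val_ids]

    # --- stage 4: train and select --------------------------------------
    grids = config.grids or {}
    results = {}
    for task, y in (("triage", y_pool_tri), ("exacerbation", y_pool_exa)):
        records = []
        for fam in config.families:
            rec = train_and_tune(
                X_pool, y, fam, task=task,
                grid=grids.get(fam, DEFAULT_GRIDS[fam]),
                folds=config.folds, seed=train_seed,
            )
            records.append(rec)
        target = (
            val_cons["consensus_triage"] if task == "triage"
            else val_cons["consensus_exacerbation"]
        )
        selection = select_top_models(records, F_val, target.to_numpy(int))
        results[task] = selection
    if out:
        for task, sel in results.items():
            sel.table.to_csv(out / f"model_comparison_{task}.csv")

    # --- stage 5: evaluation ---------------------------------------------
    top_tri = results["triage"].top_two[0]
    pred_tri = top_tri.estimator.predict(F_val.to_numpy(float)).astype(int)
    algo_votes = pd.DataFrame(
        {
            "triage": pred_tri,
            "exacerbation": results["exacerbation"].top_two[0]
            .estimator.predict(F_val.to_numpy(float)).astype(int),
        },
        index=F_val.index,
    )
    cons_all = consensus_labels(
        val_labels, ConsensusScenario.ALL_MEMBERS, algo_votes=algo_votes
    ).loc[val_ids]

    cm = build_confusion(pred_tri, cons_all["consensus_triage"].to_numpy(int), K=4)
    tri_m = triage_metrics(cm)
    med_m = medical_attention_metrics(pred_tri, cons_all["consensus_triage"].to_numpy(int))
    safety = safety_summary(cm)
    agreement = {
        scenario.value: member_agreement(val_labels, scenario, algo_votes=algo_votes)
        for scenario in ConsensusScenario
    }
    dists = label_distributions(val_labels)

    # --- stage 6: importances --------------------------------------------
    importances = {}
    for task, sel in results.items():
        for rec in sel.top_two:
            if rec.family == "GB":
                importances[f"gb_{task}"] = importance_gb(rec)
            elif rec.family == "LR":
                importances[f"lr_{task}"] = importance_lr(rec)
    if out:
        for name, imp in importances.items():
            pd.DataFrame(imp.ranking, columns=["feature", "score"]).to_csv(
                out / f"importance_{name}.csv", index=False
            )

    # --- stage 7: robustness ----------------------------------------------
    curve = convergence_curve(
        val_labels, min_panel=config.min_panel,
        algo_votes=algo_votes["triage"],
    )
    if out:
        curve_frame(curve).to_csv(out / "convergence.csv", index=False)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_cases": len(cases),
        "n_train": len(train_cases),
        "n_validation": len(val_cases),
        "model_comparison": {t: s.table.to_dict() for t, s in results.items()},
        "top_triage_family": top_tri.family,
        "triage_metrics": metrics_to_dict(tri_m),
        "medical_attention_metrics": metrics_to_dict(med_m),
        "safety": {
            "under_triage_rate": safety.under_triage_rate,
            "over_triage_rate": safety.over_triage_rate,
            "under_triage_share": safety.under_triage_share,
            "gt1_count": safety.gt1_count,
        },
        "member_agreement": {
            k: v.to_dict() for k, v in agreement.items()
        },
        "outlier_raters": {k: v for k, v in dists.outliers.items()},
        "convergence": curve_frame(curve).to_dict(orient="records"),
        "importance_top10": {
            name: imp.top(10) for name, imp in importances.items()
        },
    }
    if out:
        (out / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
    return report
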