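"""Simulate the physician panel and derive the consensus labels.

Labels a small cohort with the heterogeneous 9-rater panel (including one
over-triager and one under-triager), prints each rater's triage mix, the
flagged outliers, and the consensus distribution under the conservative
tie-break (ties go to the more urgent category).
"""

from copdtriage import (
    CohortConfig, ConsensusScenario, consensus_labels, default_panel,
    encode_cohort, generate_cohort, label_distributions, simulate_panel,
)

cases = generate_cohort(CohortConfig(
    n_design=20, n_candidates=150, n_total=150, n_validation=20, seed=1))
features = encode_cohort(cases)
labels = simulate_panel(cases, default_panel(9, seed=2), seed=3, features=features)

dists = label_distributions(labels)
print("per-rater triage shares (1=Ok, 2=Plan, 3=Doc, 4=ER):")
print(dists.triage_shares.round(2).to_string())
print(f"\ncross-rater mean: {dists.triage_mean.round(2).to_dict()}")
print(f"raters > 2 SD from the panel mean: {dists.outliers}")

cons = consensus_labels(labels, ConsensusScenario.EXCLUDE_ALGO)
mix = cons["consensus_triage"].value_counts(normalize=True).sort_index()
print(f"\nconsensus triage mix: {mix.round(2).to_dict()}")
print(f"consensus exacerbation rate: {cons['consensus_exacerbation'].mean():.2f}")
# doctor_2 (over-triager) and doctor_3 (under-triager) should be flagged;
# the consensus mix sits between the individual styles.
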