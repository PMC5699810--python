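"""Batch feature encoding of case collections into a model matrix."""

from __future__ import annotations

import pandas as pd

from .schema import PatientCase, VariableSpec, encode_features


def encode_cohort(
    cases: list[PatientCase],
    bin_config: dict | None = None,
    schema: list[VariableSpec] | None = None,
    combined_sputum: bool = True,
    single_sputum: bool = True,
) -> pd.DataFrame:
    """Encode cases into a DataFrame (rows = case_id, columns = features)."""
    rows = {}
    for case in cases:
        fv = encode_features(
            case,
            bin_config=bin_config,
            schema=schema,
            combined_sputum=combined_sputum,
            single_sputum=single_sputum,
        )
        rows[case.case_id] = fv.features
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "case_id"
    return df
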