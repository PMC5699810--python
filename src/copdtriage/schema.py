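"""Clinical variable schema, case validation and model-feature encoding.

The cohort is described by 31 clinical variables (patient profile,
comorbidities, current symptoms and vital signs) plus two baseline vitals
used for delta features.  Cases are validated against the schema and then
encoded into the classifier feature space: one-hot level indicators for
categorical variables, half-open ``(a, b]`` interval indicators for binned
vitals, percent-change / absolute-delta bins against baseline, a combined
sputum (colour change + volume increase) feature, and numeric pass-through
covariates (age, BMI, height).

``unknown`` is a first-class response: every variable that admits it gets a
dedicated ``<prefix>_unknown`` indicator, and for each binned vital the bin
indicators plus the unknown indicator always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

UNKNOWN = "unknown"

#: Triage categories in increasing order of urgency.
TRIAGE_CATEGORIES = {1: "Ok", 2: "Plan", 3: "Doc", 4: "ER"}

VALID_GROUPS = ("profile", "comorbidity", "symptom", "vital", "baseline_vital")


class SchemaError(ValueError):
    """Raised for malformed schemas or encoding configuration."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one clinical variable."""

    name: str
    kind: str  # "categorical" | "continuous"
    group: str
    allows_unknown: bool
    levels: tuple[str, ...] | None = None  # categorical
    range: tuple[float, float] | None = None  # continuous
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise SchemaError(f"bad kind {self.kind!r} for {self.name}")
        if self.group not in VALID_GROUPS:
            raise SchemaError(f"bad group {self.group!r} for {self.name}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"categorical {self.name} needs levels")
        if self.kind == "continuous" and self.range is None:
            raise SchemaError(f"continuous {self.name} needs a range")


@dataclass
class PatientCase:
    """One simulated patient: variable name -> level code, number or UNKNOWN."""

    case_id: str
    values: dict[str, object]
    split: str | None = None  # "train" | "validation"


@dataclass
class FeatureVector:
    """Encoded case: feature name -> 0/1 indicator or numeric covariate."""

    case_id: str
    features: dict[str, float]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class ValidationReport:
    case_id: str
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def load_schema(path: str | Path | None = None) -> list[VariableSpec]:
    """Load the variable schema from YAML (package default when no path)."""
    if path is None:
        text = (
            resources.files("copdtriage").joinpath("resources/schema.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    specs = []
    for entry in raw["variables"]:
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                kind=entry["kind"],
                group=entry["group"],
                allows_unknown=bool(entry["allows_unknown"]),
                levels=tuple(str(x) for x in entry["levels"]) if "levels" in entry else None,
                range=tuple(float(x) for x in entry["range"]) if "range" in entry else None,
                units=entry.get("units"),
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    return specs


_DEFAULT_SCHEMA: list[VariableSpec] | None = None


def default_schema() -> list[VariableSpec]:
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        _DEFAULT_SCHEMA = load_schema()
    return _DEFAULT_SCHEMA


def schema_by_name(schema: list[VariableSpec] | None = None) -> dict[str, VariableSpec]:
    return {s.name: s for s in (schema or default_schema())}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_case(case: PatientCase, schema: list[VariableSpec] | None = None) -> ValidationReport:
    """Check a case against the schema.

    Returns a report whose ``violations`` name the variable, the offending
    value and the violated rule (``incomplete case``, ``unknown not
    permitted``, ``range violation``).
    """
    schema = schema or default_schema()
    violations: list[str] = []
    for spec in schema:
        if spec.name not in case.values:
            violations.append(f"incomplete case: missing {spec.name}")
            continue
        value = case.values[spec.name]
        if _is_unknown(value):
            if not spec.allows_unknown:
                violations.append(f"unknown not permitted: {spec.name}")
            continue
        if spec.kind == "categorical":
            if str(value) not in spec.levels:
                violations.append(
                    f"range violation: {spec.name} = {value!r} not in {list(spec.levels)}"
                )
        else:
            try:
                x = float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                violations.append(f"range violation: {spec.name} = {value!r} not numeric")
                continue
            lo, hi = spec.range  # type: ignore[misc]
            if not (lo <= x <= hi):
                violations.append(
                    f"range violation: {spec.name} = {x} outside [{lo}, {hi}]"
                )
    return ValidationReport(case_id=case.case_id, violations=violations)


def _is_unknown(value: object) -> bool:
    return isinstance(value, str) and value.strip().lower() == UNKNOWN


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------

#: Default bin edges. o2sat/heart-rate/delta cut points follow the printed
#: feature names of the fitted models; fev1 and temperature complete the
#: table with package defaults. All intervals are half-open "(a, b]" except
#: the delta-O2Sat bins which are left-closed "[a, b)".
DEFAULT_BINS: dict[str, list[float]] = {
    "o2sat": [0, 85, 87, 89, 91, 93, 100],
    "heartrate": [0, 100, 110, 120, 250],
    "fev1": [0, 20, 40, 60, 80, 90, 100],
    "temperature": [90, 97, 99, 100.4, 108],
    "dfev1": [-100, -15, -5, 0, 10, 100],
    "do2sat": [-100, -4, -2, 0, 100],
}

_BIN_PREFIX = {
    "o2sat": "O2Sat",
    "heartrate": "hr",
    "fev1": "fev1",
    "temperature": "temp",
    "dfev1": "dfev1",
    "do2sat": "dO2Sat",
}

#: Baseline-O2Sat gate for the delta-O2Sat features.
DO2SAT_BASELINE_GATE = 93.0

_PASSTHROUGH = ("age", "height")  # numeric covariates emitted as-is (+ BMI)


def _fmt(x: float) -> str:
    return f"{x:g}"


def bin_feature_names(var: str, edges: list[float]) -> list[str]:
    """Names of the bin indicators for one binned variable."""
    prefix = _BIN_PREFIX.get(var, var)
    names = []
    for a, b in zip(edges[:-1], edges[1:]):
        if var == "do2sat":
            names.append(f"{prefix}_[{_fmt(a)},{_fmt(b)})_base<{_fmt(DO2SAT_BASELINE_GATE)}")
        elif var == "heartrate" and b == edges[-1] and len(edges) > 2 and b >= 200:
            names.append(f"{prefix}_>{_fmt(a)}")
        else:
            names.append(f"{prefix}_({_fmt(a)}, {_fmt(b)}]")
    return names


def _bin_index(x: float, edges: list[float], left_closed: bool = False) -> int:
    """Index of the bin containing x; values outside the span are clipped."""
    side = "right" if left_closed else "left"
    idx = int(np.searchsorted(edges, x, side=side)) - 1
    return min(max(idx, 0), len(edges) - 2)


def bmi_from_imperial(weight_lb: float, height_in: float) -> float:
    """Body-mass index from weight in pounds and height in inches."""
    return 703.0 * weight_lb / (height_in ** 2)


def _check_bin_config(bin_config: dict[str, list[float]]) -> None:
    for var, edges in bin_config.items():
        if len(edges) < 2 or any(b <= a for a, b in zip(edges[:-1], edges[1:])):
            raise SchemaError(f"bad bin config: edges for {var} must strictly increase")


def encode_features(
    case: PatientCase,
    bin_config: dict[str, list[float]] | None = None,
    schema: list[VariableSpec] | None = None,
    combined_sputum: bool = True,
    single_sputum: bool = True,
) -> FeatureVector:
    """Encode one validated case into the classifier feature space."""
    schema = schema or default_schema()
    by_name = {s.name: s for s in schema}
    bins = dict(DEFAULT_BINS)
    if bin_config:
        bins.update(bin_config)
    _check_bin_config(bins)
    for var in list(bins) + list(case.values):
        if var not in by_name and var not in ("dfev1", "do2sat"):
            raise SchemaError(f"schema mismatch: unknown variable {var!r}")

    v = case.values
    feats: dict[str, float] = {}
    prov: dict[str, tuple[str, ...]] = {}

    def put(name: str, value: float, *sources: str) -> None:
        feats[name] = float(value)
        prov[name] = sources

    # numeric pass-through covariates
    put("Age", float(v["age"]), "age")
    put("Height", float(v["height"]), "height")
    put("BMI", bmi_from_imperial(float(v["weight"]), float(v["height"])), "weight", "height")

    # categorical variables
    for spec in schema:
        if spec.kind != "categorical":
            continue
        val = v[spec.name]
        unk = _is_unknown(val)
        if spec.name == "gender":
            put("gender_male", 1.0 if str(val) == "male" else 0.0, "gender")
        elif spec.name in ("sputum_col", "sputum_vol"):
            if single_sputum:
                put(f"{spec.name}_1", 1.0 if str(val) == "yes" else 0.0, spec.name)
                put(f"{spec.name}_0", 1.0 if str(val) == "no" else 0.0, spec.name)
        elif spec.name == "infection":
            put("Infection", 1.0 if str(val) == "yes" else 0.0, "infection")
        elif spec.name == "sleeplessness":
            put("Sleeplessness", 1.0 if str(val) == "yes" else 0.0, "sleeplessness")
        elif set(spec.levels or ()) == {"yes", "no"}:
            put(spec.name, 0.0 if unk else (1.0 if str(val) == "yes" else 0.0), spec.name)
            if spec.allows_unknown:
                put(f"{spec.name}_unknown", 1.0 if unk else 0.0, spec.name)
        else:  # multi-level categorical -> one-hot
            for level in spec.levels or ():
                put(f"{spec.name}_{level}", 0.0 if unk else (1.0 if str(val) == level else 0.0), spec.name)
            if spec.allows_unknown:
                put(f"{spec.name}_unknown", 1.0 if unk else 0.0, spec.name)

    # combined sputum status: count of positive sputum signs (0, 1 or 2)
    if combined_sputum:
        n_pos = int(str(v["sputum_col"]) == "yes") + int(str(v["sputum_vol"]) == "yes")
        for k in (0, 1, 2):
            put(f"sputum(col+vol)_{k}", 1.0 if n_pos == k else 0.0, "sputum_col", "sputum_vol")

    # binned current vitals
    for var in ("o2sat", "fev1", "heartrate", "temperature"):
        names = bin_feature_names(var, bins[var])
        val = v[var]
        unk = _is_unknown(val)
        idx = None if unk else _bin_index(float(val), bins[var])
        for i, name in enumerate(names):
            put(name, 1.0 if idx == i else 0.0, var)
        put(f"{_BIN_PREFIX[var]}_unknown", 1.0 if unk else 0.0, var)

    # delta features against baseline
    _encode_delta_fev1(v, bins["dfev1"], put)
    _encode_delta_o2sat(v, bins["do2sat"], put)

    return FeatureVector(case_id=case.case_id, features=feats, provenance=prov)


def _encode_delta_fev1(v: dict[str, object], edges: list[float], put) -> None:
    """FEV1 percent change from baseline, binned half-open right-closed."""
    names = bin_feature_names("dfev1", edges)
    cur, base = v["fev1"], v["fev1_base"]
    if _is_unknown(cur) or _is_unknown(base):
        idx = None
        unk = 1.0
    else:
        pct = 100.0 * (float(cur) - float(base)) / float(base)
        idx = _bin_index(pct, edges)
        unk = 0.0
    for i, name in enumerate(names):
        put(name, 1.0 if idx == i else 0.0, "fev1", "fev1_base")
    put("dfev1_unknown", unk, "fev1", "fev1_base")


def _encode_delta_o2sat(v: dict[str, object], edges: list[float], put) -> None:
    """O2Sat absolute change, left-closed bins, gated on baseline < 93%.

    When the baseline is known and at or above the gate the delta features
    are inactive (all zero) by design; the unknown indicator fires only when
    the current or baseline saturation is actually unknown.
    """
    names = bin_feature_names("do2sat", edges)
    cur, base = v["o2sat"], v["o2sat_base"]
    if _is_unknown(cur) or _is_unknown(base):
        idx = None
        unk = 1.0
    elif float(base) >= DO2SAT_BASELINE_GATE:
        idx = None
        unk = 0.0
    else:
        delta = float(cur) - float(base)
        idx = _bin_index(delta, edges, left_closed=True)
        unk = 0.0
    for i, name in enumerate(names):
        put(name, 1.0 if idx == i else 0.0, "o2sat", "o2sat_base")
    put("dO2Sat_unknown", unk, "o2sat", "o2sat_base")


def decode_categoricals(fv: FeatureVector, schema: list[VariableSpec] | None = None) -> dict[str, str]:
    """Recover categorical levels from the one-hot block (round-trip check)."""
    schema = schema or default_schema()
    out: dict[str, str] = {}
    f = fv.features
    for spec in schema:
        if spec.kind != "categorical":
            continue
        if spec.name == "gender":
            out["gender"] = "male" if f["gender_male"] == 1.0 else "female"
        elif spec.name in ("sputum_col", "sputum_vol"):
            if f"{spec.name}_1" in f:
                out[spec.name] = "yes" if f[f"{spec.name}_1"] == 1.0 else "no"
        elif spec.name == "infection":
            out["infection"] = "yes" if f["Infection"] == 1.0 else "no"
        elif spec.name == "sleeplessness":
            out["sleeplessness"] = "yes" if f["Sleeplessness"] == 1.0 else "no"
        elif set(spec.levels or ()) == {"yes", "no"}:
            if spec.allows_unknown and f[f"{spec.name}_unknown"] == 1.0:
                out[spec.name] = UNKNOWN
            else:
                out[spec.name] = "yes" if f[spec.name] == 1.0 else "no"
        else:
            if spec.allows_unknown and f[f"{spec.name}_unknown"] == 1.0:
                out[spec.name] = UNKNOWN
            else:
                for level in spec.levels or ():
                    if f[f"{spec.name}_{level}"] == 1.0:
                        out[spec.name] = level
                        break
    return out


def feature_names(
    bin_config: dict[str, list[float]] | None = None,
    schema: list[VariableSpec] | None = None,
    combined_sputum: bool = True,
    single_sputum: bool = True,
) -> list[str]:
    """Column order of the encoded feature space (a probe case is encoded)."""
    schema = schema or default_schema()
    probe_values: dict[str, object] = {}
    for spec in schema:
        if spec.kind == "categorical":
            probe_values[spec.name] = spec.levels[0]  # type: ignore[index]
        else:
            lo, hi = spec.range  # type: ignore[misc]
            probe_values[spec.name] = 0.5 * (lo + hi)
    fv = encode_features(
        PatientCase("probe", probe_values),
        bin_config=bin_config,
        schema=schema,
        combined_sputum=combined_sputum,
        single_sputum=single_sputum,
    )
    return list(fv.features)
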