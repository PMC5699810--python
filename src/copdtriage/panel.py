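"""Synthetic physician panel.

Each simulated rater is a parametric policy: an additive severity score over
the encoded case features, Gaussian latent noise, and three increasing
thresholds that carve the score into the four ordinal triage actions
(Ok < Plan < Doc < ER).  A separate weighted rule with a single threshold
produces the binary exacerbation call.  Confidences (0-100%) increase
monotonically with the distance of the latent score from the nearest
threshold.

Panel heterogeneity (distinct weightings, threshold biases, noise levels,
including extreme over- and under-triagers) is expressed entirely through
the policy parameters, so the ground-truth labelling process is always known
— which is what makes classifier-recovery experiments possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import FeatureVector, PatientCase, encode_features


class PanelError(ValueError):
    pass


@dataclass
class RaterPolicy:
    """Parametric labeler standing in for one physician."""

    rater_id: str
    weights: dict[str, float]
    thresholds: tuple[float, float, float]
    exacerbation_weights: dict[str, float]
    exacerbation_threshold: float
    bias: float = 0.0  # additive score shift; positive pushes toward higher triage
    exacerbation_bias: float = 0.0
    noise_sd: float = 0.0
    confidence_scale: float = 1.0

    def __post_init__(self):
        t1, t2, t3 = self.thresholds
        if not (t1 < t2 < t3):
            raise PanelError("thresholds must strictly increase")
        if self.noise_sd < 0:
            raise PanelError("noise_sd must be non-negative")


class LabelMatrix:
    """Raters x cases table of triage, exacerbation and confidences."""

    COLUMNS = ("triage", "exacerbation", "triage_confidence", "exacerbation_confidence")

    def __init__(self, df: pd.DataFrame):
        if list(df.columns) != list(self.COLUMNS):
            df = df[list(self.COLUMNS)]
        if df.index.names != ["rater_id", "case_id"]:
            raise PanelError("LabelMatrix index must be (rater_id, case_id)")
        if df.index.duplicated().any():
            raise PanelError("duplicate (rater, case) entries")
        tri = df["triage"].to_numpy()
        if not np.isin(tri, [1, 2, 3, 4]).all():
            raise PanelError("triage categories must be in 1..4")
        ex = df["exacerbation"].to_numpy()
        if not np.isin(ex, [0, 1]).all():
            raise PanelError("exacerbation must be 0/1")
        for c in ("triage_confidence", "exacerbation_confidence"):
            v = df[c].to_numpy(float)
            if ((v < 0) | (v > 100)).any():
                raise PanelError(f"{c} outside [0, 100]")
        self.df = df.sort_index()

    @property
    def raters(self) -> list[str]:
        return list(self.df.index.get_level_values("rater_id").unique())

    @property
    def cases(self) -> list[str]:
        return list(self.df.index.get_level_values("case_id").unique())

    def pivot(self, column: str = "triage") -> pd.DataFrame:
        """Cases x raters table of one label column."""
        return self.df[column].unstack("rater_id")

    def subset_raters(self, raters: list[str]) -> "LabelMatrix":
        return LabelMatrix(self.df.loc[list(raters)])

    @classmethod
    def from_records(cls, records: list[dict]) -> "LabelMatrix":
        df = pd.DataFrame.from_records(records).set_index(["rater_id", "case_id"])
        return cls(df)


# ---------------------------------------------------------------------------
# Scoring and rating
# ---------------------------------------------------------------------------

def severity_score(case_features: FeatureVector | dict[str, float], policy: RaterPolicy) -> float:
    """Additive severity: sum of weight x feature over weighted features, plus bias."""
    feats = case_features.features if isinstance(case_features, FeatureVector) else case_features
    return sum(w * feats.get(name, 0.0) for name, w in policy.weights.items()) + policy.bias


def _exacerbation_score(feats: dict[str, float], policy: RaterPolicy) -> float:
    return (
        sum(w * feats.get(name, 0.0) for name, w in policy.exacerbation_weights.items())
        + policy.exacerbation_bias
    )


def _triage_from_score(score: float, thresholds: tuple[float, float, float]) -> int:
    t1, t2, t3 = thresholds
    if score <= t1:
        return 1
    if score <= t2:
        return 2
    if score <= t3:
        return 3
    return 4


def _confidence(distance: float, scale: float) -> float:
    """Monotone map of threshold distance to [0, 100)."""
    return 100.0 * (1.0 - math.exp(-abs(distance) / max(scale, 1e-12)))


def rate_case(
    case: PatientCase | FeatureVector,
    policy: RaterPolicy,
    seed: int | np.random.Generator = 0,
    bin_config: dict | None = None,
) -> tuple[int, int, float, float]:
    """Label one case: (triage, exacerbation, triage_conf %, exacerbation_conf %)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fv = case if isinstance(case, FeatureVector) else encode_features(case, bin_config=bin_config)
    feats = fv.features

    score = severity_score(feats, policy)
    if policy.noise_sd > 0:
        score += policy.noise_sd * rng.standard_normal()
    triage = _triage_from_score(score, policy.thresholds)
    d_tri = min(abs(score - t) for t in policy.thresholds)
    conf_tri = _confidence(d_tri, policy.confidence_scale)

    e_score = _exacerbation_score(feats, policy)
    if policy.noise_sd > 0:
        e_score += policy.noise_sd * rng.standard_normal()
    exac = 1 if e_score > policy.exacerbation_threshold else 0
    conf_ex = _confidence(e_score - policy.exacerbation_threshold, policy.confidence_scale)
    return triage, exac, conf_tri, conf_ex


def simulate_panel(
    cases: list[PatientCase],
    policies: list[RaterPolicy],
    seed: int = 0,
    bin_config: dict | None = None,
    features: pd.DataFrame | None = None,
) -> LabelMatrix:
    """Label every case with every policy.

    Per-split panels (e.g. a smaller panel on training cases and a full one
    on validation) are obtained by calling this on the corresponding case
    subsets with the corresponding policy lists.  Precomputed ``features``
    (cases x feature columns, indexed by case_id) avoid re-encoding.
    """
    if not policies:
        raise PanelError("panel misconfigured: at least one policy required")
    ids = [p.rater_id for p in policies]
    if len(set(ids)) != len(ids):
        raise PanelError("panel misconfigured: duplicate rater_id")

    if features is None:
        from .features import encode_cohort

        features = encode_cohort(cases, bin_config=bin_config)
    F = features
    case_ids = list(F.index)

    ss = np.random.SeedSequence(seed)
    records = []
    for policy, child in zip(policies, ss.spawn(len(policies))):
        rng = np.random.default_rng(child)
        w = np.array([policy.weights.get(c, 0.0) for c in F.columns])
        we = np.array([policy.exacerbation_weights.get(c, 0.0) for c in F.columns])
        scores = F.to_numpy(float) @ w + policy.bias
        e_scores = F.to_numpy(float) @ we + policy.exacerbation_bias
        if policy.noise_sd > 0:
            scores = scores + policy.noise_sd * rng.standard_normal(len(scores))
            e_scores = e_scores + policy.noise_sd * rng.standard_normal(len(e_scores))
        t1, t2, t3 = policy.thresholds
        triage = 1 + (scores > t1).astype(int) + (scores > t2).astype(int) + (scores > t3).astype(int)
        exac = (e_scores > policy.exacerbation_threshold).astype(int)
        d_tri = np.min(np.abs(scores[:, None] - np.array([t1, t2, t3])[None, :]), axis=1)
        conf_tri = 100.0 * (1.0 - np.exp(-d_tri / max(policy.confidence_scale, 1e-12)))
        conf_ex = 100.0 * (
            1.0 - np.exp(-np.abs(e_scores - policy.exacerbation_threshold) / max(policy.confidence_scale, 1e-12))
        )
        for k, cid in enumerate(case_ids):
            records.append(
                dict(
                    rater_id=policy.rater_id,
                    case_id=cid,
                    triage=int(triage[k]),
                    exacerbation=int(exac[k]),
                    triage_confidence=float(conf_tri[k]),
                    exacerbation_confidence=float(conf_ex[k]),
                )
            )
    return LabelMatrix.from_records(records)


# ---------------------------------------------------------------------------
# Default panels
# ---------------------------------------------------------------------------

#: Severity weights of the reference policy, over encoded feature names.
#: Larger totals mean a sicker presentation; thresholds below partition the
#: score into the four triage actions.
REFERENCE_WEIGHTS: dict[str, float] = {
    "O2Sat_(0, 85]": 4.0,
    "O2Sat_(85, 87]": 3.0,
    "O2Sat_(87, 89]": 2.2,
    "O2Sat_(89, 91]": 1.2,
    "O2Sat_(91, 93]": 0.5,
    "dfev1_(-100, -15]": 2.0,
    "dfev1_(-15, -5]": 1.0,
    "dO2Sat_[-100,-4)_base<93": 1.5,
    "dO2Sat_[-4,-2)_base<93": 0.8,
    "hr_(100, 110]": 0.6,
    "hr_(110, 120]": 1.2,
    "hr_>120": 2.0,
    "temp_(100.4, 108]": 1.0,
    "shortbreath_3": 1.5,
    "wheeze_3": 1.0,
    "cough_3": 0.8,
    "mmrc_cur_4": 0.5,
    "mmrc_cur_5": 1.0,
    "sputum(col+vol)_1": 0.5,
    "sputum(col+vol)_2": 1.0,
    "Infection": 0.6,
    "gold_3": 0.5,
    "gold_4": 1.0,
    "recent_exac": 0.6,
    "oxygen_user": 0.5,
    "chf": 0.4,
    "pulm_htn": 0.4,
}

REFERENCE_THRESHOLDS: tuple[float, float, float] = (2.0, 4.75, 6.75)

REFERENCE_EXAC_WEIGHTS: dict[str, float] = {
    "shortbreath_3": 1.2,
    "cough_3": 1.0,
    "wheeze_3": 0.9,
    "sputum(col+vol)_1": 0.7,
    "sputum(col+vol)_2": 1.4,
    "Infection": 0.8,
    "dfev1_(-100, -15]": 1.2,
    "dfev1_(-15, -5]": 0.6,
    "O2Sat_(0, 85]": 1.5,
    "O2Sat_(85, 87]": 1.0,
    "Sleeplessness": 0.3,
}

REFERENCE_EXAC_THRESHOLD = 2.5


def reference_policy(rater_id: str = "reference", noise_sd: float = 0.0) -> RaterPolicy:
    return RaterPolicy(
        rater_id=rater_id,
        weights=dict(REFERENCE_WEIGHTS),
        thresholds=REFERENCE_THRESHOLDS,
        exacerbation_weights=dict(REFERENCE_EXAC_WEIGHTS),
        exacerbation_threshold=REFERENCE_EXAC_THRESHOLD,
        noise_sd=noise_sd,
    )


def default_panel(n_raters: int = 9, seed: int = 0, noise_sd: float = 0.35) -> list[RaterPolicy]:
    """Heterogeneous 9-rater panel with two outlier styles.

    Raters share the reference severity structure with per-rater weight
    jitter, threshold shifts and latent noise.  Rater 2 is an extreme
    over-triager (large positive bias, ER-heavy) and rater 3 an extreme
    under-triager, mirroring the outlier behaviour a real panel can show.
    """
    rng = np.random.default_rng(seed)
    policies = []
    for k in range(1, n_raters + 1):
        weights = {
            name: w * float(np.exp(rng.normal(0.0, 0.15)))
            for name, w in REFERENCE_WEIGHTS.items()
        }
        ew = {
            name: w * float(np.exp(rng.normal(0.0, 0.15)))
            for name, w in REFERENCE_EXAC_WEIGHTS.items()
        }
        bias = float(rng.normal(0.0, 0.25))
        if k == 2:  # over-triager: inflates severity, ER-heavy outlier
            bias += 1.6
        elif k == 3:  # under-triager: deflates severity, Ok-heavy outlier
            bias -= 2.2
        policies.append(
            RaterPolicy(
                rater_id=f"doctor_{k}",
                weights=weights,
                thresholds=REFERENCE_THRESHOLDS,
                exacerbation_weights=ew,
                exacerbation_threshold=REFERENCE_EXAC_THRESHOLD + float(rng.normal(0.0, 0.2)),
                bias=bias,
                noise_sd=noise_sd,
            )
        )
    return policies


#: Sparse threshold policy used for classifier-recovery experiments: few
#: features, weights on a 0.5 lattice, thresholds placed off-lattice so every
#: case clears its nearest threshold by at least 0.25.
RECOVERY_WEIGHTS: dict[str, float] = {
    "O2Sat_(0, 85]": 2.0,
    "O2Sat_(85, 87]": 1.5,
    "O2Sat_(87, 89]": 1.0,
    "shortbreath_3": 1.0,
    "wheeze_3": 0.5,
    "hr_>120": 1.0,
    "dfev1_(-100, -15]": 1.5,
    "gold_4": 0.5,
}

RECOVERY_THRESHOLDS: tuple[float, float, float] = (0.75, 1.75, 3.25)

RECOVERY_EXAC_WEIGHTS: dict[str, float] = {
    "cough_3": 1.0,
    "sputum(col+vol)_2": 1.0,
    "sputum(col+vol)_1": 0.5,
    "Infection": 0.5,
    "shortbreath_3": 0.5,
}

RECOVERY_EXAC_THRESHOLD = 1.25


def recovery_panel(n_raters: int = 9, bias_spread: float = 0.1) -> list[RaterPolicy]:
    """Noiseless sparse-policy panel whose labels a classifier can recover.

    All raters share ``RECOVERY_WEIGHTS``; small bias offsets stay inside the
    0.25 lattice margin, so every rater labels every case identically and the
    consensus equals the policy's own labels.
    """
    offsets = np.linspace(-bias_spread, bias_spread, n_raters)
    base = RaterPolicy(
        rater_id="recovery",
        weights=dict(RECOVERY_WEIGHTS),
        thresholds=RECOVERY_THRESHOLDS,
        exacerbation_weights=dict(RECOVERY_EXAC_WEIGHTS),
        exacerbation_threshold=RECOVERY_EXAC_THRESHOLD,
    )
    return [
        replace(base, rater_id=f"doctor_{k + 1}", bias=float(offsets[k]))
        for k in range(n_raters)
    ]


def noiseless_panel(n_raters: int = 9, bias_spread: float = 0.1) -> list[RaterPolicy]:
    """Deterministic panel sharing the reference weights with small bias offsets.

    The induced consensus is a thresholding of the reference severity score,
    giving a known ground truth for classifier-recovery experiments.
    """
    offsets = np.linspace(-bias_spread, bias_spread, n_raters)
    return [
        replace(reference_policy(f"doctor_{k + 1}"), bias=float(offsets[k]))
        for k in range(n_raters)
    ]
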