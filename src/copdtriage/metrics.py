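"""Agreement and safety statistics for triage and exacerbation predictions.

Confusion matrices are laid out with rows = consensus ("true") category and
columns = predicted category, ordered Ok < Plan < Doc < ER for triage and
no < yes for exacerbation.  Entries below the diagonal are *under-triage*
(the rater chose a less urgent action than consensus), entries above are
over-triage.  On top of the usual one-vs-rest measures with the emergency
category as positive, two bespoke safety statistics are computed:

* ``UTP`` (upper-triangular proximity) = 1 - LT/n, where LT is the total
  below-diagonal count — how close the matrix is to never under-triaging;
* ``EG1`` = C_G1/n, the fraction of cases misclassified by more than one
  ordinal category.

"Medical attention" collapses the four triage actions to a binary outcome:
categories 3 (call the doctor) and 4 (emergency room) require attention,
1 and 2 do not.

Metrics with a zero denominator are reported as ``None`` (undefined), never
coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import LabelMatrix

MEDICAL_ATTENTION_MIN_CATEGORY = 3


class MetricError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = consensus category, columns = predicted."""

    counts: np.ndarray
    categories: tuple[int, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.categories)
        if self.counts.shape != (K, K):
            raise MetricError("counts must be K x K")
        if (self.counts < 0).any():
            raise MetricError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.categories, name="consensus")
        cols = pd.Index(self.categories, name="predicted")
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def build_confusion(predicted, consensus, K: int = 4) -> ConfusionMatrix:
    """Tally predictions against consensus into a K x K matrix."""
    predicted = np.asarray(predicted, dtype=int)
    consensus = np.asarray(consensus, dtype=int)
    if predicted.shape != consensus.shape:
        raise MetricError("alignment error: prediction/consensus length mismatch")
    cats = tuple(range(1, K + 1))
    for v in (predicted, consensus):
        if len(v) and (v.min() < 1 or v.max() > K):
            raise MetricError(f"categories must be in 1..{K}")
    counts = np.zeros((K, K), dtype=int)
    for c, p in zip(consensus, predicted):
        counts[c - 1, p - 1] += 1
    return ConfusionMatrix(counts=counts, categories=cats)


def _ratio(num: int, den: int, percent: bool) -> float | None:
    if den == 0:
        return None
    return 100.0 * num / den if percent else num / den


@dataclass
class TriageMetrics:
    """Accuracy, emergency one-vs-rest measures and the safety statistics."""

    ACC: float | None
    TPR: float | None
    TNR: float | None
    PPV: float | None
    NPV: float | None
    UTP: float | None
    EG1: float | None
    TC: int
    FC: int
    TP_ER: int
    TN_ER: int
    FP_ER: int
    FN_ER: int
    LT: int
    C_G1: int
    n: int


def triage_metrics(
    cm: ConfusionMatrix, percent: bool = True, denominator: int | None = None
) -> TriageMetrics:
    """Compute the seven triage statistics from a 4x4 confusion matrix.

    ``denominator`` overrides n in UTP and EG1 (the study computed both over
    its fixed 101-case validation set); by default the matrix total is used.
    """
    K = len(cm.categories)
    if K != 4:
        raise MetricError("triage metrics require K = 4")
    C = cm.counts
    n = cm.n
    if n == 0:
        raise MetricError("empty confusion matrix")
    er = K - 1  # index of the emergency category

    TC = int(np.trace(C))
    FC = n - TC
    TP = int(C[er, er])
    FN = int(C[er, :er].sum())  # consensus ER, predicted non-ER
    FP = int(C[:er, er].sum())  # consensus non-ER, predicted ER
    TN = int(C[:er, :er].sum())
    LT = int(np.tril(C, k=-1).sum())
    i, j = np.indices(C.shape)
    C_G1 = int(C[np.abs(i - j) > 1].sum())
    den = denominator if denominator is not None else n

    one = 100.0 if percent else 1.0
    return TriageMetrics(
        ACC=_ratio(TC, TC + FC, percent),
        TPR=_ratio(TP, TP + FN, percent),
        TNR=_ratio(TN, TN + FP, percent),
        PPV=_ratio(TP, TP + FP, percent),
        NPV=_ratio(TN, TN + FN, percent),
        UTP=one * (1.0 - LT / den),
        EG1=one * (C_G1 / den),
        TC=TC, FC=FC, TP_ER=TP, TN_ER=TN, FP_ER=FP, FN_ER=FN, LT=LT, C_G1=C_G1, n=n,
    )


@dataclass
class BinaryMetrics:
    """Accuracy and one-vs-rest measures on a 2x2 table (positive = index 1)."""

    ACC: float | None
    TPR: float | None
    TNR: float | None
    PPV: float | None
    NPV: float | None
    TC: int
    FC: int
    TP: int
    TN: int
    FP: int
    FN: int
    n: int


def binary_metrics(cm: ConfusionMatrix, percent: bool = True) -> BinaryMetrics:
    if len(cm.categories) != 2:
        raise MetricError("binary metrics require K = 2")
    C = cm.counts
    n = cm.n
    if n == 0:
        raise MetricError("empty confusion matrix")
    TN, FP, FN, TP = int(C[0, 0]), int(C[0, 1]), int(C[1, 0]), int(C[1, 1])
    TC, FC = TP + TN, FP + FN
    return BinaryMetrics(
        ACC=_ratio(TC, n, percent),
        TPR=_ratio(TP, TP + FN, percent),
        TNR=_ratio(TN, TN + FP, percent),
        PPV=_ratio(TP, TP + FP, percent),
        NPV=_ratio(TN, TN + FN, percent),
        TC=TC, FC=FC, TP=TP, TN=TN, FP=FP, FN=FN, n=n,
    )


def collapse_to_attention(categories) -> np.ndarray:
    """Map triage 1..4 to the binary medical-attention outcome (1/2 of the
    2-category coding: 1 = no attention, 2 = attention needed)."""
    c = np.asarray(categories, dtype=int)
    return np.where(c >= MEDICAL_ATTENTION_MIN_CATEGORY, 2, 1)


def medical_attention_metrics(predicted, consensus, percent: bool = True) -> BinaryMetrics:
    """Collapse triage to need-for-attention and evaluate the 2x2 table."""
    cm = build_confusion(collapse_to_attention(predicted), collapse_to_attention(consensus), K=2)
    return binary_metrics(cm, percent=percent)


@dataclass
class SafetySummary:
    under_triage_rate: float
    over_triage_rate: float
    under_triage_share: float | None  # among misclassifications
    gt1_count: int
    per_category_misses: dict[int, dict[str, float | None]]
    n: int


def safety_summary(cm: ConfusionMatrix) -> SafetySummary:
    """Under-/over-triage rates and per-consensus-category miss breakdown (%)."""
    if len(cm.categories) != 4:
        raise MetricError("safety summary requires K = 4")
    C = cm.counts
    n = cm.n
    LT = int(np.tril(C, k=-1).sum())
    UT = int(np.triu(C, k=1).sum())
    TC = int(np.trace(C))
    i, j = np.indices(C.shape)
    gt1 = int(C[np.abs(i - j) > 1].sum())
    per_cat = {}
    for k, cat in enumerate(cm.categories):
        row = C[k]
        total = int(row.sum())
        under = int(row[:k].sum())
        over = int(row[k + 1:].sum())
        per_cat[cat] = {
            "n": total,
            "missed_rate": _ratio(total - int(row[k]), total, True),
            "under_rate": _ratio(under, total, True),
            "over_rate": _ratio(over, total, True),
        }
    return SafetySummary(
        under_triage_rate=100.0 * LT / n,
        over_triage_rate=100.0 * UT / n,
        under_triage_share=_ratio(LT, n - TC, True),
        gt1_count=gt1,
        per_category_misses=per_cat,
        n=n,
    )


# ---------------------------------------------------------------------------
# Panel label distributions (per-rater voting styles)
# ---------------------------------------------------------------------------

@dataclass
class LabelDistributions:
    triage_shares: pd.DataFrame  # raters x categories, rows sum to 1
    exacerbation_shares: pd.DataFrame
    triage_mean: pd.Series | None
    triage_sd: pd.Series | None
    exacerbation_mean: pd.Series | None
    exacerbation_sd: pd.Series | None
    outliers: dict[str, list[tuple[str, int]]]  # rater -> [(task, category)]


def label_distributions(labels: LabelMatrix, sd_flag: float = 2.0) -> LabelDistributions:
    """Per-rater category shares, cross-rater mean +/- SD, and outlier flags.

    A rater is flagged on a category when its share deviates from the
    cross-rater mean by more than ``sd_flag`` standard deviations.  With a
    single rater only the shares are reported.
    """
    def shares(column: str, cats: list[int]) -> pd.DataFrame:
        piv = labels.pivot(column)
        out = pd.DataFrame(
            {c: (piv == c).mean(axis=0) for c in cats}, index=piv.columns
        )
        out.index.name = "rater_id"
        return out

    tri = shares("triage", [1, 2, 3, 4])
    exa = shares("exacerbation", [0, 1])

    multi = len(labels.raters) >= 2
    tri_mean = tri.mean(axis=0) if multi else None
    tri_sd = tri.std(axis=0, ddof=1) if multi else None
    exa_mean = exa.mean(axis=0) if multi else None
    exa_sd = exa.std(axis=0, ddof=1) if multi else None

    outliers: dict[str, list[tuple[str, int]]] = {}
    if multi:
        for task, table, mean, sd in (
            ("triage", tri, tri_mean, tri_sd),
            ("exacerbation", exa, exa_mean, exa_sd),
        ):
            for rater in table.index:
                for cat in table.columns:
                    s = sd[cat]
                    if s > 0 and abs(table.loc[rater, cat] - mean[cat]) > sd_flag * s:
                        outliers.setdefault(rater, []).append((task, int(cat)))
    return LabelDistributions(
        triage_shares=tri,
        exacerbation_shares=exa,
        triage_mean=tri_mean,
        triage_sd=tri_sd,
        exacerbation_mean=exa_mean,
        exacerbation_sd=exa_sd,
        outliers=outliers,
    )


def metrics_to_dict(m) -> dict:
    """Flatten a metrics dataclass to a plain dict (None kept for undefined)."""
    from dataclasses import asdict

    return asdict(m)
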