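"""Panel-size robustness of the consensus.

How many raters does a stable consensus need?  For every base panel size s
(from a configured minimum up to one less than the member count), every
size-s subset of the members is taken, its per-case majority consensus
(conservative tie-break) computed, and for each member outside the subset
the fraction of cases whose consensus changes when that member's votes are
added.  The change fractions are averaged over the added members, and the
mean / max / min over all size-s subsets is reported.  Enumeration is
exhaustive — with panels of ten or fewer members this is cheap — so the
curve is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .panel import LabelMatrix


class RobustnessError(ValueError):
    pass


@dataclass
class ConvergencePoint:
    panel_size_from: int
    panel_size_to: int
    mean_change: float  # % of cases whose consensus label changes
    max_change: float
    min_change: float


def _majority_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-wise modal category with ties resolved to the highest category.

    ``counts`` is (n_cases, K) with K vote counts per case for categories
    1..K; scanning categories from the top keeps the first (highest) maximum.
    """
    K = counts.shape[1]
    rev = counts[:, ::-1]
    idx = rev.argmax(axis=1)  # first max in reversed order = highest category
    return K - idx


def convergence_curve(
    votes: LabelMatrix | pd.DataFrame,
    min_panel: int = 5,
    column: str = "triage",
    algo_votes: pd.Series | None = None,
) -> list[ConvergencePoint]:
    """Consensus change-rate curve over growing panel sizes.

    ``votes`` may be a LabelMatrix (the ``column`` label is used) or a
    cases x members integer frame.  ``algo_votes`` (case-indexed) adds the
    algorithm as one more member of the pool.
    """
    if min_panel < 1:
        raise RobustnessError("invalid panel size")
    table = votes.pivot(column) if isinstance(votes, LabelMatrix) else votes.copy()
    if algo_votes is not None:
        table = table.join(algo_votes.rename("__algo__"))
    members = list(table.columns)
    if len(members) < min_panel + 1:
        raise RobustnessError("need at least min_panel + 1 members")

    V = table.to_numpy(int)  # cases x members
    K = int(V.max())
    n_cases, M = V.shape
    # one-hot vote counts per member: member -> (cases, K)
    onehot = np.stack([np.eye(K, dtype=int)[V[:, m] - 1] for m in range(M)])

    points = []
    for s in range(min_panel, M):
        per_subset = []
        for subset in combinations(range(M), s):
            counts = onehot[list(subset)].sum(axis=0)
            base = _majority_matrix(counts)
            others = [m for m in range(M) if m not in subset]
            fracs = []
            for m in others:
                grown = _majority_matrix(counts + onehot[m])
                fracs.append(float((grown != base).mean()))
            per_subset.append(100.0 * float(np.mean(fracs)))
        points.append(
            ConvergencePoint(
                panel_size_from=s,
                panel_size_to=s + 1,
                mean_change=float(np.mean(per_subset)),
                max_change=float(np.max(per_subset)),
                min_change=float(np.min(per_subset)),
            )
        )
    return points


def curve_frame(points: list[ConvergencePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                panel_size_from=p.panel_size_from,
                panel_size_to=p.panel_size_to,
                mean_change=p.mean_change,
                max_change=p.max_change,
                min_change=p.min_change,
            )
            for p in points
        ]
    )
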