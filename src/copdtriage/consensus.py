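"""Panel consensus with the conservative tie-break.

The consensus label of a case is the modal vote; when several categories tie
for the maximal count, the *highest* (most conservative, i.e. safest) one is
taken — ER beats Doc beats Plan beats Ok, and "exacerbation: yes" beats
"no".  Three membership scenarios are supported for scoring a member against
the consensus:

* ``ALL_MEMBERS`` — the algorithm's votes join the physicians' in every
  per-case consensus;
* ``EXCLUDE_ALGO`` — physicians only;
* ``LEAVE_SELF_OUT`` — the consensus for the member being scored is
  recomputed with that member's own votes removed (algorithm votes may still
  be included by passing them explicitly).
"""

from __future__ import annotations

from collections import Counter
from enum import Enum

import pandas as pd

from .panel import LabelMatrix


class ConsensusError(ValueError):
    pass


class ConsensusScenario(Enum):
    ALL_MEMBERS = "all_members"
    EXCLUDE_ALGO = "exclude_algo"
    LEAVE_SELF_OUT = "leave_self_out"


def majority_vote(votes) -> int:
    """Modal category; ties resolve to the highest (most conservative)."""
    votes = list(votes)
    if not votes:
        raise ConsensusError("no votes")
    counts = Counter(votes)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def _consensus_frame(pivots: dict[str, pd.DataFrame]) -> pd.DataFrame:
    out = {}
    for name, table in pivots.items():
        out[name] = table.apply(lambda row: majority_vote(row.dropna().astype(int)), axis=1)
    df = pd.DataFrame(out)
    df.index.name = "case_id"
    return df


def consensus_labels(
    labels: LabelMatrix,
    scenario: ConsensusScenario = ConsensusScenario.EXCLUDE_ALGO,
    scored_member: str | None = None,
    algo_votes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case consensus triage and exacerbation under a membership scenario.

    ``algo_votes`` is a case-indexed frame with columns ``triage`` and
    ``exacerbation``.  Returns a case-indexed frame with columns
    ``consensus_triage`` and ``consensus_exacerbation``.
    """
    tri = labels.pivot("triage")
    exa = labels.pivot("exacerbation")

    if scenario is ConsensusScenario.ALL_MEMBERS:
        if algo_votes is None:
            raise ConsensusError("ALL_MEMBERS requires algo_votes")
        tri = tri.join(algo_votes["triage"].rename("__algo__"))
        exa = exa.join(algo_votes["exacerbation"].rename("__algo__"))
    elif scenario is ConsensusScenario.LEAVE_SELF_OUT:
        if scored_member is None:
            raise ConsensusError("member required for LEAVE_SELF_OUT")
        if scored_member in tri.columns:
            tri = tri.drop(columns=[scored_member])
            exa = exa.drop(columns=[scored_member])
        elif scored_member != "__algo__":
            raise ConsensusError(f"unknown member {scored_member!r}")
        if algo_votes is not None and scored_member != "__algo__":
            tri = tri.join(algo_votes["triage"].rename("__algo__"))
            exa = exa.join(algo_votes["exacerbation"].rename("__algo__"))
    elif scenario is not ConsensusScenario.EXCLUDE_ALGO:
        raise ConsensusError(f"unknown scenario {scenario!r}")

    df = _consensus_frame({"consensus_triage": tri, "consensus_exacerbation": exa})
    return df


def member_agreement(
    labels: LabelMatrix,
    scenario: ConsensusScenario,
    algo_votes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent agreement of every member with the scenario's consensus.

    Under ``LEAVE_SELF_OUT`` the consensus is recomputed per member; under
    the other scenarios a single consensus is scored against.  The algorithm
    (when its votes are supplied) is scored as member ``__algo__``.
    """
    tri = labels.pivot("triage")
    exa = labels.pivot("exacerbation")
    members = list(tri.columns)
    if algo_votes is not None:
        members.append("__algo__")

    rows = []
    for member in members:
        if scenario is ConsensusScenario.LEAVE_SELF_OUT:
            cons = consensus_labels(labels, scenario, scored_member=member, algo_votes=algo_votes)
        else:
            cons = consensus_labels(labels, scenario, algo_votes=algo_votes)
        if member == "__algo__":
            mt = algo_votes["triage"]
            me = algo_votes["exacerbation"]
        else:
            mt, me = tri[member], exa[member]
        rows.append(
            dict(
                member=member,
                triage_agreement=100.0 * float((mt == cons["consensus_triage"]).mean()),
                exacerbation_agreement=100.0
                * float((me == cons["consensus_exacerbation"]).mean()),
            )
        )
    return pd.DataFrame(rows).set_index("member")
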