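"""Stay-probability analysis and strategy read-outs.

Stay behavior — repeating the previous first-stage choice — is scored in
the 2x2 design of previous transition (common, rare) by previous outcome
(reward, no reward). A purely model-free learner shows a main effect of
previous reward; a model-based learner shows the transition-by-reward
interaction. Two difference scores summarize this per session:

    mf_diff = (common_rewarded + rare_rewarded)
            - (common_unrewarded + rare_unrewarded)
    mb_diff = (common_rewarded + rare_unrewarded)
            - (rare_rewarded + common_unrewarded)

using the four cell stay probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .task import Session

CELLS = ("common_rewarded", "common_unrewarded", "rare_rewarded", "rare_unrewarded")

#: Reward paid per rewarded trial, in euro.
REWARD_EUR = 0.10


@dataclass
class StayTable:
    """Stay counts and probabilities per (previous transition, previous reward)."""

    stays: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CELLS})
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CELLS})

    def stay_prob(self, cell: str) -> Optional[float]:
        """Stay probability for a cell; None when the cell has no pairs."""
        n = self.counts[cell]
        if n == 0:
            return None
        return self.stays[cell] / n

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict[str, Optional[float]]:
        return {c: self.stay_prob(c) for c in CELLS}


@dataclass(frozen=True)
class StrategyScores:
    """Model-based and model-free stay-probability difference scores."""

    mb_diff: Optional[float]
    mf_diff: Optional[float]


def compute_stay_table(session: Session) -> StayTable:
    """Score consecutive completed-trial pairs of a session.

    Pair (t-1, t) is classified by the transition type and reward of
    trial t-1; "stay" means the first-stage action repeats at t. Pairs
    separated by an aborted trial are dropped, and the session's first
    trial is never a stay target.
    """
    completed = [
        t for t in session.trials if not t.aborted
    ]
    if len(completed) < 2:
        raise ValueError("need at least 2 completed trials")
    table = StayTable()
    for prev, cur in zip(session.trials, session.trials[1:]):
        if prev.aborted or cur.aborted:
            continue
        cell = "{}_{}".format(
            prev.transition_type, "rewarded" if prev.reward else "unrewarded"
        )
        table.counts[cell] += 1
        table.stays[cell] += int(cur.first_action == prev.first_action)
    return table


def strategy_scores(table: StayTable) -> StrategyScores:
    """Difference scores from the four stay probabilities.

    Any undefined (zero-count) cell propagates to undefined scores
    rather than being treated as zero.
    """
    p = table.as_dict()
    if any(v is None for v in p.values()):
        return StrategyScores(mb_diff=None, mf_diff=None)
    cr, cn = p["common_rewarded"], p["common_unrewarded"]
    rr, rn = p["rare_rewarded"], p["rare_unrewarded"]
    return StrategyScores(
        mb_diff=(cr + rn) - (rr + cn),
        mf_diff=(cr + rr) - (cn + rn),
    )


def mean_payoff(session: Session) -> float:
    """Session earnings in euro: 0.10 EUR per rewarded trial."""
    return REWARD_EUR * sum(
        1 for t in session.trials if not t.aborted and t.reward
    )


def session_scores(session: Session) -> dict:
    """Convenience bundle: stay table cells, scores, payoff for one session."""
    table = compute_stay_table(session)
    scores = strategy_scores(table)
    out = {
        "subject_id": session.subject_id,
        "group_label": session.group_label,
        "condition": session.condition,
        "stay_cr": table.stay_prob("common_rewarded"),
        "stay_cn": table.stay_prob("common_unrewarded"),
        "stay_rr": table.stay_prob("rare_rewarded"),
        "stay_rn": table.stay_prob("rare_unrewarded"),
        "mb_diff": scores.mb_diff,
        "mf_diff": scores.mf_diff,
        "payoff_eur": mean_payoff(session),
    }
    return out


def cohort_summary(
    scores: Sequence[tuple[str, str, StrategyScores, float]]
) -> pd.DataFrame:
    """Mean and standard error of the scores per group x condition.

    ``scores`` rows are (group_label, condition, StrategyScores, payoff_eur).
    Single-observation cells report SE = 0.
    """
    if not scores:
        raise ValueError("no scores given")
    rows = [
        {
            "group_label": g,
            "condition": c,
            "mb_diff": s.mb_diff,
            "mf_diff": s.mf_diff,
            "payoff_eur": p,
        }
        for g, c, s, p in scores
    ]
    df = pd.DataFrame(rows)
    grouped = df.groupby(["group_label", "condition"])[
        ["mb_diff", "mf_diff", "payoff_eur"]
    ]
    mean = grouped.mean()
    sem = grouped.sem(ddof=1).fillna(0.0)
    out = mean.join(sem, lsuffix="_mean", rsuffix="_se")
    return out.reset_index()
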