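"""Hybrid model-based / model-free reinforcement-learning agent.

The agent values first-stage actions with a weighted mixture of two
systems. The model-free system learns state-action values by SARSA(λ)
temporal-difference updates from experienced rewards. The model-based
system computes first-stage values prospectively through the Bellman
equation, combining the known 70/30 transition probabilities with the
best second-stage model-free value in each state. A single weight
ω ∈ [0, 1] mixes the two (ω = 0 purely model-free, ω = 1 purely
model-based). Choices are softmax in the net values, with a
perseveration bonus π for repeating the previous first-stage action.

Eligibility traces act only within a trial: the second-stage reward
prediction error is passed back to the first-stage value with weight λ
in the same trial and never carries over to later trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .task import (
    RewardProbabilityTrajectory,
    Session,
    TransitionStructure,
    TrialRecord,
    sample_reward,
    sample_transition,
)

#: Canonical parameter order used by array conversions and the optimizer.
PARAM_ORDER = ("alpha1", "alpha2", "beta1", "beta2", "lam", "pi", "omega")

#: Key names used in external config files ("lambda" instead of "lam").
EXTERNAL_KEYS = ("alpha1", "alpha2", "beta1", "beta2", "lambda", "pi", "omega")


@dataclass(frozen=True)
class AgentParameters:
    """The seven free parameters of the hybrid model.

    alpha1, alpha2 : learning rates at the first and second stage, in [0, 1]
    beta1, beta2   : inverse softmax temperatures per stage, >= 0
    lam            : within-trial eligibility-trace weight λ, in [0, 1]
    pi             : perseveration bonus π (negative values favour switching)
    omega          : model-based weight ω, in [0, 1]
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    lam: float
    pi: float
    omega: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta1", "beta2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "AgentParameters":
        return cls(**dict(zip(PARAM_ORDER, map(float, theta))))

    def to_dict(self) -> dict[str, float]:
        return {ext: float(getattr(self, internal))
                for ext, internal in zip(EXTERNAL_KEYS, PARAM_ORDER)}

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParameters":
        vals = {internal: float(d[ext])
                for ext, internal in zip(EXTERNAL_KEYS, PARAM_ORDER)}
        return cls(**vals)


@dataclass
class ValueState:
    """The agent's learned quantities carried across trials."""

    q1_mf: np.ndarray  # shape (2,): first-stage model-free values
    q2_mf: np.ndarray  # shape (2, 2): second-stage values per (state, action)
    prev_first_action: Optional[int] = None

    @classmethod
    def initial(cls, q_init: float = 0.5) -> "ValueState":
        return cls(q1_mf=np.full(2, q_init), q2_mf=np.full((2, 2), q_init))

    def copy(self) -> "ValueState":
        return ValueState(
            q1_mf=self.q1_mf.copy(),
            q2_mf=self.q2_mf.copy(),
            prev_first_action=self.prev_first_action,
        )


@dataclass(frozen=True)
class TrialOutcome:
    """The four events of one completed trial, as consumed by the update."""

    first_action: int
    second_state: int
    second_action: int
    reward: int


def model_based_values(
    q2_mf: np.ndarray, structure: TransitionStructure
) -> np.ndarray:
    """Bellman first-stage values from second-stage model-free values.

    Q_MB(a) = P(common) * max_a' Q2[dest_common(a), a']
            + P(rare)   * max_a' Q2[dest_rare(a), a']
    """
    state_max = np.max(q2_mf, axis=1)
    out = np.empty(2)
    for a in (0, 1):
        common = structure.common_destination[a]
        out[a] = (
            structure.common_prob * state_max[common]
            + structure.rare_prob * state_max[1 - common]
        )
    return out


def net_first_stage_values(
    q1_mb: np.ndarray, q1_mf: np.ndarray, omega: float
) -> np.ndarray:
    """ω-weighted mixture of model-based and model-free first-stage values."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    return omega * np.asarray(q1_mb) + (1.0 - omega) * np.asarray(q1_mf)


def _softmax2(x0: float, x1: float) -> np.ndarray:
    # two-option softmax via the logistic of the value difference
    p0 = 1.0 / (1.0 + math.exp(x1 - x0))
    return np.array([p0, 1.0 - p0])


def first_stage_choice_probs(
    q_net: np.ndarray, beta1: float, pi: float, prev_action: Optional[int]
) -> np.ndarray:
    """Softmax over β₁·[Q_net(a) + π·rep(a)].

    rep(a) is 1 for the action chosen on the previous trial and 0
    otherwise; on the first trial (no previous action) rep is 0 for both.
    """
    if beta1 < 0:
        raise ValueError("beta1 must be non-negative")
    rep = np.zeros(2)
    if prev_action is not None:
        rep[prev_action] = 1.0
    x = beta1 * (np.asarray(q_net) + pi * rep)
    return _softmax2(x[0], x[1])


def second_stage_choice_probs(q2_state: np.ndarray, beta2: float) -> np.ndarray:
    """Softmax over β₂·Q2 for the two actions of one second-stage state."""
    if beta2 < 0:
        raise ValueError("beta2 must be non-negative")
    x = beta2 * np.asarray(q2_state)
    return _softmax2(x[0], x[1])


def update_values(
    state: ValueState, outcome: TrialOutcome, params: AgentParameters
) -> ValueState:
    """Apply one trial's SARSA(λ) updates, returning a new ValueState.

    Both first-stage correction terms use the second-stage value as it
    stood *before* its within-trial update. Only the chosen entries are
    touched; unchosen values are left as they are.
    """
    new = state.copy()
    a1, s2, a2, r = (
        outcome.first_action,
        outcome.second_state,
        outcome.second_action,
        float(outcome.reward),
    )
    q2_old = new.q2_mf[s2, a2]
    delta2 = r - q2_old
    new.q2_mf[s2, a2] = q2_old + params.alpha2 * delta2
    new.q1_mf[a1] = (
        new.q1_mf[a1]
        + params.alpha1 * (q2_old - new.q1_mf[a1])
        + params.alpha1 * params.lam * delta2
    )
    new.prev_first_action = a1
    return new


def act_and_learn(
    state: ValueState,
    params: AgentParameters,
    trajectory: RewardProbabilityTrajectory,
    structure: TransitionStructure,
    t: int,
    rng: np.random.Generator,
) -> tuple[TrialRecord, ValueState]:
    """Generate one trial: choose, transition, choose, collect reward, learn."""
    q1_mb = model_based_values(state.q2_mf, structure)
    q_net = net_first_stage_values(q1_mb, state.q1_mf, params.omega)
    p1 = first_stage_choice_probs(
        q_net, params.beta1, params.pi, state.prev_first_action
    )
    a1 = int(rng.random() >= p1[0])
    s2, transition = sample_transition(a1, structure, rng)
    p2 = second_stage_choice_probs(state.q2_mf[s2], params.beta2)
    a2 = int(rng.random() >= p2[0])
    r = sample_reward(s2, a2, trajectory, t, rng)
    record = TrialRecord(
        trial_index=t,
        first_action=a1,
        transition_type=transition,
        second_state=s2,
        second_action=a2,
        reward=r,
    )
    new_state = update_values(state, TrialOutcome(a1, s2, a2, r), params)
    return record, new_state


def simulate_session(
    params: AgentParameters,
    trajectory: RewardProbabilityTrajectory,
    structure: TransitionStructure = TransitionStructure(),
    rng: Optional[np.random.Generator] = None,
    condition: str = "narrow",
    q_init: float = 0.5,
    subject_id: str = "s0",
    group_label: str = "",
    seed: Optional[int] = None,
) -> Session:
    """Run an agent through a full session of the given trajectory."""
    if rng is None:
        rng = np.random.default_rng(seed)
    state = ValueState.initial(q_init)
    trials: list[TrialRecord] = []
    for t in range(trajectory.n_trials):
        record, state = act_and_learn(state, params, trajectory, structure, t, rng)
        trials.append(record)
    return Session(
        condition=condition,
        trials=trials,
        trajectory=trajectory,
        structure=structure,
        seed=seed,
        subject_id=subject_id,
        group_label=group_label,
    )
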