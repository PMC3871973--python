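"""Two-stage Markov decision task environment.

The task has three states: a first-stage state A with two actions, and two
second-stage states B and C, each with two actions. A first-stage choice
leads to one second-stage state with high ("common", 70%) probability and
to the other with low ("rare", 30%) probability. Each second-stage action
pays a unit reward with a probability that drifts across trials as a
Gaussian random walk confined between reflecting boundaries.

States are coded B=0, C=1; actions are 0/1; trials are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CONDITIONS = ("narrow", "wide")

#: Flattened (state, action) walk order: (B,0), (B,1), (C,0), (C,1).
WALK_INDEX = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}


@dataclass(frozen=True)
class TransitionStructure:
    """First-stage transition model.

    ``common_destination[a]`` is the second-stage state reached with
    probability ``common_prob`` after first-stage action ``a``; the other
    state is reached with the complementary (rare) probability.
    """

    common_prob: float = 0.7
    common_destination: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if not 0.5 < self.common_prob <= 1.0:
            raise ValueError(
                f"common_prob must exceed rare_prob (got {self.common_prob})"
            )
        if sorted(self.common_destination) != [0, 1]:
            raise ValueError("common_destination must be a bijection on {0, 1}")

    @property
    def rare_prob(self) -> float:
        return 1.0 - self.common_prob

    def rare_destination(self, action: int) -> int:
        return 1 - self.common_destination[action]


@dataclass(frozen=True)
class RandomWalkConfig:
    """Configuration of the four second-stage reward-probability walks."""

    lower_bound: float
    upper_bound: float
    step_sd: float = 0.025
    n_options: int = 4
    init_mode: str = "uniform_random"
    init_values: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower_bound < self.upper_bound <= 1.0:
            raise ValueError("need 0 <= lower_bound < upper_bound <= 1")
        if self.step_sd <= 0:
            raise ValueError("step_sd must be positive")
        if self.init_mode not in ("uniform_random", "fixed_values"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "fixed_values":
            if self.init_values is None or len(self.init_values) != self.n_options:
                raise ValueError("fixed_values init requires n_options init_values")
            for v in self.init_values:
                if not self.lower_bound <= v <= self.upper_bound:
                    raise ValueError("init_values must lie within the bounds")

    @classmethod
    def narrow(cls, **kw) -> "RandomWalkConfig":
        return cls(lower_bound=0.25, upper_bound=0.75, **kw)

    @classmethod
    def wide(cls, **kw) -> "RandomWalkConfig":
        return cls(lower_bound=0.0, upper_bound=1.0, **kw)

    @classmethod
    def for_condition(cls, condition: str, **kw) -> "RandomWalkConfig":
        if condition == "narrow":
            return cls.narrow(**kw)
        if condition == "wide":
            return cls.wide(**kw)
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class RewardProbabilityTrajectory:
    """Reward probabilities per trial for the four (state, action) options.

    ``probs`` has shape (n_trials, 4) in the order (B,0), (B,1), (C,0), (C,1).
    ``reflected[t, j]`` marks that the step into row ``t`` of walk ``j``
    required boundary reflection (row 0 is all False); interior steps are
    those where the raw Gaussian proposal already lay within the bounds.
    """

    probs: np.ndarray
    config: RandomWalkConfig
    reflected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != self.config.n_options:
            raise ValueError("probs must have shape (n_trials, n_options)")
        if self.reflected is None:
            self.reflected = np.zeros(self.probs.shape, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, state: int, action: int, t: int) -> float:
        return float(self.probs[t, WALK_INDEX[(state, action)]])


@dataclass
class TrialRecord:
    """One trial's observable events; missing fields mark an aborted trial."""

    trial_index: int
    first_action: Optional[int]
    transition_type: Optional[str]
    second_state: Optional[int]
    second_action: Optional[int]
    reward: Optional[int]
    aborted: bool = False

    def __post_init__(self) -> None:
        missing = self.first_action is None or self.second_action is None
        if missing != self.aborted:
            raise ValueError("aborted flag inconsistent with missing responses")


@dataclass
class Session:
    """One subject's run of a single random-walk condition."""

    condition: str
    trials: list[TrialRecord]
    trajectory: Optional[RewardProbabilityTrajectory]
    structure: TransitionStructure
    seed: Optional[int] = None
    subject_id: str = "s0"
    group_label: str = ""

    def completed_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.aborted]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def reflect_into_bounds(x: float, lower: float, upper: float) -> float:
    """Mirror a proposal back into [lower, upper], re-applying as needed."""
    while x < lower or x > upper:
        if x > upper:
            x = 2.0 * upper - x
        else:
            x = 2.0 * lower - x
    return x


def step_random_walk(
    p: float, config: RandomWalkConfig, rng: np.random.Generator
) -> float:
    """Advance one reward probability by a reflected Gaussian step."""
    if not config.lower_bound <= p <= config.upper_bound:
        raise ValueError(f"p={p} outside [{config.lower_bound}, {config.upper_bound}]")
    proposal = p + rng.normal(0.0, config.step_sd)
    return reflect_into_bounds(proposal, config.lower_bound, config.upper_bound)


def generate_walks(
    config: RandomWalkConfig, n_trials: int, rng: np.random.Generator
) -> RewardProbabilityTrajectory:
    """Generate the four independent reward-probability walks.

    Each walk starts uniformly within the bounds (or at ``init_values``) and
    advances by i.i.d. Gaussian steps of SD ``step_sd`` with mirror
    reflection at the boundaries.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = config.n_options
    probs = np.empty((n_trials, k))
    reflected = np.zeros((n_trials, k), dtype=bool)
    if config.init_mode == "fixed_values":
        probs[0] = config.init_values
    else:
        probs[0] = rng.uniform(config.lower_bound, config.upper_bound, size=k)
    lo, hi = config.lower_bound, config.upper_bound
    for t in range(1, n_trials):
        noise = rng.normal(0.0, config.step_sd, size=k)
        for j in range(k):
            proposal = probs[t - 1, j] + noise[j]
            if proposal < lo or proposal > hi:
                reflected[t, j] = True
                proposal = reflect_into_bounds(proposal, lo, hi)
            probs[t, j] = proposal
    return RewardProbabilityTrajectory(probs=probs, config=config, reflected=reflected)


def sample_transition(
    first_action: int, structure: TransitionStructure, rng: np.random.Generator
) -> tuple[int, str]:
    """Sample the second-stage state reached after a first-stage action."""
    if first_action not in (0, 1):
        raise ValueError(f"invalid first-stage action {first_action!r}")
    if rng.random() < structure.common_prob:
        return structure.common_destination[first_action], "common"
    return structure.rare_destination(first_action), "rare"


def sample_reward(
    second_state: int,
    second_action: int,
    trajectory: RewardProbabilityTrajectory,
    t: int,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward draw from the option's walk probability at trial t."""
    if not 0 <= t < trajectory.n_trials:
        raise IndexError(f"trial index {t} out of range")
    if (second_state, second_action) not in WALK_INDEX:
        raise ValueError("invalid (state, action) pair")
    return int(rng.random() < trajectory.prob(second_state, second_action, t))


def interior_increments(trajectory: RewardProbabilityTrajectory) -> np.ndarray:
    """Per-trial walk increments for steps where no reflection occurred."""
    deltas = np.diff(trajectory.probs, axis=0)
    mask = ~trajectory.reflected[1:]
    return deltas[mask]
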