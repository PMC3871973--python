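"""Reading and writing the package's delimited-text formats.

Session logs are plain CSV, one row per trial:

    subject_id, group_label, condition, trial_index, first_action,
    transition_type, second_state, second_action, reward, aborted

Second-stage states are written as the letters B/C; missing responses
(aborted trials) are empty fields. Agent parameter sets travel as
JSON/YAML mappings with keys alpha1, alpha2, beta1, beta2, lambda, pi,
omega.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .agent import AgentParameters
from .task import (
    RewardProbabilityTrajectory,
    Session,
    TransitionStructure,
    TrialRecord,
)

SESSION_COLUMNS = [
    "subject_id",
    "group_label",
    "condition",
    "trial_index",
    "first_action",
    "transition_type",
    "second_state",
    "second_action",
    "reward",
    "aborted",
]

_STATE_LETTER = {0: "B", 1: "C"}
_LETTER_STATE = {"B": 0, "C": 1}


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group_label": s.group_label,
                    "condition": s.condition,
                    "trial_index": t.trial_index,
                    "first_action": t.first_action,
                    "transition_type": t.transition_type,
                    "second_state": (
                        None if t.second_state is None else _STATE_LETTER[t.second_state]
                    ),
                    "second_action": t.second_action,
                    "reward": t.reward,
                    "aborted": int(t.aborted),
                }
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions(sessions: Sequence[Session], path: Union[str, Path]) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return int(v)


def frame_to_sessions(
    df: pd.DataFrame, structure: Optional[TransitionStructure] = None
) -> list[Session]:
    """Rebuild Session objects (without trajectories) from a log table."""
    structure = structure or TransitionStructure()
    sessions = []
    for (subject_id, condition), sub in df.groupby(
        ["subject_id", "condition"], sort=False
    ):
        sub = sub.sort_values("trial_index")
        trials = []
        for _, row in sub.iterrows():
            second_state = row["second_state"]
            if isinstance(second_state, str) and second_state in _LETTER_STATE:
                second_state = _LETTER_STATE[second_state]
            else:
                second_state = _opt_int(second_state)
            trials.append(
                TrialRecord(
                    trial_index=int(row["trial_index"]),
                    first_action=_opt_int(row["first_action"]),
                    transition_type=(
                        None
                        if pd.isna(row["transition_type"])
                        else str(row["transition_type"])
                    ),
                    second_state=second_state,
                    second_action=_opt_int(row["second_action"]),
                    reward=_opt_int(row["reward"]),
                    aborted=bool(int(row["aborted"])),
                )
            )
        group = str(sub["group_label"].iloc[0]) if "group_label" in sub else ""
        if group == "nan":
            group = ""
        sessions.append(
            Session(
                condition=str(condition),
                trials=trials,
                trajectory=None,
                structure=structure,
                subject_id=str(subject_id),
                group_label=group,
            )
        )
    return sessions


def read_sessions(
    path: Union[str, Path], structure: Optional[TransitionStructure] = None
) -> list[Session]:
    df = pd.read_csv(path, keep_default_na=True)
    return frame_to_sessions(df, structure)


def write_trajectory(
    trajectory: RewardProbabilityTrajectory, path: Union[str, Path]
) -> None:
    cols = ["p_B0", "p_B1", "p_C0", "p_C1"]
    pd.DataFrame(trajectory.probs, columns=cols).to_csv(path, index=False)


def write_parameters(params: AgentParameters, path: Union[str, Path]) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data))
    else:
        path.write_text(json.dumps(data, indent=2))


def read_parameters(path: Union[str, Path]) -> AgentParameters:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return AgentParameters.from_dict(data)
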