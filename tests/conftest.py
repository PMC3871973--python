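import pytest

from twostep.task import Session, TransitionStructure, TrialRecord


@pytest.fixture
def structure():
    return TransitionStructure()


def build_session(
    first_actions,
    transitions,
    second_actions,
    rewards,
    structure=TransitionStructure(),
    condition="narrow",
    subject_id="s0",
    aborted_at=(),
):
    """Construct a Session from compact event lists.

    Second-stage states are derived from (first_action, transition) so
    records are internally consistent; indices in ``aborted_at`` become
    aborted (response-less) trials.
    """
    trials = []
    for i, (a1, tr, a2, r) in enumerate(
        zip(first_actions, transitions, second_actions, rewards)
    ):
        if i in aborted_at:
            trials.append(
                TrialRecord(
                    trial_index=i,
                    first_action=None,
                    transition_type=None,
                    second_state=None,
                    second_action=None,
                    reward=None,
                    aborted=True,
                )
            )
            continue
        tr = {"C": "common", "R": "rare"}.get(tr, tr)
        if tr == "common":
            s2 = structure.common_destination[a1]
        else:
            s2 = structure.rare_destination(a1)
        trials.append(
            TrialRecord(
                trial_index=i,
                first_action=a1,
                transition_type=tr,
                second_state=s2,
                second_action=a2,
                reward=r,
            )
        )
    return Session(
        condition=condition,
        trials=trials,
        trajectory=None,
        structure=structure,
        subject_id=subject_id,
    )
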