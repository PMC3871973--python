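import math

import numpy as np
import pytest

from conftest import build_session
from twostep.agent import AgentParameters, simulate_session
from twostep.fitting import (
    FitBounds,
    GridSpec,
    fit_session,
    fit_subject,
    grid_search,
    negative_log_likelihood,
    negative_log_likelihood_batch,
    refine_fit,
)
from twostep.task import RandomWalkConfig, generate_walks

PARAMS = AgentParameters(
    alpha1=0.63, alpha2=0.49, beta1=3.91, beta2=4.71, lam=0.23, pi=0.21, omega=0.57
)

SMALL_GRID = GridSpec(
    alpha1=(0.3, 0.7),
    alpha2=(0.3, 0.7),
    beta1=(2.0, 6.0),
    beta2=(2.0, 6.0),
    lam=(0.2, 0.8),
    pi=(0.0, 0.25),
    omega=(0.2, 0.8),
)


def oracle_replay_nll(params, session, q_init=0.5):
    """Independent step-by-step likelihood replay.

    Deliberately written with explicit softmax vectors rather than the
    logistic shortcut of the implementation under test.
    """
    q1 = np.full(2, q_init, dtype=float)
    q2 = np.full((2, 2), q_init, dtype=float)
    prev = None
    st = session.structure
    total = 0.0
    for trial in session.trials:
        if trial.aborted:
            continue
        a1, s2, a2, r = (
            trial.first_action,
            trial.second_state,
            trial.second_action,
            trial.reward,
        )
        q_mb = np.zeros(2)
        for a in (0, 1):
            dest = st.common_destination[a]
            q_mb[a] = st.common_prob * q2[dest].max() + st.rare_prob * q2[
                1 - dest
            ].max()
        q_net = params.omega * q_mb + (1 - params.omega) * q1
        rep = np.zeros(2)
        if prev is not None:
            rep[prev] = 1.0
        z1 = np.exp(params.beta1 * (q_net + params.pi * rep))
        total -= math.log(z1[a1] / z1.sum())
        z2 = np.exp(params.beta2 * q2[s2])
        total -= math.log(z2[a2] / z2.sum())
        old = q2[s2, a2]
        q2[s2, a2] = old + params.alpha2 * (r - old)
        q1[a1] = q1[a1] + params.alpha1 * (old - q1[a1]) + params.alpha1 * params.lam * (
            r - old
        )
        prev = a1
    return total


THREE_TRIALS = dict(
    first_actions=[0, 1, 0],
    transitions=["C", "R", "C"],
    second_actions=[0, 1, 1],
    rewards=[1, 0, 1],
)


class TestLikelihood:
    def test_matches_independent_replay_on_three_trials(self):
        session = build_session(**THREE_TRIALS)
        ours = negative_log_likelihood(PARAMS, session)
        theirs = oracle_replay_nll(PARAMS, session)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_matches_independent_replay_on_simulated_session(self):
        rng = np.random.default_rng(12)
        traj = generate_walks(RandomWalkConfig.narrow(), 100, rng)
        session = simulate_session(PARAMS, traj, rng=rng)
        assert negative_log_likelihood(PARAMS, session) == pytest.approx(
            oracle_replay_nll(PARAMS, session), abs=1e-10
        )

    @pytest.mark.parametrize("n_trials", [1, 3, 10])
    def test_zero_beta_closed_form(self, n_trials):
        # every choice probability is 1/2, so NLL = 2 T ln 2 exactly
        rng = np.random.default_rng(n_trials)
        session = build_session(
            first_actions=list(rng.integers(2, size=n_trials)),
            transitions=list(rng.choice(["C", "R"], size=n_trials)),
            second_actions=list(rng.integers(2, size=n_trials)),
            rewards=list(rng.integers(2, size=n_trials)),
        )
        params = AgentParameters(0.5, 0.5, 0.0, 0.0, 0.5, 0.3, 0.5)
        assert negative_log_likelihood(params, session) == pytest.approx(
            2 * n_trials * math.log(2), abs=1e-12
        )

    def test_single_trial_symmetric_start(self):
        # all values equal before any update: both stages are coin flips
        session = build_session(
            first_actions=[0], transitions=["C"], second_actions=[0], rewards=[1]
        )
        params = AgentParameters(0.9, 0.2, 2.0, 2.0, 0.4, 0.0, 0.5)
        assert negative_log_likelihood(params, session) == pytest.approx(
            2 * math.log(2), abs=1e-12
        )

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(21)
        traj = generate_walks(RandomWalkConfig.wide(), 80, rng)
        session = simulate_session(PARAMS, traj, rng=rng)
        thetas = np.column_stack(
            [
                rng.uniform(0, 1, 20),
                rng.uniform(0, 1, 20),
                rng.uniform(0, 15, 20),
                rng.uniform(0, 15, 20),
                rng.uniform(0, 1, 20),
                rng.uniform(-2, 2, 20),
                rng.uniform(0, 1, 20),
            ]
        )
        batch = negative_log_likelihood_batch(thetas, session)
        scalar = [
            negative_log_likelihood(AgentParameters.from_array(t), session)
            for t in thetas
        ]
        assert batch == pytest.approx(scalar, abs=1e-9)

    def test_trial_index_metadata_is_irrelevant(self):
        a = build_session(**THREE_TRIALS)
        b = build_session(**THREE_TRIALS)
        for t in b.trials:
            t.trial_index += 100
        assert negative_log_likelihood(PARAMS, a) == negative_log_likelihood(
            PARAMS, b
        )

    def test_aborted_trials_skip_likelihood_but_keep_prev_action(self):
        with_abort = build_session(
            first_actions=[0, 0, 1, 0],
            transitions=["C", "C", "R", "C"],
            second_actions=[0, 0, 1, 1],
            rewards=[1, 1, 0, 1],
            aborted_at=(1,),
        )
        equivalent = build_session(
            first_actions=[0, 1, 0],
            transitions=["C", "R", "C"],
            second_actions=[0, 1, 1],
            rewards=[1, 0, 1],
        )
        assert negative_log_likelihood(PARAMS, with_abort) == pytest.approx(
            negative_log_likelihood(PARAMS, equivalent), abs=1e-12
        )

    def test_empty_session_rejected(self):
        session = build_session(
            first_actions=[0], transitions=["C"], second_actions=[0], rewards=[1],
            aborted_at=(0,),
        )
        with pytest.raises(ValueError):
            negative_log_likelihood(PARAMS, session)


class TestGridSearch:
    def test_singleton_grid_matches_direct_evaluation(self):
        session = build_session(**THREE_TRIALS)
        grid = GridSpec(
            alpha1=(0.63,), alpha2=(0.49,), beta1=(3.91,), beta2=(4.71,),
            lam=(0.23,), pi=(0.21,), omega=(0.57,),
        )
        ranked = grid_search(session, grid)
        assert len(ranked) == 1
        assert ranked[0][1] == pytest.approx(
            negative_log_likelihood(PARAMS, session), abs=1e-9
        )

    def test_output_sorted_ascending(self):
        session = build_session(**THREE_TRIALS)
        ranked = grid_search(session, SMALL_GRID)
        nlls = [v for _, v in ranked]
        assert nlls == sorted(nlls)

    def test_generating_point_ranks_highly(self):
        true = AgentParameters(0.7, 0.7, 6.0, 6.0, 0.2, 0.25, 0.8)
        rng = np.random.default_rng(33)
        traj = generate_walks(RandomWalkConfig.wide(), 201, rng)
        session = simulate_session(true, traj, rng=rng)
        ranked = grid_search(session, SMALL_GRID)
        key = tuple(true.as_array())
        rank = next(
            i for i, (p, _) in enumerate(ranked) if tuple(p.as_array()) == key
        )
        assert rank < len(ranked) / 10


class TestRefinement:
    def _simulated(self, seed=3, n=201):
        rng = np.random.default_rng(seed)
        traj = generate_walks(RandomWalkConfig.narrow(), n, rng)
        return simulate_session(PARAMS, traj, rng=rng)

    def test_descent_from_truth(self):
        session = self._simulated()
        res = refine_fit(session, [PARAMS])
        assert res.neg_log_likelihood <= negative_log_likelihood(PARAMS, session)
        lo, hi = zip(*FitBounds().as_list())
        theta = res.params.as_array()
        assert np.all(theta >= lo) and np.all(theta <= hi)

    def test_single_trial_session_is_handled(self):
        session = build_session(
            first_actions=[1], transitions=["R"], second_actions=[0], rewards=[0]
        )
        res = refine_fit(session, [PARAMS])
        assert np.isfinite(res.neg_log_likelihood)
        assert res.n_trials_used == 1

    def test_fit_session_uses_requested_starts(self):
        session = self._simulated(seed=8, n=60)
        res = fit_session(session, SMALL_GRID, n_starts=12)
        assert res.n_starts == 12
        assert res.neg_log_likelihood <= grid_search(session, SMALL_GRID)[0][1]

    def test_conditions_fit_independently(self):
        rng = np.random.default_rng(17)
        narrow = simulate_session(
            PARAMS, generate_walks(RandomWalkConfig.narrow(), 60, rng), rng=rng,
            condition="narrow",
        )
        wide = simulate_session(
            PARAMS, generate_walks(RandomWalkConfig.wide(), 60, rng), rng=rng,
            condition="wide",
        )
        r_nw = fit_subject(narrow, wide, SMALL_GRID, n_starts=4)
        r_wn = fit_subject(wide, narrow, SMALL_GRID, n_starts=4)
        assert r_nw[0].neg_log_likelihood == pytest.approx(
            r_wn[1].neg_log_likelihood, abs=1e-9
        )
        assert r_nw[1].neg_log_likelihood == pytest.approx(
            r_wn[0].neg_log_likelihood, abs=1e-9
        )
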