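"""Maximum-likelihood estimation of the hybrid agent's parameters.

Fitting replays a session trial by trial: at each completed trial the
likelihood of the observed first- and second-stage choices is evaluated
under the current value state, and the values are then updated with the
observed outcome. The negative log-likelihood (NLL) is minimized per
session by a coarse factorial grid search followed by bounded local
refinement (L-BFGS-B) from the best grid points.

Two likelihood paths are provided: a scalar replay used by the local
optimizer, and a batch replay vectorized over parameter sets used by the
grid search. They implement the identical recursion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .agent import PARAM_ORDER, AgentParameters
from .task import Session

#: Hard cap on factorial grid size, to keep grid search desk-scale.
GRID_CAP = 200_000


@dataclass(frozen=True)
class GridSpec:
    """Grid values per parameter for the coarse search stage."""

    alpha1: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    alpha2: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    beta1: tuple = (1.0, 3.0, 5.0, 8.0, 12.0)
    beta2: tuple = (1.0, 3.0, 5.0, 8.0, 12.0)
    lam: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    pi: tuple = (-0.5, 0.0, 0.25, 0.5)
    omega: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)

    @property
    def size(self) -> int:
        n = 1
        for name in PARAM_ORDER:
            n *= len(getattr(self, name))
        return n

    def points(self) -> np.ndarray:
        """All grid points as an array of shape (n_points, 7)."""
        if self.size > GRID_CAP:
            raise ValueError(f"grid has {self.size} points (cap {GRID_CAP})")
        axes = [getattr(self, name) for name in PARAM_ORDER]
        return np.array(list(itertools.product(*axes)), dtype=float)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the local refinement stage."""

    alpha1: tuple = (0.0, 1.0)
    alpha2: tuple = (0.0, 1.0)
    beta1: tuple = (0.0, 20.0)
    beta2: tuple = (0.0, 20.0)
    lam: tuple = (0.0, 1.0)
    pi: tuple = (-5.0, 5.0)
    omega: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    def as_list(self) -> list[tuple[float, float]]:
        return [getattr(self, name) for name in PARAM_ORDER]

    def contains(self, theta: np.ndarray) -> bool:
        return all(
            lo <= v <= hi for v, (lo, hi) in zip(theta, self.as_list())
        )


@dataclass
class FitResult:
    """Outcome of fitting one session."""

    params: AgentParameters
    neg_log_likelihood: float
    n_trials_used: int
    n_starts: int
    converged: bool
    condition: str = ""
    subject_id: str = ""


def _trial_arrays(session: Session) -> tuple[np.ndarray, ...]:
    completed = session.completed_trials()
    if not completed:
        raise ValueError("session has no completed trials")
    a1 = np.array([t.first_action for t in completed], dtype=np.intp)
    s2 = np.array([t.second_state for t in completed], dtype=np.intp)
    a2 = np.array([t.second_action for t in completed], dtype=np.intp)
    r = np.array([t.reward for t in completed], dtype=float)
    return a1, s2, a2, r


def negative_log_likelihood(
    params: AgentParameters,
    session: Session,
    q_init: float = 0.5,
) -> float:
    """NLL (nats) of a session's completed choices under the hybrid model.

    Aborted trials contribute no likelihood terms and no value updates;
    the previous-action memory for the perseveration bonus is retained
    across them.
    """
    a1s, s2s, a2s, rs = _trial_arrays(session)
    st = session.structure
    cp, rp = st.common_prob, st.rare_prob
    dest0 = st.common_destination[0]
    alpha1, alpha2 = params.alpha1, params.alpha2
    beta1, beta2 = params.beta1, params.beta2
    lam, pi, omega = params.lam, params.pi, params.omega

    q1 = [q_init, q_init]
    q2 = [[q_init, q_init], [q_init, q_init]]
    prev: Optional[int] = None
    nll = 0.0
    exp = math.exp
    log1p = math.log1p
    for a1, s2, a2, r in zip(a1s, s2s, a2s, rs):
        mb = max(q2[0][0], q2[0][1])
        mc = max(q2[1][0], q2[1][1])
        if dest0 == 0:
            qmb0 = cp * mb + rp * mc
            qmb1 = rp * mb + cp * mc
        else:
            qmb0 = rp * mb + cp * mc
            qmb1 = cp * mb + rp * mc
        x0 = omega * qmb0 + (1.0 - omega) * q1[0]
        x1 = omega * qmb1 + (1.0 - omega) * q1[1]
        if prev is not None:
            if prev == 0:
                x0 += pi
            else:
                x1 += pi
        # log P(chosen) = -log(1 + exp(-beta1 * (x_chosen - x_other)))
        d1 = beta1 * ((x0 - x1) if a1 == 0 else (x1 - x0))
        nll += log1p(exp(-d1))
        d2 = beta2 * (
            (q2[s2][0] - q2[s2][1]) if a2 == 0 else (q2[s2][1] - q2[s2][0])
        )
        nll += log1p(exp(-d2))
        q2_old = q2[s2][a2]
        delta2 = r - q2_old
        q2[s2][a2] = q2_old + alpha2 * delta2
        q1[a1] += alpha1 * (q2_old - q1[a1]) + alpha1 * lam * delta2
        prev = a1
    return nll


def negative_log_likelihood_batch(
    thetas: np.ndarray,
    session: Session,
    q_init: float = 0.5,
) -> np.ndarray:
    """Vectorized NLL over many parameter sets (shape (K, 7)) at once.

    Implements the same replay as :func:`negative_log_likelihood` with all
    value states carried as arrays over the K parameter sets.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    k = thetas.shape[0]
    alpha1, alpha2, beta1, beta2, lam, pi, omega = thetas.T.copy()
    a1s, s2s, a2s, rs = _trial_arrays(session)
    st = session.structure
    cp, rp = st.common_prob, st.rare_prob
    dest0 = st.common_destination[0]

    q1 = np.full((k, 2), q_init)
    q2 = np.full((k, 2, 2), q_init)
    rows = np.arange(k)
    nll = np.zeros(k)
    prev: Optional[int] = None
    for a1, s2, a2, r in zip(a1s, s2s, a2s, rs):
        state_max = q2.max(axis=2)  # (k, 2)
        if dest0 == 0:
            qmb0 = cp * state_max[:, 0] + rp * state_max[:, 1]
            qmb1 = rp * state_max[:, 0] + cp * state_max[:, 1]
        else:
            qmb0 = rp * state_max[:, 0] + cp * state_max[:, 1]
            qmb1 = cp * state_max[:, 0] + rp * state_max[:, 1]
        x0 = omega * qmb0 + (1.0 - omega) * q1[:, 0]
        x1 = omega * qmb1 + (1.0 - omega) * q1[:, 1]
        if prev is not None:
            if prev == 0:
                x0 = x0 + pi
            else:
                x1 = x1 + pi
        diff1 = (x0 - x1) if a1 == 0 else (x1 - x0)
        nll += np.logaddexp(0.0, -beta1 * diff1)
        q_s2 = q2[:, s2, :]
        diff2 = (
            q_s2[:, 0] - q_s2[:, 1] if a2 == 0 else q_s2[:, 1] - q_s2[:, 0]
        )
        nll += np.logaddexp(0.0, -beta2 * diff2)
        q2_old = q2[rows, s2, a2].copy()
        delta2 = r - q2_old
        q2[rows, s2, a2] = q2_old + alpha2 * delta2
        q1[rows, a1] += alpha1 * (q2_old - q1[rows, a1]) + alpha1 * lam * delta2
        prev = a1
    return nll


def grid_search(
    session: Session,
    grid: Optional[GridSpec] = None,
    q_init: float = 0.5,
) -> list[tuple[AgentParameters, float]]:
    """Evaluate the NLL over the full factorial grid, sorted ascending."""
    grid = grid or GridSpec()
    pts = grid.points()
    if pts.shape[0] == 0:
        raise ValueError("grid is empty")
    nlls = negative_log_likelihood_batch(pts, session, q_init=q_init)
    order = np.argsort(nlls, kind="stable")
    return [
        (AgentParameters.from_array(pts[i]), float(nlls[i])) for i in order
    ]


def refine_fit(
    session: Session,
    starts: Sequence[AgentParameters],
    bounds: Optional[FitBounds] = None,
    q_init: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FitResult:
    """Bounded local refinement from multiple starts; best solution wins."""
    if not starts:
        raise ValueError("need at least one starting point")
    bounds = bounds or FitBounds()
    box = bounds.as_list()
    for s in starts:
        if not bounds.contains(s.as_array()):
            raise ValueError("starting point outside bounds")

    def objective(theta: np.ndarray) -> float:
        return negative_log_likelihood(
            AgentParameters.from_array(np.clip(theta, *zip(*box))),
            session,
            q_init=q_init,
        )

    n_completed = len(session.completed_trials())
    best_theta: Optional[np.ndarray] = None
    best_nll = math.inf
    any_success = False
    for start in starts:
        theta0 = start.as_array()
        f0 = objective(theta0)
        if f0 < best_nll:
            best_nll, best_theta = f0, theta0
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
        )
        if res.success:
            any_success = True
        if res.fun < best_nll:
            best_nll, best_theta = float(res.fun), np.array(res.x)
    theta = np.clip(best_theta, *zip(*box))
    return FitResult(
        params=AgentParameters.from_array(theta),
        neg_log_likelihood=float(best_nll),
        n_trials_used=n_completed,
        n_starts=len(starts),
        converged=any_success,
        condition=session.condition,
        subject_id=session.subject_id,
    )


def fit_session(
    session: Session,
    grid: Optional[GridSpec] = None,
    bounds: Optional[FitBounds] = None,
    n_starts: int = 12,
    q_init: float = 0.5,
) -> FitResult:
    """Grid search, then refine from the best ``n_starts`` grid points."""
    ranked = grid_search(session, grid, q_init=q_init)
    starts = [p for p, _ in ranked[:n_starts]]
    return refine_fit(session, starts, bounds, q_init=q_init)


def fit_subject(
    narrow: Session,
    wide: Session,
    grid: Optional[GridSpec] = None,
    bounds: Optional[FitBounds] = None,
    n_starts: int = 12,
    q_init: float = 0.5,
    pool_starts: bool = False,
) -> tuple[FitResult, FitResult]:
    """Fit both of a subject's sessions independently.

    By default each condition's starting points come from its own grid
    search; with ``pool_starts`` the best candidates of the two
    conditions' grids are pooled and the top ``n_starts`` (by that
    session's own NLL) used for both refinements.
    """
    if not pool_starts:
        return (
            fit_session(narrow, grid, bounds, n_starts, q_init),
            fit_session(wide, grid, bounds, n_starts, q_init),
        )
    results = []
    grids = {s.condition: grid_search(s, grid, q_init=q_init) for s in (narrow, wide)}
    for session in (narrow, wide):
        pooled: dict[tuple, float] = {}
        for cond_ranked in grids.values():
            for p, _ in cond_ranked[:n_starts]:
                key = tuple(p.as_array())
                if key not in pooled:
                    pooled[key] = negative_log_likelihood(p, session, q_init=q_init)
        order = sorted(pooled.items(), key=lambda kv: kv[1])[:n_starts]
        starts = [AgentParameters.from_array(k) for k, _ in order]
        results.append(refine_fit(session, starts, bounds, q_init=q_init))
    return results[0], results[1]
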