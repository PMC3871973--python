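"""Synthetic agent cohorts and parameter-recovery experiments.

Cohorts emulate the study design this package models: each subject runs
201 trials under the narrow (0.25-0.75) and 201 trials under the wide
(0.00-1.00) reward-probability random walk, with one hybrid-agent
parameter vector per subject. Group presets anchor the parameter
distributions at median estimates reported for younger and older adults
(split by working-memory span) performing this task; draws are
independent truncated normals whose spread is derived from the reported
interquartile ranges (sd = IQR / 1.349, the normal-distribution
conversion).

Parameter recovery — simulate agents at known parameters, refit every
session, and correlate true with recovered values — is the package's
main validation surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agent import PARAM_ORDER, AgentParameters, simulate_session
from .fitting import FitBounds, GridSpec, fit_subject
from .task import RandomWalkConfig, Session, TransitionStructure, generate_walks

# Median / 25th / 75th percentile parameter estimates per group and
# random-walk condition, column order (beta1, beta2, alpha1, alpha2,
# lam, pi, omega). Groups: younger/older adults x low/high WM span.
_PRESET_TABLE = {
    "younger_low_narrow": {
        "p25": (2.33, 2.64, 0.24, 0.30, 0.05, 0.10, 0.09),
        "median": (3.91, 4.71, 0.63, 0.49, 0.23, 0.21, 0.57),
        "p75": (8.90, 5.81, 0.85, 0.69, 0.52, 0.42, 0.69),
    },
    "younger_low_wide": {
        "p25": (2.63, 2.83, 0.26, 0.37, 0.03, 0.06, 0.15),
        "median": (5.12, 4.02, 0.52, 0.56, 0.17, 0.16, 0.57),
        "p75": (10.37, 5.21, 0.86, 0.73, 0.62, 0.33, 0.79),
    },
    "younger_high_narrow": {
        "p25": (3.96, 3.67, 0.04, 0.52, 0.00, 0.05, 0.21),
        "median": (7.63, 4.82, 0.39, 0.64, 0.09, 0.11, 0.61),
        "p75": (10.73, 6.04, 0.67, 0.86, 0.89, 0.167, 0.74),
    },
    "younger_high_wide": {
        "p25": (3.46, 6.57, 0.07, 0.39, 0.03, 0.09, 0.34),
        "median": (9.99, 4.59, 0.40, 0.65, 0.15, 0.12, 0.64),
        "p75": (12.39, 3.78, 0.58, 0.85, 0.36, 0.24, 0.78),
    },
    "older_low_narrow": {
        "p25": (2.41, 1.83, 0.18, 0.05, 0.09, 0.09, 0.08),
        "median": (5.83, 2.92, 0.65, 0.33, 0.33, 0.18, 0.24),
        "p75": (9.44, 5.24, 0.95, 0.87, 0.90, 0.27, 0.67),
    },
    "older_low_wide": {
        "p25": (2.64, 1.43, 0.04, 0.08, 0.02, 0.05, 0.15),
        "median": (6.12, 3.36, 0.33, 0.44, 0.33, 0.14, 0.35),
        "p75": (13.54, 4.91, 0.82, 0.88, 0.83, 0.29, 0.49),
    },
    "older_high_narrow": {
        "p25": (2.19, 1.98, 0.04, 0.11, 0.11, 0.04, 0.01),
        "median": (3.62, 2.69, 0.40, 0.56, 0.38, 0.18, 0.15),
        "p75": (6.42, 6.20, 0.84, 0.90, 0.82, 0.35, 0.48),
    },
    "older_high_wide": {
        "p25": (2.52, 2.10, 0.09, 0.06, 0.08, 0.04, 0.01),
        "median": (6.32, 3.75, 0.62, 0.32, 0.49, 0.18, 0.11),
        "p75": (8.98, 5.89, 0.91, 0.69, 0.80, 0.35, 0.48),
    },
}

_TABLE_COLS = ("beta1", "beta2", "alpha1", "alpha2", "lam", "pi", "omega")


def _row_to_params(row: tuple) -> dict[str, float]:
    return dict(zip(_TABLE_COLS, row))


#: Median parameter vectors per preset, as AgentParameters.
MEDIAN_PRESETS: dict[str, AgentParameters] = {
    name: AgentParameters(**_row_to_params(tbl["median"]))
    for name, tbl in _PRESET_TABLE.items()
}


def preset_iqr_sd(name: str) -> dict[str, float]:
    """Per-parameter sd implied by a preset's IQR (sd = IQR / 1.349)."""
    tbl = _PRESET_TABLE[name]
    p25 = _row_to_params(tbl["p25"])
    p75 = _row_to_params(tbl["p75"])
    return {k: abs(p75[k] - p25[k]) / 1.349 for k in _TABLE_COLS}


@dataclass(frozen=True)
class ParameterDistribution:
    """Marginal sampling rule for one parameter: fixed, truncated normal,
    or uniform over the bounds."""

    kind: str  # "fixed" | "truncnorm" | "uniform"
    mean: float = 0.0
    sd: float = 0.0
    bounds: tuple[float, float] = (0.0, 1.0)

    def sample(self, rng: np.random.Generator) -> float:
        lo, hi = self.bounds
        if self.kind == "fixed":
            return self.mean
        if self.kind == "uniform":
            return float(rng.uniform(lo, hi))
        if self.kind == "truncnorm":
            if self.sd <= 0:
                return float(np.clip(self.mean, lo, hi))
            a = (lo - self.mean) / self.sd
            b = (hi - self.mean) / self.sd
            return float(
                stats.truncnorm.rvs(
                    a, b, loc=self.mean, scale=self.sd, random_state=rng
                )
            )
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass
class GroupSpec:
    """How to draw one group's agent parameters."""

    label: str
    distributions: dict[str, ParameterDistribution]
    n_subjects: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        missing = set(PARAM_ORDER) - set(self.distributions)
        if missing:
            raise ValueError(f"missing distributions for {sorted(missing)}")

    @classmethod
    def from_preset(
        cls,
        preset: str,
        n_subjects: int,
        label: Optional[str] = None,
        sd_scale: float = 1.0,
        bounds: Optional[FitBounds] = None,
        overrides: Optional[dict[str, ParameterDistribution]] = None,
    ) -> "GroupSpec":
        """Group anchored at a preset's medians with IQR-derived spread.

        ``sd_scale=0`` fixes every parameter at the preset median;
        ``overrides`` replaces individual marginals (e.g. omega uniform).
        """
        bounds = bounds or FitBounds()
        medians = MEDIAN_PRESETS[preset]
        sds = preset_iqr_sd(preset)
        dists = {}
        for name in PARAM_ORDER:
            mean = getattr(medians, name)
            sd = sds[name] * sd_scale
            kind = "truncnorm" if sd > 0 else "fixed"
            dists[name] = ParameterDistribution(
                kind=kind, mean=mean, sd=sd, bounds=getattr(bounds, name)
            )
        if overrides:
            dists.update(overrides)
        return cls(label=label or preset, distributions=dists, n_subjects=n_subjects)


@dataclass
class CohortSpec:
    """A full synthetic study: groups x the two walk conditions."""

    groups: list[GroupSpec]
    n_trials_per_condition: int = 201
    conditions: tuple[str, ...] = ("narrow", "wide")
    master_seed: int = 0
    structure: TransitionStructure = field(default_factory=TransitionStructure)
    q_init: float = 0.5
    yoked_walks: bool = False

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")


def sample_agent_parameters(
    spec: GroupSpec, rng: np.random.Generator
) -> AgentParameters:
    """Draw one subject's parameter vector from the group's marginals."""
    return AgentParameters(
        **{name: spec.distributions[name].sample(rng) for name in PARAM_ORDER}
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, dict[str, Session]], pd.DataFrame]:
    """Simulate every subject of every group under all conditions.

    Returns ``(sessions, truth)`` where ``sessions[subject_id][condition]``
    is a Session and ``truth`` tabulates each subject's generating
    parameters. Per-subject randomness is spawned from ``master_seed``;
    with ``yoked_walks`` all subjects share each condition's reward
    trajectory (variance-reduction mode).
    """
    sessions: dict[str, dict[str, Session]] = {}
    truth_rows = []
    # One child seed sequence per subject (child 0 reserved for yoked walks).
    n_total = sum(g.n_subjects for g in spec.groups)
    children = np.random.SeedSequence(spec.master_seed).spawn(n_total + 1)
    yoked: dict[str, object] = {}
    if spec.yoked_walks:
        walk_rng = np.random.default_rng(children[0])
        for cond in spec.conditions:
            cfg = RandomWalkConfig.for_condition(cond)
            yoked[cond] = generate_walks(cfg, spec.n_trials_per_condition, walk_rng)
    children = children[1:]
    idx = 0
    for group in spec.groups:
        for i in range(group.n_subjects):
            seq = children[idx]
            idx += 1
            subject_id = f"{group.label}_{i:03d}"
            param_rng, *cond_rngs = [
                np.random.default_rng(s) for s in seq.spawn(1 + len(spec.conditions))
            ]
            params = sample_agent_parameters(group, param_rng)
            sessions[subject_id] = {}
            for cond, rng in zip(spec.conditions, cond_rngs):
                if spec.yoked_walks:
                    trajectory = yoked[cond]
                else:
                    cfg = RandomWalkConfig.for_condition(cond)
                    trajectory = generate_walks(
                        cfg, spec.n_trials_per_condition, rng
                    )
                sessions[subject_id][cond] = simulate_session(
                    params,
                    trajectory,
                    structure=spec.structure,
                    rng=rng,
                    condition=cond,
                    q_init=spec.q_init,
                    subject_id=subject_id,
                    group_label=group.label,
                )
            row = {"subject_id": subject_id, "group_label": group.label}
            row.update({k: getattr(params, k) for k in PARAM_ORDER})
            truth_rows.append(row)
    return sessions, pd.DataFrame(truth_rows)


@dataclass
class RecoveryReport:
    """True-vs-recovered agreement per parameter, plus fit diagnostics."""

    metrics: pd.DataFrame  # index: parameter; columns: correlation, bias, rmse
    group_medians: pd.DataFrame  # recovered medians per group
    n_converged: int
    n_subjects: int
    fits: pd.DataFrame  # per subject x condition fitted parameters
    failed_subjects: list[str] = field(default_factory=list)


def recovery_metrics(truth: pd.DataFrame, recovered: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation, bias and RMSE per parameter.

    Both frames need a ``subject_id`` column and one column per
    parameter; rows are matched by subject. Correlation is NaN when
    either side is constant.
    """
    merged = truth.merge(recovered, on="subject_id", suffixes=("_true", "_rec"))
    rows = {}
    for name in PARAM_ORDER:
        t = merged[f"{name}_true"].to_numpy(dtype=float)
        r = merged[f"{name}_rec"].to_numpy(dtype=float)
        if np.std(t) > 0 and np.std(r) > 0:
            corr = float(np.corrcoef(t, r)[0, 1])
        else:
            corr = float("nan")
        rows[name] = {
            "correlation": corr,
            "bias": float(np.mean(r - t)),
            "rmse": float(np.sqrt(np.mean((r - t) ** 2))),
            "median_abs_error": float(np.median(np.abs(r - t))),
        }
    return pd.DataFrame(rows).T


def parameter_recovery(
    sessions: dict[str, dict[str, Session]],
    truth: pd.DataFrame,
    grid: Optional[GridSpec] = None,
    bounds: Optional[FitBounds] = None,
    n_starts: int = 12,
    q_init: float = 0.5,
) -> RecoveryReport:
    """Refit every simulated subject and compare with the truth table.

    Each condition is fitted independently; a subject's recovered
    parameter is the mean of the two per-condition estimates. Subjects
    whose fits error out are reported in ``failed_subjects``, never
    silently dropped.
    """
    if len(sessions) < 2:
        raise ValueError("recovery needs at least 2 subjects")
    fit_rows = []
    recovered_rows = []
    failed = []
    n_converged = 0
    for subject_id, by_cond in sessions.items():
        try:
            narrow, wide = by_cond["narrow"], by_cond["wide"]
            fits = fit_subject(narrow, wide, grid, bounds, n_starts, q_init)
        except Exception:
            failed.append(subject_id)
            continue
        est = {name: 0.0 for name in PARAM_ORDER}
        for res in fits:
            n_converged += int(res.converged)
            row = {
                "subject_id": subject_id,
                "condition": res.condition,
                "negLL": res.neg_log_likelihood,
                "n_trials_used": res.n_trials_used,
                "converged": res.converged,
            }
            for name in PARAM_ORDER:
                v = getattr(res.params, name)
                row[name] = v
                est[name] += v / len(fits)
            fit_rows.append(row)
        recovered_rows.append({"subject_id": subject_id, **est})
    recovered = pd.DataFrame(recovered_rows)
    metrics = recovery_metrics(truth, recovered)
    merged = truth[["subject_id", "group_label"]].merge(recovered, on="subject_id")
    group_medians = merged.groupby("group_label")[list(PARAM_ORDER)].median()
    return RecoveryReport(
        metrics=metrics,
        group_medians=group_medians,
        n_converged=n_converged,
        n_subjects=len(sessions),
        fits=pd.DataFrame(fit_rows),
        failed_subjects=failed,
    )
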