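"""Synthetic decision agents, participant populations, and pleasantness ratings.

Agents stand in for participants: each carries a discounting curve
(hyperbolic rate k, or logistic slope/switch-point (a, b) on the log-delay
axis) defined on the normalized subjective-value scale SV', plus a softmax
choice-noise temperature tau.  A population couples correlated state and
trait anxiety scores to the per-task discounting parameters and to
pleasantness-rating slopes through simple linear structural equations, so
that the downstream anxiety path analyses have a known generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .curves import normalize_sv, sv_hyperbolic, sv_logistic
from .task import (
    EXPERIENTIAL,
    HYPOTHETICAL,
    Choice,
    TaskConfig,
    TrialRecord,
    run_session,
)

__all__ = [
    "Agent",
    "PopulationParams",
    "StudyTables",
    "simulate_choice",
    "generate_population",
    "generate_ratings",
    "generate_study",
    "generate_logistic_agents",
    "generate_hyperbolic_agents",
    "likert_round",
]


@dataclass(frozen=True)
class Agent:
    """One simulated decision maker.

    ``model`` selects the subjective-value curve; tau >= 0 is the softmax
    temperature on the normalized value scale (0 = deterministic, ties broken
    toward the delayed option).
    """

    model: Literal["hyperbolic", "logistic"]
    k: float | None = None
    a: float | None = None
    b: float | None = None
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.model == "hyperbolic":
            if self.k is None or self.k <= 0:
                raise ValueError("hyperbolic agent requires k > 0")
        elif self.model == "logistic":
            if self.a is None or self.a <= 0 or self.b is None:
                raise ValueError("logistic agent requires a > 0 and b")
        else:
            raise ValueError(f"unknown agent model {self.model!r}")

    def sv_norm(self, delay: float) -> float:
        """Normalized subjective value SV' of the delayed reward."""
        if self.model == "hyperbolic":
            return float(sv_hyperbolic(delay, self.k))
        return float(sv_logistic(delay, self.a, self.b))

    def policy(self, config: TaskConfig, rng: np.random.Generator) -> Callable[[TrialRecord], Choice]:
        """Choice policy for :func:`discountlab.task.run_session`."""
        sv_min = config.sv_min

        def choose(trial: TrialRecord) -> Choice:
            imm = trial.presented_value / config.delayed_value
            return simulate_choice(self, imm, 1.0, trial.delay, sv_min=sv_min, rng=rng)

        return choose


def simulate_choice(
    agent: Agent,
    immediate_value: float,
    delayed_value: float,
    delay: float,
    sv_min: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Choice:
    """Choose between an immediate and a delayed reward.

    The immediate option's value (as a fraction of the delayed reward) and
    the agent's delayed SV are both placed on the normalized scale anchored
    at ``sv_min`` before comparison.  With tau = 0 the larger value wins,
    ties going to the delayed option; with tau > 0 the choice is a logistic
    (softmax) draw at temperature tau.
    """
    if delay <= 0:
        raise ValueError("delay must be > 0")
    frac = immediate_value / delayed_value
    imm = float(normalize_sv(np.clip(frac, sv_min, 1.0), sv_min))
    sv = agent.sv_norm(delay)
    if agent.tau == 0:
        return Choice.IMMEDIATE if imm > sv else Choice.DELAYED
    if rng is None:
        rng = np.random.default_rng()
    p_imm = 1.0 / (1.0 + np.exp(-(imm - sv) / agent.tau))
    return Choice.IMMEDIATE if rng.random() < p_imm else Choice.DELAYED


def likert_round(x) -> np.ndarray:
    """Round half away from zero, then clip to the [-4, 4] Likert grid."""
    x = np.asarray(x, dtype=float)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, -4, 4)


@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters for a synthetic study population.

    Anxiety anchors default to the printed sample moments (state 34.3/10.1,
    trait 43.0/10.8, r = 0.59); discounting anchors default to the
    experiential and hypothetical group-level logistic fixed effects
    (intercept -a*b, slope a).  Structural coefficients are expressed on the
    scale of the affected generating parameter per SD of the (standardized)
    anxiety predictor.
    """

    n: int = 44
    seed: int = 0
    tau: float = 0.002

    state_mean: float = 34.3
    state_sd: float = 10.1
    trait_mean: float = 43.0
    trait_sd: float = 10.8
    r_state_trait: float = 0.59

    # experiential logistic mixed-model scale: y = beta0 + beta1 log T
    exp_beta0_mean: float = -13.5
    exp_beta0_sd: float = 1.0
    exp_beta1_mean: float = 4.3
    exp_beta1_sd: float = 0.5
    hyp_beta0_mean: float = -12.4
    hyp_beta0_sd: float = 1.5
    hyp_beta1_mean: float = 1.8
    hyp_beta1_sd: float = 0.3

    # pleasantness ratings: rating = intercept + slope * occlusion_level + e
    rating_intercept: float = 3.3
    rating_slope_mean: float = -0.55
    rating_slope_sd: float = 0.10
    rating_noise_sd: float = 1.4

    # structural effects (per SD of standardized predictor, on the scale of
    # the affected parameter); state acts on experiential discounting only
    # through the rating-slope magnitude (complete mediation by reward
    # sensitivity), trait acts directly, and a positive state x trait
    # interaction keeps high-trait agents willing to wait.
    path_state_to_slope_mag: float = -0.05
    path_trait_to_slope_mag: float = 0.03
    path_sens_to_b_exp: float = 4.0
    path_state_to_b_exp: float = 0.0
    path_trait_to_b_exp: float = 0.35
    path_statextrait_to_b_exp: float = 0.15
    path_state_to_b_hyp: float = -0.05
    path_trait_to_b_hyp: float = -0.30
    b_exp_resid_sd: float = 0.5
    b_hyp_resid_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size n must be >= 2")
        if abs(self.r_state_trait) > 1:
            raise ValueError("|r_state_trait| must be <= 1")
        for name in ("state_sd", "trait_sd", "exp_beta0_sd", "exp_beta1_sd",
                     "hyp_beta0_sd", "hyp_beta1_sd", "rating_slope_sd",
                     "rating_noise_sd", "b_exp_resid_sd", "b_hyp_resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _positive_normal(rng, mean, sd, size, floor=1e-2):
    """Normal draws truncated (by redraw) to stay positive."""
    x = rng.normal(mean, sd, size)
    while np.any(x <= floor):
        bad = x <= floor
        x[bad] = rng.normal(mean, sd, bad.sum())
    return x


def generate_logistic_agents(
    n: int,
    beta0_mean: float,
    beta0_sd: float,
    beta1_mean: float,
    beta1_sd: float,
    tau: float,
    rng: np.random.Generator,
) -> list[Agent]:
    """Agents whose (a, b) derive from mixed-model coefficients
    y = beta0 + beta1 log T, i.e. a = beta1 and b = -beta0/beta1."""
    beta1 = _positive_normal(rng, beta1_mean, beta1_sd, n)
    beta0 = rng.normal(beta0_mean, beta0_sd, n)
    return [Agent(model="logistic", a=float(b1), b=float(-b0 / b1), tau=tau)
            for b0, b1 in zip(beta0, beta1)]


def generate_hyperbolic_agents(
    n: int,
    log_k_mean: float,
    log_k_sd: float,
    tau: float,
    rng: np.random.Generator,
) -> list[Agent]:
    beta0 = rng.normal(log_k_mean, log_k_sd, n)
    return [Agent(model="hyperbolic", k=float(np.exp(b0)), tau=tau) for b0 in beta0]


def generate_population(pop: PopulationParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a participant table with correlated anxiety and structural effects.

    Columns: participant_id, state_anxiety, trait_anxiety, rating_slope,
    rating intercept/noise, model, per-task logistic parameters, tau.
    """
    if rng is None:
        rng = np.random.default_rng(pop.seed)
    cov = np.array([
        [pop.state_sd ** 2, pop.r_state_trait * pop.state_sd * pop.trait_sd],
        [pop.r_state_trait * pop.state_sd * pop.trait_sd, pop.trait_sd ** 2],
    ])
    if np.any(np.linalg.eigvalsh(cov) < -1e-12):
        raise ValueError("implied anxiety covariance is not positive semi-definite")
    st = rng.multivariate_normal([pop.state_mean, pop.trait_mean], cov, size=pop.n)
    state, trait = st[:, 0], st[:, 1]
    z_s = (state - pop.state_mean) / pop.state_sd
    z_t = (trait - pop.trait_mean) / pop.trait_sd

    # mediator carrier: magnitude of the occlusion->pleasantness slope
    slope_mag = (np.abs(pop.rating_slope_mean)
                 + pop.path_state_to_slope_mag * z_s
                 + pop.path_trait_to_slope_mag * z_t
                 + rng.normal(0.0, pop.rating_slope_sd, pop.n))
    slope_mag = np.clip(slope_mag, 0.02, None)
    rating_slope = -slope_mag
    z_m = (slope_mag - np.abs(pop.rating_slope_mean)) / max(
        np.hypot(pop.rating_slope_sd,
                 np.hypot(pop.path_state_to_slope_mag, pop.path_trait_to_slope_mag)),
        1e-9,
    )

    # experiential switch point b carries the anxiety structure; AUC inherits
    # it downstream because model_auc is monotone in b
    b_exp_base = pop.exp_beta0_mean / -pop.exp_beta1_mean
    a_exp = _positive_normal(rng, pop.exp_beta1_mean, pop.exp_beta1_sd, pop.n)
    b_exp = (b_exp_base
             + pop.path_sens_to_b_exp * z_m * (pop.b_exp_resid_sd / 4.0)
             + pop.path_state_to_b_exp * z_s
             + pop.path_trait_to_b_exp * z_t
             + pop.path_statextrait_to_b_exp * z_s * z_t
             + rng.normal(0.0, pop.b_exp_resid_sd, pop.n))

    b_hyp_base = pop.hyp_beta0_mean / -pop.hyp_beta1_mean
    a_hyp = _positive_normal(rng, pop.hyp_beta1_mean, pop.hyp_beta1_sd, pop.n)
    b_hyp = (b_hyp_base
             + pop.path_state_to_b_hyp * z_s
             + pop.path_trait_to_b_hyp * z_t
             + rng.normal(0.0, pop.b_hyp_resid_sd, pop.n))

    return pd.DataFrame({
        "participant_id": [f"p{i + 1:03d}" for i in range(pop.n)],
        "state_anxiety": state,
        "trait_anxiety": trait,
        "model": "logistic",
        "a_experiential": a_exp,
        "b_experiential": b_exp,
        "a_hypothetical": a_hyp,
        "b_hypothetical": b_hyp,
        "tau": pop.tau,
        "rating_intercept": pop.rating_intercept,
        "rating_slope": rating_slope,
        "rating_noise_sd": pop.rating_noise_sd,
    })


def generate_ratings(
    participant: pd.Series,
    levels: Sequence[int] = tuple(range(1, 11)),
    reps: int = 6,
    rng: np.random.Generator | None = None,
    config: TaskConfig = EXPERIENTIAL,
) -> pd.DataFrame:
    """Pleasantness ratings: linear in occlusion level, Likert-discretized.

    Occlusion level o = 1..10 indexes ascending occlusion; the corresponding
    occluded fraction is 1 minus the visible fraction of grid level 11 - o.
    Six repetitions per level reproduce the 60-trial rating task.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    occ_levels = np.repeat(np.asarray(levels, dtype=int), reps)
    visible = np.asarray(config.immediate_values, dtype=float)
    occ_frac = 1.0 - visible[len(visible) - occ_levels]
    raw = (participant["rating_intercept"]
           + participant["rating_slope"] * occ_levels
           + rng.normal(0.0, participant["rating_noise_sd"], occ_levels.size))
    return pd.DataFrame({
        "participant_id": participant["participant_id"],
        "occlusion_level": occ_levels,
        "occlusion_fraction": occ_frac,
        "rating": likert_round(raw),
    })


@dataclass
class StudyTables:
    """The bundle of tables a full (synthetic or real) study produces."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    points: pd.DataFrame
    ratings: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.participants["participant_id"])
        for name in ("trials", "points", "ratings"):
            tab = getattr(self, name)
            if not set(tab["participant_id"]).issubset(ids):
                raise ValueError(f"{name} references unknown participant_ids")

    def write_csvs(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.points.to_csv(out / "indifference_points.csv", index=False)
        self.ratings.to_csv(out / "ratings.csv", index=False)


def _session_frames(config, agent, seed, pid, rng):
    trials, points = run_session(config, agent.policy(config, rng), seed, pid)
    tdf = pd.DataFrame({
        "participant_id": pid,
        "task_kind": config.task_kind.value,
        "trial_index": [t.trial_index for t in trials],
        "delay": [t.delay for t in trials],
        "delay_units": config.delay_units,
        "level_index": [t.presented_level_index for t in trials],
        "immediate_value": [t.presented_value for t in trials],
        "choice": [t.choice.value for t in trials],
        "run_index": [t.run_index for t in trials],
        "seed": seed,
    })
    pdf = pd.DataFrame({
        "participant_id": pid,
        "task_kind": config.task_kind.value,
        "delay": [p.delay for p in points],
        "delay_units": config.delay_units,
        "run_index": [p.run_index for p in points],
        "level": [p.level for p in points],
        "value": [p.value for p in points],
        "at_boundary": [p.at_boundary.value for p in points],
    })
    return tdf, pdf


def generate_study(
    pop: PopulationParams,
    configs: tuple[TaskConfig, TaskConfig] = (EXPERIENTIAL, HYPOTHETICAL),
    seed: int | None = None,
) -> StudyTables:
    """End-to-end synthetic study: population, both tasks, ratings."""
    if seed is None:
        seed = pop.seed
    root = np.random.SeedSequence(seed)
    ss_pop, ss_sessions, ss_ratings = root.spawn(3)
    participants = generate_population(pop, np.random.default_rng(ss_pop))

    trial_frames, point_frames, rating_frames = [], [], []
    session_seeds = iter(ss_sessions.generate_state(2 * len(participants) + 8))
    rating_rng = np.random.default_rng(ss_ratings)
    for _, row in participants.iterrows():
        pid = row["participant_id"]
        for config in configs:
            suffix = config.task_kind.value
            agent = Agent(
                model="logistic",
                a=row[f"a_{suffix}"],
                b=row[f"b_{suffix}"],
                tau=row["tau"],
            )
            sess_seed = int(next(session_seeds) % (2 ** 31))
            rng = np.random.default_rng(sess_seed)
            tdf, pdf = _session_frames(config, agent, sess_seed, pid, rng)
            trial_frames.append(tdf)
            point_frames.append(pdf)
        rating_frames.append(generate_ratings(row, rng=rating_rng))

    tables = StudyTables(
        participants=participants,
        trials=pd.concat(trial_frames, ignore_index=True),
        points=pd.concat(point_frames, ignore_index=True),
        ratings=pd.concat(rating_frames, ignore_index=True),
    )
    tables.validate()
    return tables
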