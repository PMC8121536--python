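"""Adaptive elicitation of indifference points by interval bisection.

Both intertemporal-choice tasks present a series of binary choices between a
smaller reward available now and a fixed larger reward available after a
delay.  For every (delay, run) cell a *semi-adaptive dichotomy* staircase
maintains an uncertainty interval over the grid of immediate-option levels
and halves it after each choice, converging on the indifference point -- the
immediate level whose subjective value equals that of waiting.

Level axis convention
---------------------
Levels are indexed by ascending immediate value: level 1 is the least
valuable immediate option (13 % of the photograph visible, or $1) and level
L the most valuable (the full photograph, or $100).  Choosing the *delayed*
option at a presented level means the agent demands a better immediate
offer, so the lower bound of the uncertainty interval rises; choosing the
*immediate* option lowers the upper bound.  The interval is tracked as the
half-open (lo, hi] over 0..L+1 so that the extreme levels are genuinely
tested: hi = L+1 encodes "never accepted any immediate offer" (exclusive
preference for the delayed reward).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Choice",
    "TaskKind",
    "Boundary",
    "TaskConfig",
    "UncertaintyInterval",
    "TrialRecord",
    "IndifferencePoint",
    "SessionState",
    "EXPERIENTIAL",
    "HYPOTHETICAL",
    "init_session",
    "select_next_trial",
    "record_choice",
    "extract_indifference_points",
    "processing_screen_duration",
    "run_session",
    "trials_to_convergence",
    "enumerate_threshold_sessions",
]


class Choice(str, Enum):
    IMMEDIATE = "immediate"
    DELAYED = "delayed"


class TaskKind(str, Enum):
    EXPERIENTIAL = "experiential"
    HYPOTHETICAL = "hypothetical"


class Boundary(str, Enum):
    NONE = "none"
    ALWAYS_DELAYED = "always_delayed"
    ALWAYS_IMMEDIATE = "always_immediate"


class ConfigError(ValueError):
    """A task configuration violates one of its invariants."""


class SessionError(RuntimeError):
    """Operation applied to a session in an incompatible state."""


@dataclass(frozen=True)
class TaskConfig:
    """Grid and bookkeeping parameters for one intertemporal-choice task.

    ``immediate_values`` are on the immediate scale (visible fraction of the
    photograph for the experiential task, dollars for the hypothetical one)
    and must be strictly increasing, ending at ``delayed_value``.
    """

    task_kind: TaskKind
    immediate_values: tuple[float, ...]
    delayed_value: float
    delays: tuple[float, ...]
    delay_units: str
    n_runs: int = 2
    start_pool: tuple[int, ...] = (4, 5, 6)
    response_buffer_s: float = 2.0
    reward_display_s: float = 5.0

    def __post_init__(self) -> None:
        v = np.asarray(self.immediate_values, dtype=float)
        if v.ndim != 1 or len(v) < 2 or np.any(np.diff(v) <= 0):
            raise ConfigError("immediate_values must be strictly increasing")
        if not np.isclose(v[-1], self.delayed_value):
            raise ConfigError(
                "max(immediate_values) must equal delayed_value on the immediate scale"
            )
        d = np.asarray(self.delays, dtype=float)
        if d.ndim != 1 or len(d) < 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ConfigError("delays must be strictly increasing and > 0")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        L = len(v)
        if not self.start_pool or any(s < 1 or s > L for s in self.start_pool):
            raise ConfigError("start_pool must be a nonempty subset of 1..L")

    @property
    def n_levels(self) -> int:
        return len(self.immediate_values)

    @property
    def sv_min(self) -> float:
        """Value of the lowest immediate level (the floor of the SV scale)."""
        return float(self.immediate_values[0]) / float(self.delayed_value)

    def level_value(self, level: int) -> float:
        """Immediate-scale magnitude of a 1-based level index."""
        return float(self.immediate_values[level - 1])


#: The ten occlusion levels of the experiential task, as visible fraction of
#: the photograph, and its eleven delays in seconds.
EXPERIENTIAL = TaskConfig(
    task_kind=TaskKind.EXPERIENTIAL,
    immediate_values=(0.13, 0.28, 0.45, 0.60, 0.70, 0.80, 0.88, 0.95, 0.97, 1.00),
    delayed_value=1.0,
    delays=(1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 25),
    delay_units="seconds",
)

#: The fourteen immediate dollar amounts of the hypothetical task and its
#: delays expressed in days (month = 30 d, year = 365 d).
HYPOTHETICAL = TaskConfig(
    task_kind=TaskKind.HYPOTHETICAL,
    immediate_values=(1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 99, 100),
    delayed_value=100.0,
    delays=(1, 2, 7, 14, 30, 91, 182, 365, 730, 1825, 3650),
    delay_units="days",
    start_pool=(7, 8, 9),
)


@dataclass
class UncertaintyInterval:
    """Half-open uncertainty range (lo, hi] for one (delay, run) cell.

    The indifference level lies in lo+1..hi, where hi = L+1 denotes an agent
    that never accepts any immediate offer.  ``converged`` once hi − lo == 1.
    """

    delay_index: int
    run_index: int
    lo: int
    hi: int
    n_levels: int
    started: bool = False
    last_choice: Choice | None = None

    @property
    def converged(self) -> bool:
        return self.hi - self.lo <= 1

    @property
    def width(self) -> int:
        return self.hi - self.lo

    def midpoint(self) -> int:
        """Next level to present: floor midpoint, nudged into (lo, hi)."""
        p = (self.lo + self.hi) // 2
        if p <= self.lo:
            p = self.lo + 1
        return min(p, self.n_levels)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    participant_id: str
    delay: float
    delay_index: int
    presented_level_index: int
    presented_value: float
    run_index: int
    choice: Choice | None = None


@dataclass(frozen=True)
class IndifferencePoint:
    participant_id: str
    task_kind: TaskKind
    delay: float
    run_index: int
    level: int
    value: float
    at_boundary: Boundary


@dataclass
class SessionState:
    config: TaskConfig
    participant_id: str
    seed: int
    rng: np.random.Generator
    intervals: dict[tuple[int, int], UncertaintyInterval]
    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return all(iv.converged for iv in self.intervals.values())


def init_session(config: TaskConfig, seed: int, participant_id: str = "p1") -> SessionState:
    """Open one staircase per (delay, run), each spanning the full level range."""
    rng = np.random.default_rng(seed)
    intervals = {
        (di, ri): UncertaintyInterval(
            delay_index=di, run_index=ri, lo=0, hi=config.n_levels + 1,
            n_levels=config.n_levels,
        )
        for di in range(len(config.delays))
        for ri in range(config.n_runs)
    }
    return SessionState(config=config, participant_id=participant_id, seed=seed,
                        rng=rng, intervals=intervals)


def select_next_trial(state: SessionState) -> TrialRecord:
    """Draw a (delay, run) cell uniformly among the unconverged ones and
    present the interval midpoint, or a start-pool level on a cell's first
    trial."""
    open_cells = [key for key, iv in state.intervals.items() if not iv.converged]
    if not open_cells:
        raise SessionError("session complete: all uncertainty intervals converged")
    key = open_cells[state.rng.integers(len(open_cells))]
    iv = state.intervals[key]
    if not iv.started:
        level = int(state.rng.choice(state.config.start_pool))
    else:
        level = iv.midpoint()
    di, ri = key
    return TrialRecord(
        trial_index=len(state.trials),
        participant_id=state.participant_id,
        delay=float(state.config.delays[di]),
        delay_index=di,
        presented_level_index=level,
        presented_value=state.config.level_value(level),
        run_index=ri,
    )


def record_choice(state: SessionState, trial: TrialRecord, choice: Choice) -> SessionState:
    """Narrow the trial's uncertainty interval according to the choice.

    Delayed choice at level p: the immediate offer was not good enough, so
    the indifference level is above p (lo <- p).  Immediate choice: level p
    was accepted, so the indifference level is at most p (hi <- p).
    """
    choice = Choice(choice)
    iv = state.intervals[(trial.delay_index, trial.run_index)]
    if iv.converged:
        raise SessionError("recording a choice against a converged interval")
    p = trial.presented_level_index
    if not (iv.lo < p <= min(iv.hi, iv.n_levels)):
        raise SessionError(
            f"presented level {p} outside the open interval ({iv.lo}, {iv.hi}]"
        )
    if choice is Choice.DELAYED:
        iv.lo = p
    else:
        iv.hi = p
    iv.started = True
    iv.last_choice = choice
    state.trials.append(replace(trial, choice=choice))
    return state


def extract_indifference_points(state: SessionState) -> list[IndifferencePoint]:
    """One point per (delay, run): the lowest level the agent accepted.

    Cells that never saw an immediate choice (hi = L+1) are exclusive-delayed
    preferences and are recorded at the maximum level with a boundary flag,
    mirroring the retention of such participants in the fits.
    """
    if not state.complete:
        raise SessionError("cannot extract indifference points: unconverged intervals")
    cfg = state.config
    points = []
    for (di, ri), iv in sorted(state.intervals.items()):
        if iv.hi > cfg.n_levels:
            level, flag = cfg.n_levels, Boundary.ALWAYS_DELAYED
        else:
            level = iv.hi
            flag = Boundary.ALWAYS_IMMEDIATE if iv.hi == 1 else Boundary.NONE
        points.append(IndifferencePoint(
            participant_id=state.participant_id,
            task_kind=cfg.task_kind,
            delay=float(cfg.delays[di]),
            run_index=ri,
            level=level,
            value=cfg.level_value(level),
            at_boundary=flag,
        ))
    return points


def processing_screen_duration(window: Sequence[TrialRecord]) -> float:
    """Duration of the equalization screen shown after every five trials.

    Five seconds plus the delays of all delayed options that were *not*
    chosen (i.e. trials resolved immediately) in the window, so that choosing
    the immediate option never shortens the session.
    """
    if len(window) != 5:
        raise ValueError("processing-screen window must contain exactly 5 trials")
    return 5.0 + sum(t.delay for t in window if t.choice is Choice.IMMEDIATE)


def run_session(
    config: TaskConfig,
    policy: Callable[[TrialRecord], Choice],
    seed: int,
    participant_id: str = "p1",
) -> tuple[list[TrialRecord], list[IndifferencePoint]]:
    """Run staircases to convergence against a choice policy.

    ``policy`` maps a presented trial to a Choice; agents from
    :mod:`discountlab.agents` provide one via ``Agent.policy(config)``.
    """
    state = init_session(config, seed, participant_id)
    limit = config.n_levels * len(config.delays) * config.n_runs + 1
    while not state.complete:
        trial = select_next_trial(state)
        choice = policy(trial)
        if choice not in (Choice.IMMEDIATE, Choice.DELAYED):
            raise SessionError(f"policy returned invalid choice token {choice!r}")
        record_choice(state, trial, choice)
        if len(state.trials) > limit:  # pragma: no cover - safety net
            raise SessionError("staircase failed to terminate")
    return state.trials, extract_indifference_points(state)


def trials_to_convergence(config: TaskConfig, start_level: int, threshold: int) -> int:
    """Number of choice trials for one staircase cell with a deterministic
    threshold agent.

    The agent accepts the immediate option iff the presented level is at
    least ``threshold``; threshold = L+1 encodes an agent that always waits.
    Deterministic given (start_level, threshold): the cell's trajectory does
    not depend on delay or run.
    """
    L = config.n_levels
    iv = UncertaintyInterval(0, 0, lo=0, hi=L + 1, n_levels=L)
    n = 0
    p = start_level
    while not iv.converged:
        n += 1
        choice = Choice.IMMEDIATE if p >= threshold else Choice.DELAYED
        if choice is Choice.DELAYED:
            iv.lo = p
        else:
            iv.hi = p
        p = iv.midpoint()
    return n


def enumerate_threshold_sessions(config: TaskConfig) -> dict:
    """Exhaustive per-cell trial counts over all deterministic threshold
    agents and all first-trial start levels.

    Returns the count table t[start][threshold] plus session-total extremes:
    because cells are independent and identically parameterized, the maximum
    (minimum) session total over all start-level assignments equals
    n_cells x max (min) over the table.
    """
    L = config.n_levels
    n_cells = len(config.delays) * config.n_runs
    table = {
        s: {t: trials_to_convergence(config, s, t) for t in range(1, L + 2)}
        for s in config.start_pool
    }
    counts = [c for row in table.values() for c in row.values()]
    return {
        "table": table,
        "n_cells": n_cells,
        "max_total": n_cells * max(counts),
        "min_total": n_cells * min(counts),
        "mean_trials_per_cell": float(np.mean(counts)),
    }
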