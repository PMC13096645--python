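"""Closed-loop agent stepping.

Each step: sample lateralised familiarity at the current (true) heading,
write it into the goal field through the (possibly celestially-rotated)
compass bump, compare goal and compass to get a turn command, turn, then
advance one step length along the new heading.  An optional perturbation
shifts the compass bump by whole columns from a given step onward, emulating
a sudden rotation of the celestial reference (e.g. mirroring the sun).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .angles import wrap_deg
from .circuit_core import (
    CircuitConfig,
    GoalField,
    encode_compass,
    rotation_cells,
    steer,
    update_goal,
)
from .mb_input import FamiliarityConfig, sample_familiarity


@dataclass(frozen=True)
class TrialConfig:
    """One closed-loop trial.

    initial_heading defaults (None) to route_direction + 90 deg: the agent
    starts side-on to the route with an empty goal field and must acquire the
    goal from familiarity input alone.  rotation_deg is applied from
    rotation_step onward, quantised to whole compass columns.  clamp_heading
    freezes the heading (open-loop, trackball-like) while still logging turn
    commands.
    """

    n_steps: int = 200
    step_length: float = 1.0
    initial_heading: float | None = None
    initial_position: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    rotation_step: int | None = None
    seed: int = 0
    clamp_heading: bool = False
    log_goal: bool = False

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if self.rotation_step is not None and not 0 <= self.rotation_step <= self.n_steps:
            raise ValueError(f"rotation_step must lie in [0, n_steps], got {self.rotation_step}")
        if self.initial_heading is not None and not np.isfinite(self.initial_heading):
            raise ValueError("initial_heading must be finite")


@dataclass(frozen=True)
class TrialRecord:
    """Per-step log of one trial; arrays all have length ``n_steps``.

    ``heading[t]``, ``x[t]``, ``y[t]`` are the state *after* step t;
    the pre-trial state is in ``initial_heading`` / ``initial_position``.
    """

    initial_heading: float
    initial_position: tuple[float, float]
    route_direction: float
    step_length: float
    heading: np.ndarray
    x: np.ndarray
    y: np.ndarray
    f_left: np.ndarray
    f_right: np.ndarray
    turn_deg: np.ndarray
    rotation_active: np.ndarray
    goal_left: np.ndarray | None = None
    goal_right: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return len(self.heading)

    def positions(self) -> np.ndarray:
        """(n_steps + 1) x 2 array of vertices, starting at the initial position."""
        xs = np.concatenate([[self.initial_position[0]], self.x])
        ys = np.concatenate([[self.initial_position[1]], self.y])
        return np.column_stack([xs, ys])

    def final_directional_error(self) -> float:
        """Absolute angle between the start-to-end chord and the route direction."""
        dx = self.x[-1] - self.initial_position[0]
        dy = self.y[-1] - self.initial_position[1]
        bearing = np.rad2deg(np.arctan2(dy, dx))
        return float(abs(wrap_deg(bearing - self.route_direction)))


def run_trial(
    circuit_cfg: CircuitConfig,
    familiarity_cfg: FamiliarityConfig,
    trial_cfg: TrialConfig,
) -> TrialRecord:
    """Run one seeded closed-loop trial; fully reproducible from the seed."""
    rng = np.random.default_rng(trial_cfg.seed)
    n = trial_cfg.n_steps
    init_heading = float(
        wrap_deg(
            trial_cfg.initial_heading
            if trial_cfg.initial_heading is not None
            else familiarity_cfg.route_direction + 90.0
        )
    )
    heading = init_heading
    x, y = map(float, trial_cfg.initial_position)
    goal = GoalField.zeros(circuit_cfg)
    rot_cells = rotation_cells(trial_cfg.rotation_deg, circuit_cfg)

    rec = {
        key: np.empty(n)
        for key in ("heading", "x", "y", "f_left", "f_right", "turn_deg")
    }
    rotation_active = np.zeros(n, dtype=bool)
    goal_left = np.empty((n, circuit_cfg.n_columns)) if trial_cfg.log_goal else None
    goal_right = np.empty((n, circuit_cfg.n_columns)) if trial_cfg.log_goal else None

    for t in range(n):
        rotated = trial_cfg.rotation_step is not None and t >= trial_cfg.rotation_step
        compass = encode_compass(heading, rot_cells if rotated else 0, circuit_cfg)
        fam = sample_familiarity(heading, familiarity_cfg, rng)
        goal = update_goal(goal, compass, fam.f_left, fam.f_right, circuit_cfg)
        out = steer(goal, compass, circuit_cfg, rng)
        if not trial_cfg.clamp_heading:
            heading = float(wrap_deg(heading + out.turn_deg))
        x += trial_cfg.step_length * np.cos(np.deg2rad(heading))
        y += trial_cfg.step_length * np.sin(np.deg2rad(heading))
        rec["heading"][t] = heading
        rec["x"][t] = x
        rec["y"][t] = y
        rec["f_left"][t] = fam.f_left
        rec["f_right"][t] = fam.f_right
        rec["turn_deg"][t] = out.turn_deg
        rotation_active[t] = rotated
        if trial_cfg.log_goal:
            goal_left[t] = goal.left_bank
            goal_right[t] = goal.right_bank

    return TrialRecord(
        initial_heading=init_heading,
        initial_position=tuple(map(float, trial_cfg.initial_position)),
        route_direction=familiarity_cfg.route_direction,
        step_length=trial_cfg.step_length,
        rotation_active=rotation_active,
        goal_left=goal_left,
        goal_right=goal_right,
        **{k: v for k, v in rec.items()},
    )


def cohort_seeds(base_seed: int, n_agents: int) -> list[int]:
    """Deterministic per-agent seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n_agents)]


def run_cohort(
    circuit_cfg: CircuitConfig,
    familiarity_cfg: FamiliarityConfig,
    trial_cfg: TrialConfig,
    n_agents: int,
    base_seed: int,
) -> list[TrialRecord]:
    """Run ``n_agents`` independent trials with seeds spawned from ``base_seed``."""
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    return [
        run_trial(circuit_cfg, familiarity_cfg, replace(trial_cfg, seed=seed))
        for seed in cohort_seeds(base_seed, n_agents)
    ]
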