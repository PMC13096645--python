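"""Column-discretised compass, goal-accumulation and steering layers.

The circuit mirrors the conserved central-complex (CX) architecture: a
protocerebral-bridge-like compass layer carries a single-peaked activity bump
over ``n_columns`` angular columns encoding the (possibly celestially-rotated)
current heading; a fan-shaped-body-like goal layer holds two decaying banks of
column activity, charged through laterally offset copies of the compass bump by
left/right familiarity input; PFL-like comparison units read the overlap of the
goal field with left- and right-shifted compass copies and their difference is
the steering command sent to the descending pathway.

Sign conventions: angles in degrees wrapped to (-180, 180], positive turns are
clockwise (to the right).  A positive column shift moves activity toward larger
preferred directions, i.e. clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import wrap_deg

STEER_EPS = 1e-9  # makes the zero-goal steering quotient exactly noise-only


class UndefinedAngleError(ValueError):
    """Raised when a population vector has no defined direction (zero resultant)."""


@dataclass(frozen=True)
class CircuitConfig:
    """Parameters of the compass/goal/steering circuit.

    Parameters
    ----------
    n_columns
        Number of compass columns spanning 360 deg; must be even and >= 4.
        Eight 45-deg columns make a 135-deg celestial rotation an exact
        three-column bump shift.
    anatomical_offset_cols
        Lateral offset (in columns) at which each hemisphere's familiarity
        input writes the goal field: the left input writes one column
        counter-clockwise of the current bump, the right input one column
        clockwise.
    pfl_offset_cols
        Offset (columns) of the shifted compass copies used by the steering
        comparison.
    decay
        Per-step goal-field decay lambda in [0, 1]; each update multiplies
        both banks by (1 - lambda) before adding input.
    gain
        Dimensionless steering gain.
    motor_noise_sd
        SD of the Gaussian noise added to each turn command, deg/step.
    turn_scale
        Converts the normalised drive difference (in [-1, 1]) to degrees.
    turn_cap
        Hard per-step limit on |turn|, degrees.
    kernel
        Compass bump shape: "cosine" (half-wave rectified cosine) or
        "vonmises" (exp(kappa (cos - 1)) with ``bump_kappa``).  Any
        single-peaked symmetric kernel yields the same qualitative dynamics.
    """

    n_columns: int = 8
    anatomical_offset_cols: int = 1
    pfl_offset_cols: int = 1
    decay: float = 0.2
    gain: float = 1.0
    motor_noise_sd: float = 10.0
    turn_scale: float = 30.0
    turn_cap: float = 90.0
    kernel: str = "cosine"
    bump_kappa: float = 2.0

    def __post_init__(self):
        if self.n_columns < 4 or self.n_columns % 2 != 0:
            raise ValueError(f"n_columns must be even and >= 4, got {self.n_columns}")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError(f"decay must lie in [0, 1], got {self.decay}")
        if self.motor_noise_sd < 0:
            raise ValueError(f"motor_noise_sd must be >= 0, got {self.motor_noise_sd}")
        if self.turn_cap <= 0:
            raise ValueError(f"turn_cap must be > 0, got {self.turn_cap}")
        if self.kernel not in ("cosine", "vonmises"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "vonmises" and self.bump_kappa <= 0:
            raise ValueError("bump_kappa must be > 0")

    @property
    def column_spacing(self) -> float:
        """Angular width of one column, degrees (360 / n_columns)."""
        return 360.0 / self.n_columns

    @property
    def preferred_directions(self) -> np.ndarray:
        """Preferred direction of each column: 0, spacing, 2*spacing, ..."""
        return np.arange(self.n_columns) * self.column_spacing


def rotation_cells(rotation_deg: float, cfg: CircuitConfig) -> int:
    """Quantise a celestial-cue rotation to an integer column shift.

    The compass bump can only be displaced by whole columns, so a rotation of
    the celestial reference is implemented as ``round(deg / spacing)`` cells
    (135 deg on the default eight-column compass is exactly three cells).
    """
    return int(round(rotation_deg / cfg.column_spacing))


@dataclass(frozen=True)
class CompassActivity:
    """Single-peaked, peak-normalised activity bump over the compass columns."""

    values: np.ndarray
    preferred_directions: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.values)


def _shift(values: np.ndarray, k: int) -> np.ndarray:
    """Move a column pattern k columns toward larger preferred directions."""
    return np.roll(values, k)


def encode_compass(heading: float, rotation_cells: int, cfg: CircuitConfig) -> CompassActivity:
    """Encode a heading as a compass bump, optionally shifted by whole columns.

    The apparent heading is ``heading + rotation_cells * column_spacing``:
    a rotation of the celestial reference displaces the bump without the
    animal having turned.  The bump is the configured kernel evaluated at the
    angular distance from each column's preferred direction, rectified and
    normalised to peak 1.
    """
    heading = float(heading)
    if not np.isfinite(heading):
        raise ValueError(f"heading must be finite, got {heading}")
    apparent = heading + rotation_cells * cfg.column_spacing
    delta = np.deg2rad(apparent - cfg.preferred_directions)
    if cfg.kernel == "cosine":
        values = np.maximum(0.0, np.cos(delta))
    else:
        values = np.exp(cfg.bump_kappa * (np.cos(delta) - 1.0))
    peak = values.max()
    return CompassActivity(values=values / peak, preferred_directions=cfg.preferred_directions)


def decode_compass(activity: CompassActivity) -> float:
    """Population-vector readout: activity-weighted circular mean, degrees.

    Raises
    ------
    UndefinedAngleError
        If the activity is all-zero or perfectly symmetric (zero resultant).
    """
    values = np.asarray(activity.values, dtype=float)
    if np.all(values == 0):
        raise UndefinedAngleError("cannot decode an all-zero compass bump")
    phi = np.deg2rad(activity.preferred_directions)
    resultant = np.sum(values * np.exp(1j * phi))
    if np.abs(resultant) < 1e-12 * values.sum():
        raise UndefinedAngleError("compass activity has no defined direction (zero resultant)")
    return float(wrap_deg(np.rad2deg(np.angle(resultant))))


@dataclass(frozen=True)
class GoalField:
    """Two per-hemisphere banks of goal-column activity; their sum encodes the goal."""

    left_bank: np.ndarray
    right_bank: np.ndarray

    @classmethod
    def zeros(cls, cfg: CircuitConfig) -> "GoalField":
        return cls(np.zeros(cfg.n_columns), np.zeros(cfg.n_columns))

    @property
    def combined(self) -> np.ndarray:
        return self.left_bank + self.right_bank

    @property
    def total_mass(self) -> float:
        return float(self.left_bank.sum() + self.right_bank.sum())


def update_goal(
    goal: GoalField,
    compass: CompassActivity,
    f_left: float,
    f_right: float,
    cfg: CircuitConfig,
) -> GoalField:
    """One leaky-integrator update of the goal field from lateralised input.

    Both banks decay by (1 - lambda); the left familiarity writes a copy of
    the compass bump displaced one anatomical offset counter-clockwise of the
    current (apparent) heading, the right writes one clockwise.  A left-view
    familiarity fires when the body points clockwise of the goal, so its
    counter-clockwise write lands on the goal — and symmetrically.
    """
    for name, f in (("f_left", f_left), ("f_right", f_right)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    keep = 1.0 - cfg.decay
    off = cfg.anatomical_offset_cols
    left = keep * goal.left_bank + f_left * _shift(compass.values, -off)
    right = keep * goal.right_bank + f_right * _shift(compass.values, +off)
    return GoalField(left_bank=left, right_bank=right)


@dataclass(frozen=True)
class SteeringOutput:
    """Lateralised premotor drives and the resulting signed turn command."""

    drive_left: float
    drive_right: float
    turn_deg: float


def steer(
    goal: GoalField,
    compass: CompassActivity,
    cfg: CircuitConfig,
    rng: np.random.Generator | None = None,
) -> SteeringOutput:
    """Compare goal and compass headings; emit a signed turn command.

    The right drive is the overlap of the combined goal field with the compass
    bump shifted clockwise by the PFL offset (and mirrored for the left), so a
    goal clockwise of the apparent heading yields drive_right > drive_left and
    a positive (rightward) expected turn.  The drive difference is normalised
    by total drive, scaled to degrees, perturbed by Gaussian motor noise when
    an ``rng`` is given, and capped at ``turn_cap``.
    """
    combined = goal.combined
    if len(combined) != compass.n_columns:
        raise ValueError("goal and compass column counts differ")
    off = cfg.pfl_offset_cols
    drive_right = float(combined @ _shift(compass.values, +off))
    drive_left = float(combined @ _shift(compass.values, -off))
    turn = cfg.gain * cfg.turn_scale * (drive_right - drive_left) / (drive_right + drive_left + STEER_EPS)
    if rng is not None and cfg.motor_noise_sd > 0:
        turn += rng.normal(0.0, cfg.motor_noise_sd)
    turn = float(np.clip(turn, -cfg.turn_cap, cfg.turn_cap))
    return SteeringOutput(drive_left=drive_left, drive_right=drive_right, turn_deg=turn)
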