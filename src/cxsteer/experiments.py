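"""In-silico experiments on the closed-loop model.

Two protocols:

* a directional-bias x directional-noise robustness sweep scoring the
  start-to-end directional error of 200-step paths, which exposes the three
  regimes of route guidance (stable following for positive bias, reversed
  following for negative bias, a labile transition zone at zero bias);

* a celestial-rotation cohort, where a mid-trial whole-column shift of the
  compass bump (a 135-deg sun rotation = 3 columns on the default compass)
  perturbs route-following agents; paths are discretised every few steps and
  summarised as cohort bearings and turn angles aligned on rotation onset,
  plus a phase report quantifying the onset veer, corrective turn, meander
  window, and restabilisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agent_loop import TrialConfig, TrialRecord, run_cohort, run_trial
from .angles import wrap_deg
from .circuit_core import CircuitConfig
from .mb_input import FamiliarityConfig
from .path_metrics import PathTable, directional_error


@dataclass(frozen=True)
class SweepSpec:
    """Grid and replication of the bias x noise sweep."""

    bias_grid: tuple = tuple(range(-90, 95, 5))
    noise_grid: tuple = tuple(range(0, 65, 5))
    reps: int = 20
    n_steps: int = 200

    def __post_init__(self):
        if len(self.bias_grid) == 0 or len(self.noise_grid) == 0:
            raise ValueError("grids must be non-empty")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class SweepResult:
    """Tidy table: one row per (bias, noise) cell with mean/SD directional error."""

    table: pd.DataFrame

    def cell(self, bias: float, noise: float) -> pd.Series:
        sel = self.table[(self.table.bias == bias) & (self.table.noise == noise)]
        if len(sel) != 1:
            raise KeyError(f"no unique cell for bias={bias}, noise={noise}")
        return sel.iloc[0]


def sweep_bias_noise(
    spec: SweepSpec,
    circuit_cfg: CircuitConfig,
    familiarity_cfg: FamiliarityConfig,
    base_seed: int,
) -> SweepResult:
    """Run the bias x noise sweep; errors are in [0, 180] degrees.

    Each cell runs ``reps`` seeded trials with the familiarity bias and noise
    overridden, scoring the absolute angle between the start-to-end chord and
    the route direction after ``n_steps`` steps.
    """
    ss = np.random.SeedSequence(base_seed)
    rows = []
    trial_cfg = TrialConfig(n_steps=spec.n_steps)
    for bias in spec.bias_grid:
        for noise in spec.noise_grid:
            fam = replace(
                familiarity_cfg, directional_bias=float(bias), directional_noise_sd=float(noise)
            )
            seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(spec.reps)]
            errors = [
                run_trial(circuit_cfg, fam, replace(trial_cfg, seed=s)).final_directional_error()
                for s in seeds
            ]
            rows.append(
                {
                    "bias": float(bias),
                    "noise": float(noise),
                    "mean_error": float(np.mean(errors)),
                    "sd_error": float(np.std(errors, ddof=1)) if spec.reps > 1 else 0.0,
                    "reps": spec.reps,
                }
            )
    return SweepResult(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class RotationSummary:
    """Cohort time-course around rotation onset.

    ``table`` has one row per aligned segment index (0 = segment starting at
    onset): circular mean +/- SE of bearings relative to the route, and
    mean +/- SE of absolute turn angles at the junction entering the segment
    (turn index 0 is the junction at the rotation itself).
    """

    table: pd.DataFrame
    rotation_step: int
    segment_stride: int
    records: list[TrialRecord]


def _segment_series(record: TrialRecord, stride: int):
    """Bearings and junction turn angles of a path subsampled every ``stride`` steps."""
    verts = record.positions()[::stride]
    if len(verts) < 3:
        raise ValueError("fewer than 2 segments after subsampling; lower the stride")
    d = np.diff(verts, axis=0)
    bearings = np.rad2deg(np.arctan2(d[:, 1], d[:, 0]))
    turns = np.abs(wrap_deg(np.diff(bearings)))
    return bearings, turns


def sun_rotation_experiment(
    circuit_cfg: CircuitConfig,
    familiarity_cfg: FamiliarityConfig,
    n_agents: int = 20,
    rotation_deg: float = 135.0,
    rotation_step: int = 120,
    segment_stride: int = 3,
    n_steps: int = 300,
    base_seed: int = 0,
    settle_steps: int | None = None,
) -> RotationSummary:
    """Perturb a route-following cohort by a mid-trial celestial rotation.

    Agents start side-on to the route, acquire the goal from familiarity, and
    at ``rotation_step`` the compass bump is shifted by the quantised rotation.
    Paths are subsampled every ``segment_stride`` steps; per-segment bearings
    (relative to the route) and junction turn angles are averaged across the
    cohort and aligned so that index 0 is the segment/junction at onset.

    ``rotation_step`` must be a multiple of ``segment_stride`` so the onset
    falls exactly on a junction.  The agents begin aligned with the route
    (initial heading = route) so the pre-onset window shows settled behaviour.
    """
    if rotation_step % segment_stride != 0:
        raise ValueError("rotation_step must be a multiple of segment_stride")
    if segment_stride < 1:
        raise ValueError("segment_stride must be >= 1")
    if rotation_step + 2 * segment_stride > n_steps:
        raise ValueError("fewer than 2 post-onset segments; extend n_steps")
    trial_cfg = TrialConfig(
        n_steps=n_steps,
        rotation_deg=rotation_deg,
        rotation_step=rotation_step,
        initial_heading=familiarity_cfg.route_direction,
    )
    records = run_cohort(circuit_cfg, familiarity_cfg, trial_cfg, n_agents, base_seed)
    onset_seg = rotation_step // segment_stride
    all_bearings, all_turns = [], []
    for rec in records:
        bearings, turns = _segment_series(rec, segment_stride)
        all_bearings.append(wrap_deg(bearings - familiarity_cfg.route_direction))
        all_turns.append(turns)
    bearings = np.vstack(all_bearings)  # agents x segments
    turns = np.vstack(all_turns)  # agents x junctions; junction j sits at vertex j+1

    rows = []
    n_segments = bearings.shape[1]
    for seg in range(n_segments):
        rel = np.deg2rad(bearings[:, seg])
        resultant = np.mean(np.exp(1j * rel))
        bearing_mean = float(wrap_deg(np.rad2deg(np.angle(resultant))))
        # circular SD from resultant length
        r = np.abs(resultant)
        bearing_sd = float(np.rad2deg(np.sqrt(-2.0 * np.log(max(r, 1e-12)))))
        row = {
            "seg_index": seg - onset_seg,
            "bearing_mean": bearing_mean,
            "bearing_se": bearing_sd / np.sqrt(n_agents),
            "turn_mean": np.nan,
            "turn_se": np.nan,
            "post": seg >= onset_seg,
        }
        j = seg - 1  # junction entering this segment
        if 0 <= j < turns.shape[1]:
            row["turn_mean"] = float(turns[:, j].mean())
            row["turn_se"] = float(turns[:, j].std(ddof=1) / np.sqrt(n_agents))
        rows.append(row)
    return RotationSummary(
        table=pd.DataFrame(rows),
        rotation_step=rotation_step,
        segment_stride=segment_stride,
        records=records,
    )


@dataclass(frozen=True)
class PhaseMarkers:
    """Cohort-level markers of the five perturbation-response phases.

    The veer (ii) and the corrective turn (iii) are read from the signed
    per-step cohort-mean turn command; the disturbance/meander window (iv-v)
    is read from the cohort-mean absolute turn angle between successive path
    segments, where the motor noise largely averages out and the conflict
    between old and new goal directions is visible.

    baseline_mean / baseline_sd : pre-onset cohort-mean segment turn-angle
        statistics (phase i, stabilised route-following).
    onset_sign / onset_magnitude : sign and mean magnitude (deg/step) of the
        signed cohort turn over the first steps after onset (phase ii veer).
    corrective_latency : steps from onset to the first cohort-mean turn of
        opposite sign to the veer (phase iii), or None.
    meander_len : number of segments, within ``horizon_segments`` of onset,
        whose cohort-mean turn angle exceeds baseline + 2 SD — counted only
        if the elevation starts within ``onset_link`` segments of onset, so a
        perturbation-free cohort reports no window (phase iv; the window
        includes the veer and corrective-turn segments).
    restabilisation_segment : index (relative to onset, in segments) just
        after the last elevated segment of the window (phase v), or None.
    """

    baseline_mean: float
    baseline_sd: float
    onset_sign: int
    onset_magnitude: float
    corrective_latency: int | None
    meander_len: int
    restabilisation_segment: int | None


def phase_report(
    records: list[TrialRecord],
    rotation_step: int,
    segment_stride: int = 3,
    onset_window: int = 3,
    onset_link: int = 3,
    horizon_segments: int = 20,
) -> PhaseMarkers:
    """Quantify the perturbation-response phases from a cohort of trial records."""
    turns = np.vstack([rec.turn_deg for rec in records])  # agents x steps
    if rotation_step < 2 * segment_stride or rotation_step > turns.shape[1]:
        raise ValueError("rotation_step outside the usable recorded steps")
    if rotation_step % segment_stride != 0:
        raise ValueError("rotation_step must be a multiple of segment_stride")

    mean_signed = turns.mean(axis=0)
    onset_slice = mean_signed[rotation_step : rotation_step + onset_window]
    onset_magnitude = float(np.abs(onset_slice).mean())
    onset_sign = int(np.sign(onset_slice.mean())) if onset_slice.mean() != 0 else 0

    corrective_latency = None
    if onset_sign != 0:
        post = mean_signed[rotation_step:]
        opposite = np.flatnonzero(np.sign(post) == -onset_sign)
        if len(opposite):
            corrective_latency = int(opposite[0])

    # segment-level turn angles; junction j sits at step (j + 1) * stride
    seg_turns = np.vstack([_segment_series(rec, segment_stride)[1] for rec in records])
    mean_turn = seg_turns.mean(axis=0)
    onset_junction = rotation_step // segment_stride - 1  # junction at the onset step
    baseline = mean_turn[:onset_junction]
    baseline_mean = float(baseline.mean())
    baseline_sd = float(baseline.std(ddof=1))
    threshold = baseline_mean + 2.0 * baseline_sd

    post_turns = mean_turn[onset_junction:][: horizon_segments + 1]
    exceed = np.flatnonzero(post_turns > threshold)
    meander_len = 0
    restab = None
    if len(exceed) and exceed[0] < onset_link:
        meander_len = int(len(exceed))
        restab = int(exceed[-1] + 1)
    return PhaseMarkers(
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        onset_sign=onset_sign,
        onset_magnitude=onset_magnitude,
        corrective_latency=corrective_latency,
        meander_len=meander_len,
        restabilisation_segment=restab,
    )


def record_to_path(record: TrialRecord, stride: int = 1) -> PathTable:
    """Export a trial's positions (including the start) as a PathTable."""
    verts = record.positions()[::stride]
    times = np.arange(len(record.positions()))[::stride].astype(float)
    return PathTable(time=times, x=verts[:, 0], y=verts[:, 1])


def record_directional_error(record: TrialRecord) -> float:
    """Directional error of a record via the generic path metric (same formula)."""
    return directional_error(record_to_path(record), record.route_direction)
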