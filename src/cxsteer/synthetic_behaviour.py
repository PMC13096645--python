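"""Synthetic behavioural recordings with ground-truth labels.

Emulates the two kinds of data the behavioural metrics consume, so the whole
pipeline runs without any field recordings:

* trackball-style angular-velocity traces of individuals held in eight fixed
  compass orientations, turning toward the route direction (or by a fixed
  per-individual side bias when facing the route or anti-route), with smooth
  AR(1) noise;
* 2-D homing paths produced by the closed-loop agent, optionally with a
  mid-path celestial-rotation perturbation, exported in the metrics' path
  format.

Every generator is a pure function of (spec, seed) and emits ground-truth
labels alongside the data, so recovery of the generating structure by the
metrics pipeline can be scored automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent_loop import TrialConfig, TrialRecord, run_trial
from .angles import wrap_deg
from .circuit_core import CircuitConfig
from .experiments import record_to_path
from .mb_input import FamiliarityConfig
from .path_metrics import OmegaTrace, PathTable


@dataclass(frozen=True)
class TrackballSpec:
    """Shape of a synthetic trackball cohort.

    Each individual is recorded once per orientation.  The deterministic part
    of each trace is ``expected_sign * mean_turn_speed``; AR(1) noise with
    stationary SD ``noise_sd`` (lag-1 coefficient ``ar_coef``) is added so the
    traces resemble smooth behavioural angular velocities.  At orientations
    facing the route or anti-route the expected sign is the individual's fixed
    side bias.
    """

    n_individuals: int = 12
    orientations: tuple = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    route_direction: float = 0.0
    mean_turn_speed: float = 20.0  # deg/s
    noise_sd: float = 10.0  # deg/s, stationary SD of the AR(1) noise
    ar_coef: float = 0.8
    duration: float = 12.0  # s
    rate: float = 10.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be > 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticCohort:
    """Traces keyed by (individual, orientation) plus ground-truth labels."""

    traces: dict
    labels: pd.DataFrame
    spec: TrackballSpec


def _ar1(n: int, sd: float, coef: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = coef * out[i - 1] + rng.normal(0.0, innov_sd)
    return out


def _expected_sign(orientation: float, route: float, side_bias: int) -> int:
    """+1 if the route lies clockwise (to the right) of the body axis, -1 if
    counter-clockwise; the individual's side bias when aligned or anti-aligned."""
    offset = float(wrap_deg(route - orientation))
    if offset == 0.0 or offset == 180.0:
        return side_bias
    return 1 if offset > 0 else -1


def _gen_cohort(spec: TrackballSpec, orientation_tuned: bool) -> SyntheticCohort:
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.rate))
    time = np.arange(n_samples) / spec.rate
    side_bias = rng.choice([-1, 1], size=spec.n_individuals)
    traces, rows = {}, []
    for ind in range(spec.n_individuals):
        for orient in spec.orientations:
            if orientation_tuned:
                sign = _expected_sign(orient, spec.route_direction, int(side_bias[ind]))
            else:
                sign = int(rng.choice([-1, 1]))
            omega = sign * spec.mean_turn_speed + _ar1(n_samples, spec.noise_sd, spec.ar_coef, rng)
            traces[(ind, float(orient))] = OmegaTrace(time=time, omega=omega)
            rows.append(
                {
                    "individual": ind,
                    "orientation": float(orient),
                    "expected_sign": sign,
                    "side_bias": int(side_bias[ind]),
                }
            )
    return SyntheticCohort(traces=traces, labels=pd.DataFrame(rows), spec=spec)


def gen_trackball_cohort(spec: TrackballSpec) -> SyntheticCohort:
    """Familiar-route cohort: turn direction points toward the route."""
    return _gen_cohort(spec, orientation_tuned=True)


def gen_unfamiliar_cohort(spec: TrackballSpec) -> SyntheticCohort:
    """Unfamiliar-surroundings cohort: per-trace random turn direction.

    Individuals keep a side preference within each trace (the sign is constant
    over the trace) but it carries no information about orientation.
    """
    return _gen_cohort(spec, orientation_tuned=False)


def gen_perturbed_path(
    circuit_cfg: CircuitConfig,
    familiarity_cfg: FamiliarityConfig,
    trial_cfg: TrialConfig,
    sample_stride: int = 1,
) -> tuple[PathTable, TrialRecord]:
    """Run one closed-loop trial and export its track in the metrics path format.

    The bridge between the simulator and the path metrics: returns both the
    PathTable (positions sampled every ``sample_stride`` steps, starting at the
    initial position, time = step index) and the underlying TrialRecord with
    its ground truth.
    """
    record = run_trial(circuit_cfg, familiarity_cfg, trial_cfg)
    return record_to_path(record, stride=sample_stride), record
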