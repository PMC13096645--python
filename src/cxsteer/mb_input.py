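"""Lateralised, orientation-tuned familiarity signals.

Visual-scene recognition (assumed to live in the mushroom bodies) is abstracted
as a pair of tuning curves over body orientation.  The left signal peaks, on
average, ``directional_bias`` degrees clockwise of the route direction — i.e.
it fires when the body points right of the goal — and the right signal
symmetrically at minus the bias.  Each step the two curves are independently
jittered by Gaussian "directional noise", and responses below a floor are
zeroed, so the circuit receives sporadic lateralised input rather than a
continuous error signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FamiliarityConfig:
    """Tuning of the left/right familiarity signals.

    route_direction : allocentric goal direction, degrees.
    directional_bias : offset (deg) clockwise of the goal at which the LEFT
        signal peaks on average; the right signal peaks at minus this.
    directional_noise_sd : SD (deg) of the per-step Gaussian shift of each
        tuning curve around its mean offset.
    tuning_kappa : concentration of the exponential-cosine tuning kernel;
        kappa = 5 gives a half-maximum width of roughly +/-30 deg.
    amplitude : peak familiarity value.
    threshold : floor below which a raw response is zeroed (sporadicity).
    """

    route_direction: float = 0.0
    directional_bias: float = 45.0
    directional_noise_sd: float = 10.0
    tuning_kappa: float = 5.0
    amplitude: float = 1.0
    threshold: float = 0.05

    def __post_init__(self):
        if self.directional_noise_sd < 0:
            raise ValueError("directional_noise_sd must be >= 0")
        if self.tuning_kappa <= 0:
            raise ValueError("tuning_kappa must be > 0")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1] (0 disables familiarity)")
        if self.amplitude > 0 and not 0.0 <= self.threshold < self.amplitude:
            raise ValueError("require 0 <= threshold < amplitude")
        if self.amplitude == 0 and self.threshold != 0.0:
            raise ValueError("threshold must be 0 when amplitude is 0")


@dataclass(frozen=True)
class FamiliaritySample:
    """One step's pair of familiarity values and the noise draws that made them."""

    f_left: float
    f_right: float
    noise_draws: tuple[float, float]


def _tuning(heading, center, cfg: FamiliarityConfig):
    raw = cfg.amplitude * np.exp(cfg.tuning_kappa * (np.cos(np.deg2rad(heading - center)) - 1.0))
    return np.where(raw >= cfg.threshold, raw, 0.0)


def sample_familiarity(heading: float, cfg: FamiliarityConfig, rng: np.random.Generator) -> FamiliaritySample:
    """Draw the lateralised familiarity pair for one step at the given heading.

    The left curve's centre is ``route + bias + eps_L`` and the right curve's
    ``route - bias - eps_R`` with independent fresh draws
    eps ~ Normal(0, directional_noise_sd); responses below threshold are 0.
    """
    heading = float(heading)
    if not np.isfinite(heading):
        raise ValueError(f"heading must be finite, got {heading}")
    eps_left = float(rng.normal(0.0, cfg.directional_noise_sd)) if cfg.directional_noise_sd > 0 else 0.0
    eps_right = float(rng.normal(0.0, cfg.directional_noise_sd)) if cfg.directional_noise_sd > 0 else 0.0
    center_left = cfg.route_direction + cfg.directional_bias + eps_left
    center_right = cfg.route_direction - cfg.directional_bias - eps_right
    return FamiliaritySample(
        f_left=float(_tuning(heading, center_left, cfg)),
        f_right=float(_tuning(heading, center_right, cfg)),
        noise_draws=(eps_left, eps_right),
    )


def mean_response_curve(cfg: FamiliarityConfig, headings) -> pd.DataFrame:
    """Expected familiarity pair at each heading, marginalised over the jitter.

    The expectation over the Gaussian curve shift is computed by dense
    trapezoidal quadrature against the normal density over +/- 6 SD (the
    thresholding makes the integrand non-smooth, where adaptive Gaussian rules
    misbehave).  With zero noise this is exactly the raw tuning curve.

    Returns a DataFrame with columns ``heading``, ``f_left``, ``f_right``;
    the expected left curve peaks at ``route + bias``, the right at
    ``route - bias``.
    """
    headings = np.atleast_1d(np.asarray(headings, dtype=float))
    sd = cfg.directional_noise_sd
    if sd == 0:
        f_left = _tuning(headings, cfg.route_direction + cfg.directional_bias, cfg)
        f_right = _tuning(headings, cfg.route_direction - cfg.directional_bias, cfg)
    else:
        eps = np.linspace(-6.0 * sd, 6.0 * sd, 2001)
        pdf = np.exp(-0.5 * (eps / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))
        # grid: headings x eps
        left_vals = _tuning(headings[:, None], cfg.route_direction + cfg.directional_bias + eps[None, :], cfg)
        right_vals = _tuning(headings[:, None], cfg.route_direction - cfg.directional_bias - eps[None, :], cfg)
        f_left = np.trapezoid(left_vals * pdf, eps, axis=1)
        f_right = np.trapezoid(right_vals * pdf, eps, axis=1)
    return pd.DataFrame({"heading": headings, "f_left": f_left, "f_right": f_right})
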