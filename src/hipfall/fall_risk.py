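"""Fall-configuration exposure model and per-subject fracture probability.

The exposure model factorizes a fall into (i) a fall angle with
piecewise-uniform density over three directional segments — anterior
(-90 to -30 deg, 12% of falls), sideways (-30 to 30 deg, 39.36%) and
posterior (30 to 90 deg, 48.64%) — (ii) an impact speed ~ N(2.14, 0.63)
m/s truncated at zero, and (iii) a hip-impact factor: only 40% of
real-life falls load the hip.  A subject fractures in a fall when the
impact speed exceeds their critical velocity at the fall angle, so

    P_Fx = 100 * 0.4 * Int density(theta) * P(V > v_crit(theta)) dtheta   [%]

computed by composite trapezoid quadrature segment by segment (the speed
dimension is available in closed form), with a Monte-Carlo sampling mode
retained as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .surrogate import CriticalVelocityCurve

__all__ = [
    "FallConfigModel",
    "RiskEstimate",
    "angle_density",
    "fracture_prob_given_angle",
    "compute_pfx",
    "compute_pfx_monte_carlo",
    "relative_risk",
    "risk_table",
]


@dataclass(frozen=True)
class FallConfigModel:
    """Probability model of fall configurations striking the hip."""

    segment_bounds: tuple[float, ...] = (-90.0, -30.0, 30.0, 90.0)   # deg
    segment_masses: tuple[float, ...] = (0.12, 0.3936, 0.4864)
    speed_mean: float = 2.14          # m/s
    speed_sd: float = 0.63            # m/s
    speed_truncation: float = 0.0     # m/s, lower support bound
    hip_impact_factor: float = 0.4    # fraction of falls with hip impact

    def __post_init__(self) -> None:
        if len(self.segment_masses) != len(self.segment_bounds) - 1:
            raise ValueError("need one mass per segment")
        if abs(sum(self.segment_masses) - 1.0) > 1e-12:
            raise ValueError("segment masses must sum to 1")
        if any(m < 0 for m in self.segment_masses):
            raise ValueError("segment masses must be non-negative")
        if np.any(np.diff(self.segment_bounds) <= 0):
            raise ValueError("segment bounds must be strictly increasing")
        if not self.speed_sd > 0:
            raise ValueError("speed SD must be positive")
        if not 0 < self.hip_impact_factor <= 1:
            raise ValueError("hip_impact_factor must be in (0, 1]")


def angle_density(model: FallConfigModel, fall_angle) -> np.ndarray | float:
    """Piecewise-uniform fall-angle density (per degree)."""
    theta = np.asarray(fall_angle, dtype=float)
    lo, hi = model.segment_bounds[0], model.segment_bounds[-1]
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError(f"fall angle outside [{lo}, {hi}] deg")
    bounds = np.asarray(model.segment_bounds)
    widths = np.diff(bounds)
    seg = np.clip(np.searchsorted(bounds, theta, side="right") - 1, 0, widths.size - 1)
    dens = np.asarray(model.segment_masses)[seg] / widths[seg]
    return dens if dens.ndim else float(dens)


def fracture_prob_given_angle(model: FallConfigModel, v_crit) -> np.ndarray | float:
    """P(impact speed > v_crit) under the truncated-normal speed model.

    v_crit at or below the truncation point gives exactly 1 (every
    modeled fall exceeds it); +inf gives exactly 0.
    """
    v = np.asarray(v_crit, dtype=float)
    z = (v - model.speed_mean) / model.speed_sd
    z_t = (model.speed_truncation - model.speed_mean) / model.speed_sd
    denom = norm.sf(z_t)
    with np.errstate(invalid="ignore"):
        p = norm.sf(z) / denom
    p = np.where(v <= model.speed_truncation, 1.0, p)
    p = np.where(np.isposinf(v), 0.0, p)
    return p if p.ndim else float(p)


def _segment_nodes(curve: CriticalVelocityCurve, lo: float, hi: float) -> np.ndarray:
    mask = (curve.angle_grid >= lo - 1e-9) & (curve.angle_grid <= hi + 1e-9)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError("curve grid too sparse to cover a fall-angle segment")
    if abs(curve.angle_grid[idx[0]] - lo) > 1e-6 or abs(curve.angle_grid[idx[-1]] - hi) > 1e-6:
        raise ValueError("curve grid must include the segment boundary angles")
    return idx


def compute_pfx(curve: CriticalVelocityCurve, model: FallConfigModel) -> float:
    """Probability of hip fracture (percent) for one critical-velocity curve.

    Composite trapezoid quadrature over the angle grid, segment by segment
    so the density jumps at the segment boundaries are handled exactly;
    the result is scaled by the hip-impact factor and clamped to
    [0, 100 * factor].
    """
    if (
        curve.angle_grid[0] > model.segment_bounds[0] + 1e-9
        or curve.angle_grid[-1] < model.segment_bounds[-1] - 1e-9
    ):
        raise ValueError("curve does not cover the fall-angle domain")
    p_nodes = np.asarray(fracture_prob_given_angle(model, curve.v_crit))
    total = 0.0
    for k, mass in enumerate(model.segment_masses):
        lo, hi = model.segment_bounds[k], model.segment_bounds[k + 1]
        idx = _segment_nodes(curve, lo, hi)
        dens = mass / (hi - lo)
        total += dens * np.trapezoid(p_nodes[idx], curve.angle_grid[idx])
    pfx = 100.0 * model.hip_impact_factor * total
    return float(np.clip(pfx, 0.0, 100.0 * model.hip_impact_factor))


def compute_pfx_monte_carlo(
    curve: CriticalVelocityCurve,
    model: FallConfigModel,
    n_samples: int = 10**6,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P_Fx (percent) and its standard error.

    Samples fall angles (segment by mass, uniform within), truncated-normal
    speeds, and counts falls whose speed exceeds the linearly interpolated
    critical velocity; the hip-impact factor is applied deterministically.
    Curves containing the +inf sentinel are not supported in this mode
    (interpolation across an infinite node is ill-defined); use the
    quadrature path for those.
    """
    if np.any(np.isinf(curve.v_crit)):
        raise ValueError("Monte-Carlo mode requires a finite critical-velocity curve")
    rng = np.random.default_rng(seed)
    masses = np.asarray(model.segment_masses)
    bounds = np.asarray(model.segment_bounds)
    seg = rng.choice(masses.size, size=n_samples, p=masses)
    u = rng.uniform(size=n_samples)
    theta = bounds[seg] + u * (bounds[seg + 1] - bounds[seg])

    z_t = (model.speed_truncation - model.speed_mean) / model.speed_sd
    # inverse-CDF sampling of the truncated normal
    uu = rng.uniform(size=n_samples)
    speed = model.speed_mean + model.speed_sd * norm.ppf(
        norm.cdf(z_t) + uu * norm.sf(z_t)
    )

    v_at = np.interp(theta, curve.angle_grid, curve.v_crit)
    frac = speed > v_at
    p_hat = frac.mean()
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-300) / n_samples)
    scale = 100.0 * model.hip_impact_factor
    return float(scale * p_hat), float(scale * se)


@dataclass(frozen=True)
class RiskEstimate:
    """Per-subject trial outcome: fracture probabilities and relative risk."""

    subject_id: str
    p_fx: float                  # %, without protector
    p_fx_hp: float               # %, with protector
    rr: float | None             # P_Fx_HP / P_Fx; None when baseline risk is 0

    def __post_init__(self) -> None:
        if self.p_fx < 0 or self.p_fx_hp < 0:
            raise ValueError("fracture probabilities must be non-negative")


def relative_risk(p_fx: float, p_fx_hp: float) -> float | None:
    """Per-subject RR = P_Fx_HP / P_Fx; undefined (None) at zero baseline.

    Subjects with zero baseline risk are excluded from cohort RR means.
    """
    if p_fx < 0 or p_fx_hp < 0:
        raise ValueError("fracture probabilities must be non-negative")
    if p_fx == 0:
        return None
    return p_fx_hp / p_fx


def risk_table(estimates: Sequence[RiskEstimate]) -> pd.DataFrame:
    """Per-subject risk CSV layout; undefined RR serializes as an empty field."""
    return pd.DataFrame(
        [
            {"subject_id": e.subject_id, "p_fx": e.p_fx, "p_fx_hp": e.p_fx_hp,
             "rr": np.nan if e.rr is None else e.rr}
            for e in estimates
        ],
        columns=["subject_id", "p_fx", "p_fx_hp", "rr"],
    )
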