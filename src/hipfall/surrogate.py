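"""Subject-specific Gaussian-process surrogate of fracture length.

Each fall simulation is expensive in the real workflow, so the fracture
length surface over (fall angle, impact velocity) is learned from a hard
budget of evaluations (default 20).  The GP uses the composite kernel
``C * RBF * DotProduct + WhiteKernel`` and active learning targets the
limit state: new configurations are chosen to maximize predictive
uncertainty where the predicted fracture length is near the 10-mm
threshold, by minimizing

    f = -exp(-1e3 * (FxL_thres - FxL_GPR)^2) * sigma

with fracture length in mm.  The exponential is so sharply peaked that a
single gradient descent stalls almost everywhere; the minimizer is
therefore multi-start from a coarse grid.  After the budget is spent, the
critical-velocity curve (smallest velocity whose posterior-mean fracture
length reaches the threshold, per angle) is read off the posterior by a
smallest-root scan and bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct, WhiteKernel

from .cohort import FRACTURE_LENGTH_THRESHOLD_MM, FallSimRecord, FractureResponseParams

__all__ = [
    "SurrogateConfig",
    "SurrogateModel",
    "CriticalVelocityCurve",
    "initial_design",
    "fit_gpr",
    "acquisition_objective",
    "propose_next",
    "active_learning_loop",
    "extract_critical_velocity",
]

#: Sharpness of the acquisition peak around the fracture-length threshold,
#: in 1/mm^2.
ACQUISITION_RATE = 1e3


@dataclass(frozen=True)
class SurrogateConfig:
    """Budget, domain and kernel settings for one subject's surrogate."""

    fxl_threshold: float = FRACTURE_LENGTH_THRESHOLD_MM   # mm
    budget: int = 20
    n_initial: int = 4
    angle_bounds: tuple[float, float] = (-90.0, 90.0)     # deg
    velocity_bounds: tuple[float, float] = (0.5, 4.5)     # m/s
    constant_bounds: tuple[float, float] = (1e-4, 1e4)    # mm^2
    length_scale_bounds: tuple[float, float] = (1e-2, 1e2)  # scaled input units
    dot_sigma0_bounds: tuple[float, float] = (1e-3, 1e3)
    noise_bounds: tuple[float, float] = (1e-8, 1.0)       # mm^2
    n_restarts: int = 5
    refit_restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_initial < 3:
            raise ValueError("the initial design needs at least 3 simulations")
        if self.n_initial > self.budget:
            raise ValueError("n_initial cannot exceed the simulation budget")
        if self.angle_bounds[0] >= self.angle_bounds[1]:
            raise ValueError("degenerate angle bounds")
        if self.velocity_bounds[0] >= self.velocity_bounds[1]:
            raise ValueError("degenerate velocity bounds")
        if self.velocity_bounds[0] <= 0:
            raise ValueError("velocity lower bound must be positive")


def _scale_inputs(config: SurrogateConfig, angles, velocities) -> np.ndarray:
    """Map (angle, velocity) to the GP's internal coordinates.

    Angle is mapped to [-1, 1] by /90; velocity is centred at the domain
    midpoint and divided by the half-range, so both kernel dimensions share
    one length-scale scale.
    """
    v_lo, v_hi = config.velocity_bounds
    mid, half = (v_lo + v_hi) / 2.0, (v_hi - v_lo) / 2.0
    angles = np.asarray(angles, dtype=float).ravel()
    velocities = np.asarray(velocities, dtype=float).ravel()
    return np.column_stack([angles / 90.0, (velocities - mid) / half])


@dataclass
class SurrogateModel:
    """A fitted GP surrogate; ``predict`` returns mm-scale mean and SD."""

    gp: GaussianProcessRegressor
    config: SurrogateConfig
    records: list[FallSimRecord] = field(default_factory=list)

    def predict(self, fall_angle, impact_velocity) -> tuple[np.ndarray, np.ndarray]:
        X = _scale_inputs(self.config, fall_angle, impact_velocity)
        mean, sd = self.gp.predict(X, return_std=True)
        return mean, sd


def initial_design(config: SurrogateConfig) -> list[tuple[float, float]]:
    """Deterministic space-filling start: lateral extremes plus oblique mids.

    The default four points are (0 deg, v_lo), (0 deg, v_hi), (-60 deg,
    v_mid), (+60 deg, v_mid); ``n_initial`` beyond four extends with
    alternating oblique angles at mid velocity.
    """
    v_lo, v_hi = config.velocity_bounds
    v_mid = (v_lo + v_hi) / 2.0
    a_lo, a_hi = config.angle_bounds
    base = [(0.0, v_lo), (0.0, v_hi), (-60.0, v_mid), (60.0, v_mid)]
    extra_angles = [-30.0, 30.0, -80.0, 80.0, -45.0, 45.0, -15.0, 15.0]
    k = 0
    while len(base) < config.n_initial:
        base.append((extra_angles[k % len(extra_angles)], v_mid))
        k += 1
    design = [
        (float(np.clip(a, a_lo, a_hi)), float(np.clip(v, v_lo, v_hi)))
        for a, v in base[: config.n_initial]
    ]
    return design


def fit_gpr(
    records: Sequence[FallSimRecord],
    config: SurrogateConfig,
    warm_start_theta: np.ndarray | None = None,
) -> SurrogateModel:
    """Fit the composite-kernel GP to the simulation records.

    One kernel structure for every subject; hyperparameters are optimized
    per subject by marginal-likelihood maximization with seeded restarts.
    A de-novo fit uses ``config.n_restarts`` random restarts; when
    ``warm_start_theta`` carries the incumbent hyperparameters of the
    previous active-learning round, the first optimization starts there and
    only ``config.refit_restarts`` random restarts are added (hyperparameters
    drift slowly as single points accrue, so the incumbent basin is almost
    always the right one).
    """
    if len(records) < 3:
        raise ValueError("at least 3 simulation records are required")
    y = np.array([r.fracture_length for r in records], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite fracture lengths in the training records")
    X = _scale_inputs(
        config,
        [r.fall_angle for r in records],
        [r.impact_velocity for r in records],
    )
    kernel = (
        ConstantKernel(1.0, config.constant_bounds)
        * RBF(1.0, config.length_scale_bounds)
        * DotProduct(1.0, config.dot_sigma0_bounds)
        + WhiteKernel(1e-6, config.noise_bounds)
    )
    n_restarts = config.n_restarts
    if warm_start_theta is not None:
        kernel.theta = np.asarray(warm_start_theta, dtype=float)
        n_restarts = config.refit_restarts
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-10,
        n_restarts_optimizer=n_restarts,
        normalize_y=False,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return SurrogateModel(gp=gp, config=config, records=list(records))


def acquisition_objective(
    model: SurrogateModel, fall_angle, impact_velocity, config: SurrogateConfig
) -> np.ndarray | float:
    """Limit-state-targeting acquisition value f (lower is more desirable)."""
    mean, sd = model.predict(fall_angle, impact_velocity)
    with np.errstate(under="ignore"):
        f = -np.exp(-ACQUISITION_RATE * (config.fxl_threshold - mean) ** 2) * sd
    return f if f.ndim else float(f)


# Relative margin keeping proposals strictly inside the search domain.
_INTERIOR_MARGIN = 1e-6


def _interior_bounds(config: SurrogateConfig) -> tuple[tuple[float, float], tuple[float, float]]:
    (a_lo, a_hi), (v_lo, v_hi) = config.angle_bounds, config.velocity_bounds
    da, dv = _INTERIOR_MARGIN * (a_hi - a_lo), _INTERIOR_MARGIN * (v_hi - v_lo)
    return (a_lo + da, a_hi - da), (v_lo + dv, v_hi - dv)


#: Starts kept for the local polish stage of the acquisition search.
_N_POLISH_STARTS = 8


def _log_acquisition(model: SurrogateModel, angles, velocities, config: SurrogateConfig):
    """log(-f) = -1e3 (thr - mean)^2 + log sigma: same optimum, no underflow."""
    mean, sd = model.predict(angles, velocities)
    return -ACQUISITION_RATE * (config.fxl_threshold - mean) ** 2 + np.log(
        np.maximum(sd, 1e-300)
    )


def propose_next(model: SurrogateModel, config: SurrogateConfig) -> tuple[float, float]:
    """Pick the next fall configuration by minimizing the acquisition f.

    f underflows to exactly zero outside a sub-millimetre band around the
    predicted limit state, so the search works on the monotone transform
    log(-f) = -1e3 (thr - mean)^2 + log(sigma), which shares the optimum
    but stays finite and differentiable.  It is evaluated on a 19 x 9
    (angle x velocity) grid, then bounded L-BFGS-B polishes from the best
    grid points (plus the current best).  Ties go to the first-found point
    in row-major grid order; if sigma vanishes everywhere (degenerate
    model) the first grid point is the documented fallback.
    """
    (a_lo, a_hi), (v_lo, v_hi) = _interior_bounds(config)
    angles = np.linspace(a_lo, a_hi, 19)
    velocities = np.linspace(v_lo, v_hi, 9)
    A, V = np.meshgrid(angles, velocities, indexing="ij")  # row-major: angle outer
    grid = np.column_stack([A.ravel(), V.ravel()])
    h_grid = np.asarray(_log_acquisition(model, grid[:, 0], grid[:, 1], config))

    if not np.any(np.isfinite(h_grid)):
        return float(grid[0, 0]), float(grid[0, 1])
    best_idx = int(np.argmax(h_grid))  # first occurrence on ties
    best_x = grid[best_idx].copy()
    best_h = float(h_grid[best_idx])

    def neg_h(x: np.ndarray) -> float:
        return -float(_log_acquisition(model, x[0], x[1], config))

    bounds = [(a_lo, a_hi), (v_lo, v_hi)]
    order = np.argsort(-h_grid, kind="stable")[:_N_POLISH_STARTS]
    starts = [grid[best_idx]] + [grid[i] for i in order if i != best_idx]
    for x0 in starts:
        try:
            res = optimize.minimize(neg_h, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if np.isfinite(res.fun) and -res.fun > best_h:
            best_h = float(-res.fun)
            best_x = np.clip(res.x, [a_lo, v_lo], [a_hi, v_hi])
    return float(best_x[0]), float(best_x[1])


OracleFn = Callable[..., FallSimRecord]


def active_learning_loop(
    oracle: OracleFn,
    params: FractureResponseParams,
    config: SurrogateConfig,
    protector: bool = False,
) -> tuple[SurrogateModel, list[FallSimRecord]]:
    """Run the budgeted simulate-fit-acquire loop for one subject.

    Spends exactly ``config.budget`` oracle evaluations: the initial design
    first, then one acquisition per refit until the budget is exhausted.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(protector)]))
    records: list[FallSimRecord] = []
    for angle, velocity in initial_design(config):
        records.append(oracle(params, angle, velocity, protector=protector, rng=rng))
    model = fit_gpr(records, config)
    while len(records) < config.budget:
        angle, velocity = propose_next(model, config)
        records.append(oracle(params, angle, velocity, protector=protector, rng=rng))
        model = fit_gpr(records, config, warm_start_theta=model.gp.kernel_.theta)
    return model, records


@dataclass
class CriticalVelocityCurve:
    """Per-angle minimum fracturing impact speed; +inf marks angles where
    the (predicted) fracture length never reaches the threshold in range."""

    angle_grid: np.ndarray   # deg, ascending
    v_crit: np.ndarray       # m/s, or +inf sentinel
    protector: bool = False

    def __post_init__(self) -> None:
        self.angle_grid = np.asarray(self.angle_grid, dtype=float)
        self.v_crit = np.asarray(self.v_crit, dtype=float)
        if self.angle_grid.shape != self.v_crit.shape:
            raise ValueError("angle grid and v_crit lengths differ")
        if np.any(np.diff(self.angle_grid) <= 0):
            raise ValueError("angle grid must be strictly ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"angle": self.angle_grid, "v_crit": self.v_crit, "protector": self.protector}
        )

    def to_csv(self, path) -> None:
        # +inf serializes as the literal "inf" and round-trips through pandas
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CriticalVelocityCurve":
        frame = pd.read_csv(path)
        return cls(
            angle_grid=frame["angle"].to_numpy(float),
            v_crit=frame["v_crit"].to_numpy(float),
            protector=bool(frame["protector"].iloc[0]),
        )


def extract_critical_velocity(
    model: SurrogateModel,
    config: SurrogateConfig,
    angle_grid: np.ndarray | None = None,
    protector: bool = False,
    n_scan: int = 200,
    tol: float = 1e-4,
) -> CriticalVelocityCurve:
    """Read the critical-velocity curve off the GP posterior mean.

    For each grid angle a ``n_scan``-point velocity scan locates the first
    upward crossing of the threshold (the smallest root); bisection then
    refines it to ``tol`` m/s.  Angles whose posterior mean stays below the
    threshold over the whole range get the +inf sentinel; angles already at
    or above the threshold at the lower bound get the lower bound.
    """
    if angle_grid is None:
        angle_grid = np.arange(config.angle_bounds[0], config.angle_bounds[1] + 0.5, 1.0)
    angle_grid = np.asarray(angle_grid, dtype=float)
    if angle_grid.min() < config.angle_bounds[0] or angle_grid.max() > config.angle_bounds[1]:
        raise ValueError("angle grid outside configured bounds")
    v_lo, v_hi = config.velocity_bounds
    v_scan = np.linspace(v_lo, v_hi, n_scan)
    n_a = angle_grid.size

    A = np.repeat(angle_grid, n_scan)
    V = np.tile(v_scan, n_a)
    mean, _ = model.predict(A, V)
    above = mean.reshape(n_a, n_scan) >= config.fxl_threshold

    v_crit = np.full(n_a, np.inf)
    at_floor = above[:, 0]
    v_crit[at_floor] = v_lo

    # First below->above transition per angle, vectorized bisection on the rest.
    lo_idx = np.full(n_a, -1)
    for i in range(n_a):
        if at_floor[i]:
            continue
        hits = np.flatnonzero(above[i])
        if hits.size:
            lo_idx[i] = hits[0] - 1
    todo = np.flatnonzero(lo_idx >= 0)
    if todo.size:
        lo = v_scan[lo_idx[todo]]
        hi = v_scan[lo_idx[todo] + 1]
        ang = angle_grid[todo]
        n_iter = int(np.ceil(np.log2((v_hi - v_lo) / (n_scan - 1) / tol))) + 1
        for _ in range(max(n_iter, 1)):
            mid = 0.5 * (lo + hi)
            m, _ = model.predict(ang, mid)
            go_right = m < config.fxl_threshold
            lo = np.where(go_right, mid, lo)
            hi = np.where(go_right, hi, mid)
        v_crit[todo] = 0.5 * (lo + hi)
    return CriticalVelocityCurve(angle_grid=angle_grid, v_crit=v_crit, protector=protector)
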