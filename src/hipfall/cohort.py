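"""Virtual cohort generation and the parametric fracture-length oracle.

This module plays two roles:

1. It draws virtual subjects whose covariates (age, weight, height, BMI,
   trochanteric soft-tissue thickness, T-score, aBMD, FRAX 10-yr hip-fracture
   probability) match per sex-and-ethnicity stratum means and SDs of an
   elderly Asian cohort, using truncated normal distributions with
   physiological bounds.

2. It stands in for a subject-specific finite-element fall simulator: a
   parametric response surface maps a fall configuration (fall angle,
   impact velocity) to a fracture length in mm, monotone in velocity, worst
   for lateral impacts, attenuated by a hip protector, and modulated by the
   subject's bone quality (T-score) and soft-tissue padding (TSTT).

The oracle has a closed-form limit state: the smallest velocity producing a
10-mm fracture length is ``v_c(theta) + threshold/slope``, which the
surrogate module is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import truncnorm

__all__ = [
    "FRACTURE_LENGTH_THRESHOLD_MM",
    "SEX_LEVELS",
    "ETHNICITY_LEVELS",
    "COVARIATE_FIELDS",
    "DEFAULT_STRATA",
    "SubjectCovariates",
    "FractureResponseParams",
    "FallSimRecord",
    "LinkSpec",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "assign_response_params",
    "oracle_fracture_length",
    "fracture_onset_velocity",
    "critical_velocity_true",
    "records_to_frame",
]

#: A fall is classified as a fracture when the femoral-surface region above
#: strain thresholds reaches this length.
FRACTURE_LENGTH_THRESHOLD_MM = 10.0

SEX_LEVELS = ("male", "female")
ETHNICITY_LEVELS = ("Chinese", "Indian", "Malay")

#: Covariates sampled per stratum; BMI is derived, never sampled.
COVARIATE_FIELDS = ("age", "weight", "height", "tstt", "frax_hfp", "abmd", "t_score")

#: Physiological truncation bounds for the sampling distributions.
TRUNCATION_BOUNDS: Mapping[str, tuple[float, float]] = {
    "age": (55.0, 100.0),
    "weight": (30.0, 150.0),
    "height": (130.0, 200.0),
    "tstt": (0.5, 8.0),
    "frax_hfp": (0.0, 30.0),
    "abmd": (0.2, 1.5),
    "t_score": (-5.0, 2.0),
}

# Per-stratum (mean, SD) of the reference elderly Singaporean cohort,
# sex x ethnicity.  Units: age yr, weight kg, height cm, TSTT cm,
# FRAX-HFP %, aBMD g/cm^2, T-score unitless.
DEFAULT_STRATA: Mapping[tuple[str, str], Mapping[str, tuple[float, float]]] = {
    ("male", "Chinese"): {
        "age": (72.62, 7.12), "weight": (65.43, 9.41), "height": (164.83, 5.01),
        "tstt": (2.43, 0.55), "frax_hfp": (4.54, 3.31), "abmd": (0.72, 0.13),
        "t_score": (-1.96, 1.01),
    },
    ("male", "Indian"): {
        "age": (71.19, 8.17), "weight": (71.71, 13.91), "height": (167.15, 6.73),
        "tstt": (3.16, 0.75), "frax_hfp": (2.11, 2.15), "abmd": (0.84, 0.16),
        "t_score": (-1.04, 1.26),
    },
    ("male", "Malay"): {
        "age": (72.22, 7.34), "weight": (69.71, 13.18), "height": (164.07, 5.68),
        "tstt": (2.94, 0.65), "frax_hfp": (2.82, 2.33), "abmd": (0.76, 0.13),
        "t_score": (-1.64, 1.01),
    },
    ("female", "Chinese"): {
        "age": (71.54, 7.01), "weight": (55.58, 9.48), "height": (154.13, 6.13),
        "tstt": (3.06, 0.96), "frax_hfp": (4.36, 4.22), "abmd": (0.62, 0.10),
        "t_score": (-1.82, 0.94),
    },
    ("female", "Indian"): {
        "age": (71.81, 8.39), "weight": (62.93, 10.73), "height": (153.79, 5.92),
        "tstt": (4.23, 0.99), "frax_hfp": (1.81, 1.81), "abmd": (0.69, 0.13),
        "t_score": (-1.15, 1.21),
    },
    ("female", "Malay"): {
        "age": (69.71, 7.30), "weight": (62.61, 12.70), "height": (150.09, 5.38),
        "tstt": (4.21, 1.17), "frax_hfp": (2.61, 3.64), "abmd": (0.64, 0.11),
        "t_score": (-1.61, 1.07),
    },
}


class CohortSpecError(ValueError):
    """Raised for invalid stratum specifications."""


@dataclass(frozen=True)
class SubjectCovariates:
    """One virtual subject's clinical covariates."""

    subject_id: str
    sex: str
    ethnicity: str
    age: float          # yr
    weight: float       # kg
    height: float       # cm
    bmi: float          # kg/m^2, always weight/(height/100)^2
    tstt: float         # cm, trochanteric soft-tissue thickness
    t_score: float
    abmd: float         # g/cm^2
    frax_hfp: float     # %, 10-yr hip-fracture probability

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise CohortSpecError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise CohortSpecError(f"unknown ethnicity {self.ethnicity!r}")
        if not (self.age > 0 and self.weight > 0 and self.height > 0 and self.tstt > 0):
            raise CohortSpecError("age, weight, height and TSTT must be positive")
        if self.frax_hfp < 0:
            raise CohortSpecError("FRAX-HFP must be non-negative")
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 1e-9:
            raise CohortSpecError("bmi inconsistent with weight and height")


@dataclass(frozen=True)
class FractureResponseParams:
    """Latent parameters of a subject's fracture-length response surface.

    ``v_c0`` is the fracture-onset velocity at a pure lateral impact
    (fall angle 0); the onset velocity rises quadratically toward +-90 deg
    with rate ``angle_curvature``.  Above onset, fracture length grows
    linearly at ``slope`` mm per (m/s).  A hip protector raises the onset
    velocity by ``protector_shift * cos^2(angle)``, i.e. maximally for
    lateral impacts and not at all for pure anterior/posterior ones.
    """

    v_c0: float                 # m/s, > 0
    angle_curvature: float      # unitless, >= 0
    slope: float                # mm/(m/s), > 0
    protector_shift: float      # m/s, >= 0
    noise_sd: float = 0.0       # mm, >= 0

    def __post_init__(self) -> None:
        if not self.v_c0 > 0:
            raise ValueError("v_c0 must be positive")
        if self.angle_curvature < 0 or self.protector_shift < 0 or self.noise_sd < 0:
            raise ValueError("angle_curvature, protector_shift, noise_sd must be >= 0")
        if not self.slope > 0:
            raise ValueError("slope must be positive")


@dataclass(frozen=True)
class FallSimRecord:
    """One evaluated fall configuration: the surrogate's training datum."""

    fall_angle: float         # deg in [-90, 90]; -90 anterior, 0 lateral, +90 posterior
    impact_velocity: float    # m/s, > 0
    fracture_length: float    # mm, >= 0
    protector: bool
    fractured: bool

    def __post_init__(self) -> None:
        if self.fracture_length < 0:
            raise ValueError("fracture length cannot be negative")
        if self.fractured != (self.fracture_length >= FRACTURE_LENGTH_THRESHOLD_MM):
            raise ValueError("fractured flag inconsistent with the 10-mm threshold")


@dataclass(frozen=True)
class LinkSpec:
    """Coefficients linking covariates to the latent fracture response.

    Default link: ``v_c0 = b0 + b_t_score*T + b_tstt*TSTT - b_age*(age-70)``
    clamped at ``v_c0_floor``; higher bone quality and thicker soft tissue
    protect, advancing age weakens.
    """

    b0: float = 1.6                  # m/s baseline
    b_t_score: float = 0.25          # m/s per T-score unit
    b_tstt: float = 0.15             # m/s per cm of soft tissue
    b_age: float = 0.02              # m/s per year past 70
    v_c0_floor: float = 0.3          # m/s
    angle_curvature: float = 0.6
    slope: float = 10.0              # mm/(m/s)
    protector_shift_mean: float = 0.5   # m/s
    protector_shift_sd: float = 0.1
    protector_shift_floor: float = 0.05
    noise_sd: float = 0.0            # mm; the FE-style oracle is deterministic by default

    def __post_init__(self) -> None:
        for name in ("b0", "b_t_score", "b_tstt", "b_age"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"link coefficient {name} must be finite")


def _truncnorm_loc_for_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean.

    Sampling a truncated normal centred at the target mean biases the sample
    mean whenever the target sits near a bound (the FRAX-HFP strata are the
    worst case); solving for the location removes that bias so per-stratum
    sample means converge to the printed targets.
    """
    if not (lo < mean < hi):
        raise CohortSpecError(
            f"target mean {mean} outside truncation bounds [{lo}, {hi}]"
        )

    def shifted_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    # Truncated mean is increasing in loc; bracket generously.
    lo_loc, hi_loc = mean - 6 * sd, mean + 6 * sd
    return float(optimize.brentq(shifted_mean, lo_loc, hi_loc, xtol=1e-10))


def _sample_covariate(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd < 0:
        raise CohortSpecError("SD must be non-negative")
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    loc = _truncnorm_loc_for_mean(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def generate_cohort(
    strata: Mapping[tuple[str, str], Mapping[str, tuple[float, float]]] | None = None,
    n_per_stratum: int = 35,
    seed: int = 0,
) -> list[SubjectCovariates]:
    """Draw ``n_per_stratum`` virtual subjects from every sex x ethnicity stratum.

    Covariates are sampled independently within a stratum from truncated
    normals matching the stratum's (mean, SD); BMI is recomputed from the
    sampled weight and height.  Identical seed and spec give an identical
    cohort.
    """
    if strata is None:
        strata = DEFAULT_STRATA
    if n_per_stratum < 1:
        raise CohortSpecError("n_per_stratum must be >= 1")

    subjects: list[SubjectCovariates] = []
    for idx, (key, spec) in enumerate(strata.items()):
        sex, ethnicity = key
        if sex not in SEX_LEVELS or ethnicity not in ETHNICITY_LEVELS:
            raise CohortSpecError(f"unknown stratum label {key!r}")
        missing = [f for f in COVARIATE_FIELDS if f not in spec]
        if missing:
            raise CohortSpecError(f"stratum {key!r} missing covariates: {missing}")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), idx]))
        draws = {}
        for covariate in COVARIATE_FIELDS:
            mean, sd = spec[covariate]
            lo, hi = TRUNCATION_BOUNDS[covariate]
            draws[covariate] = _sample_covariate(mean, sd, lo, hi, n_per_stratum, rng)
        for i in range(n_per_stratum):
            weight = float(draws["weight"][i])
            height = float(draws["height"][i])
            subjects.append(
                SubjectCovariates(
                    subject_id=f"{sex}-{ethnicity}-{i + 1:03d}",
                    sex=sex,
                    ethnicity=ethnicity,
                    age=float(draws["age"][i]),
                    weight=weight,
                    height=height,
                    bmi=weight / (height / 100.0) ** 2,
                    tstt=float(draws["tstt"][i]),
                    t_score=float(draws["t_score"][i]),
                    abmd=float(draws["abmd"][i]),
                    frax_hfp=float(draws["frax_hfp"][i]),
                )
            )
    return subjects


_COHORT_COLUMNS = [
    "subject_id", "sex", "ethnicity", "age", "weight", "height", "bmi",
    "tstt", "t_score", "abmd", "frax_hfp",
]


def cohort_to_frame(subjects: Sequence[SubjectCovariates]) -> pd.DataFrame:
    """Tabulate a cohort, one row per subject, with a fixed column order."""
    return pd.DataFrame([vars(s) for s in subjects], columns=_COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectCovariates]:
    return [SubjectCovariates(**row) for row in frame[_COHORT_COLUMNS].to_dict("records")]


def assign_response_params(
    subject: SubjectCovariates,
    link: LinkSpec | None = None,
    seed: int = 0,
) -> FractureResponseParams:
    """Map a subject's covariates to latent fracture-response parameters.

    The fracture-onset velocity rises with T-score and TSTT and falls with
    age; the hip-protector shift gets mild subject-to-subject variation
    (seeded) around the link's mean, floored strictly above zero.
    """
    link = link or LinkSpec()
    v_c0 = (
        link.b0
        + link.b_t_score * subject.t_score
        + link.b_tstt * subject.tstt
        - link.b_age * (subject.age - 70.0)
    )
    v_c0 = max(v_c0, link.v_c0_floor)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2**20]))
    shift = max(
        link.protector_shift_floor,
        float(rng.normal(link.protector_shift_mean, link.protector_shift_sd)),
    )
    return FractureResponseParams(
        v_c0=v_c0,
        angle_curvature=link.angle_curvature,
        slope=link.slope,
        protector_shift=shift,
        noise_sd=link.noise_sd,
    )


def fracture_onset_velocity(
    params: FractureResponseParams,
    fall_angle: float | np.ndarray,
    protector: bool = False,
):
    """Velocity at which fracture length becomes nonzero (the ramp origin)."""
    theta = np.asarray(fall_angle, dtype=float)
    v_c = params.v_c0 * (1.0 + params.angle_curvature * (theta / 90.0) ** 2)
    if protector:
        v_c = v_c + params.protector_shift * np.cos(np.deg2rad(theta)) ** 2
    return v_c if v_c.ndim else float(v_c)


def critical_velocity_true(
    params: FractureResponseParams,
    fall_angle: float | np.ndarray,
    protector: bool = False,
    threshold: float = FRACTURE_LENGTH_THRESHOLD_MM,
):
    """Closed-form minimum velocity at which fracture length reaches ``threshold``."""
    onset = fracture_onset_velocity(params, fall_angle, protector)
    return onset + threshold / params.slope


def oracle_fracture_length(
    params: FractureResponseParams,
    fall_angle: float,
    impact_velocity: float,
    protector: bool = False,
    rng: np.random.Generator | int | None = None,
) -> FallSimRecord:
    """Evaluate the fracture-length response surface at one fall configuration.

    Deterministic core ``FxL = slope * max(0, v - v_c(angle))``; optional
    Gaussian observation noise (SD ``params.noise_sd``) is added and the
    result floored at zero.
    """
    if not -90.0 <= fall_angle <= 90.0:
        raise ValueError(f"fall_angle {fall_angle} outside [-90, 90] deg")
    if not impact_velocity > 0:
        raise ValueError("impact_velocity must be positive")
    v_c = fracture_onset_velocity(params, fall_angle, protector)
    fxl = params.slope * max(0.0, impact_velocity - v_c)
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng or seed")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        fxl = max(0.0, fxl + float(rng.normal(0.0, params.noise_sd)))
    return FallSimRecord(
        fall_angle=float(fall_angle),
        impact_velocity=float(impact_velocity),
        fracture_length=float(fxl),
        protector=bool(protector),
        fractured=fxl >= FRACTURE_LENGTH_THRESHOLD_MM,
    )


def records_to_frame(records: Sequence[FallSimRecord]) -> pd.DataFrame:
    """Tabulate simulation records (JSONL/CSV round-trips go through this)."""
    return pd.DataFrame(
        [vars(r) for r in records],
        columns=["fall_angle", "impact_velocity", "fracture_length", "protector", "fractured"],
    )
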