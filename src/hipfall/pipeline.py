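"""End-to-end in-silico trial orchestration.

Generate a virtual cohort, run the budgeted active-learning surrogate per
subject with and without a hip protector, convert the two critical-velocity
curves into fracture probabilities, and summarize the trial: stratum means,
relative risks, compliance adjustment, RR classification, and agreement /
reclassification against FRAX-based risk classification.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import stats
from .cohort import (
    DEFAULT_STRATA,
    LinkSpec,
    assign_response_params,
    cohort_to_frame,
    generate_cohort,
    oracle_fracture_length,
)
from .fall_risk import FallConfigModel, RiskEstimate, compute_pfx, relative_risk, risk_table
from .stats import AgreementCounts
from .surrogate import SurrogateConfig, active_learning_loop, extract_critical_velocity

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_trial", "TrialResult"]


class ConfigError(ValueError):
    """Aggregated configuration problems; ``errors`` lists every violation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted configuration of one in-silico trial."""

    n_per_stratum: int = 35
    strata: Mapping[tuple[str, str], Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_STRATA
    )
    link: LinkSpec = field(default_factory=LinkSpec)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    fall: FallConfigModel = field(default_factory=FallConfigModel)
    frax_threshold: float = stats.FRAX_HIGH_RISK_THRESHOLD
    rr_threshold: float = stats.RR_HIGH_THRESHOLD
    compliance: float = 0.5
    seed: int = 0
    outdir: str | None = None


_SECTION_TYPES = {
    "link": LinkSpec,
    "surrogate": SurrogateConfig,
    "fall": FallConfigModel,
}


def validate_config(raw: Mapping[str, Any] | None = None) -> RunConfig:
    """Build a RunConfig from a (possibly partial) plain mapping.

    Defaults fill every omitted key; every violation is reported at once,
    each error naming the offending key.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    kwargs: dict[str, Any] = {}

    for section, cls in _SECTION_TYPES.items():
        spec = raw.pop(section, {})
        if dataclasses.is_dataclass(spec) and isinstance(spec, cls):
            kwargs[section] = spec
            continue
        if not isinstance(spec, Mapping):
            errors.append(f"{section}: expected a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(spec) - valid_fields
        if unknown:
            errors.append(f"{section}: unknown keys {sorted(unknown)}")
        try:
            clean = {k: v for k, v in spec.items() if k in valid_fields}
            for key in ("angle_bounds", "velocity_bounds", "constant_bounds",
                        "length_scale_bounds", "dot_sigma0_bounds", "noise_bounds",
                        "segment_bounds", "segment_masses"):
                if key in clean and isinstance(clean[key], list):
                    clean[key] = tuple(clean[key])
            kwargs[section] = cls(**clean)
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")

    scalar_checks = {
        "n_per_stratum": lambda v: int(v) >= 1 or "n_per_stratum must be >= 1",
        "frax_threshold": lambda v: float(v) >= 0 or "frax_threshold must be >= 0",
        "rr_threshold": lambda v: float(v) >= 0 or "rr_threshold must be >= 0",
        "compliance": lambda v: 0 <= float(v) <= 1 or "compliance must be in [0, 1]",
        "seed": lambda v: True,
        "outdir": lambda v: True,
    }
    if "strata" in raw:
        strata_raw = raw.pop("strata")
        try:
            parsed = {}
            for key, spec in strata_raw.items():
                sex, eth = key.split("/", 1) if isinstance(key, str) else key
                parsed[(sex, eth)] = {k: tuple(v) for k, v in spec.items()}
            kwargs["strata"] = parsed
        except Exception as exc:
            errors.append(f"strata: {exc}")
    for key, check in scalar_checks.items():
        if key in raw:
            value = raw.pop(key)
            try:
                result = check(value)
                if result is not True:
                    errors.append(str(result))
                else:
                    kwargs[key] = value
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
    if raw:
        errors.append(f"unknown top-level keys {sorted(raw)}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(**kwargs)


@dataclass
class TrialResult:
    """Everything one trial run produces."""

    cohort: pd.DataFrame
    risks: pd.DataFrame
    report: dict
    curves: dict[tuple[str, bool], Any]
    records: dict[tuple[str, bool], list]
    oracle_calls: int
    events: list[dict]


def _subject_seed(base: int, idx: int) -> int:
    return int((int(base) * 1000003 + 7919 * idx + 1) % 2**31)


def _summarize(sub: pd.DataFrame, compliance: float, rr_threshold: float) -> dict:
    rr = sub["rr"].dropna()
    mean_rr = float(rr.mean()) if len(rr) else None
    return {
        "n": int(len(sub)),
        "mean_p_fx": float(sub["p_fx"].mean()),
        "mean_p_fx_hp": float(sub["p_fx_hp"].mean()),
        "n_rr_defined": int(len(rr)),
        "mean_rr": mean_rr,
        "adjusted_rr": None if mean_rr is None else stats.compliance_adjust(mean_rr, compliance),
        "n_rr_high": int((rr > rr_threshold).sum()),
    }


def run_trial(config: RunConfig) -> TrialResult:
    """Run the full in-silico hip-protector trial described by ``config``."""
    t0 = time.perf_counter()
    events: list[dict] = []
    subjects = generate_cohort(config.strata, config.n_per_stratum, config.seed)
    cohort = cohort_to_frame(subjects)
    events.append({"stage": "cohort", "n": len(subjects), "seed": config.seed,
                   "elapsed": time.perf_counter() - t0})

    oracle_calls = 0

    def counted_oracle(params, angle, velocity, protector=False, rng=None):
        nonlocal oracle_calls
        oracle_calls += 1
        return oracle_fracture_length(params, angle, velocity, protector=protector, rng=rng)

    estimates: list[RiskEstimate] = []
    curves: dict[tuple[str, bool], Any] = {}
    all_records: dict[tuple[str, bool], list] = {}
    for idx, subject in enumerate(subjects):
        s_seed = _subject_seed(config.seed, idx)
        params = assign_response_params(subject, config.link, seed=s_seed)
        pfx_by_arm = {}
        for protector in (False, True):
            t_sub = time.perf_counter()
            cfg = replace(config.surrogate, seed=_subject_seed(s_seed, int(protector)))
            model, records = active_learning_loop(counted_oracle, params, cfg, protector)
            curve = extract_critical_velocity(model, cfg, protector=protector)
            pfx_by_arm[protector] = compute_pfx(curve, config.fall)
            curves[(subject.subject_id, protector)] = curve
            all_records[(subject.subject_id, protector)] = records
            events.append({
                "stage": "surrogate", "subject_id": subject.subject_id,
                "protector": protector, "seed": cfg.seed,
                "oracle_calls": len(records),
                "elapsed": time.perf_counter() - t_sub,
            })
        estimates.append(RiskEstimate(
            subject_id=subject.subject_id,
            p_fx=pfx_by_arm[False],
            p_fx_hp=pfx_by_arm[True],
            rr=relative_risk(pfx_by_arm[False], pfx_by_arm[True]),
        ))

    risks = risk_table(estimates).merge(cohort, on="subject_id")

    # Agreement of FRAX-based classification with the model-based one
    # (needs >= 3 subjects for the tertile split).
    agreement = None
    if len(risks) >= 3:
        frax_cls = [stats.classify_frax(f, config.frax_threshold) for f in risks["frax_hfp"]]
        pfx_cls, tertile_threshold = stats.classify_pfx_tertile(risks["p_fx"].tolist())
        counts = AgreementCounts(
            both_high=sum(f == "high" and p == "high" for f, p in zip(frax_cls, pfx_cls)),
            both_low=sum(f == "low" and p == "low" for f, p in zip(frax_cls, pfx_cls)),
            down=sum(f == "high" and p == "low" for f, p in zip(frax_cls, pfx_cls)),
            up=sum(f == "low" and p == "high" for f, p in zip(frax_cls, pfx_cls)),
        )
        down_pct, net_down_pct = stats.reclassification(counts)
        agreement = {
            "counts": dataclasses.asdict(counts),
            "kappa": stats.cohens_kappa(counts),
            "mcnemar_p": stats.mcnemar_test(counts) if counts.down + counts.up > 0 else 1.0,
            "down_pct": down_pct,
            "net_down_pct": net_down_pct,
            "pfx_tertile_threshold": tertile_threshold,
            "frax_threshold": config.frax_threshold,
        }

    report = {
        "seed": config.seed,
        "n_subjects": len(subjects),
        "oracle_calls": oracle_calls,
        "budget": config.surrogate.budget,
        "overall": _summarize(risks, config.compliance, config.rr_threshold),
        "by_sex": {
            sex: _summarize(sub, config.compliance, config.rr_threshold)
            for sex, sub in risks.groupby("sex", sort=True)
        },
        "by_stratum": {
            f"{sex}/{eth}": _summarize(sub, config.compliance, config.rr_threshold)
            for (sex, eth), sub in risks.groupby(["sex", "ethnicity"], sort=True)
        },
        "compliance": config.compliance,
        "agreement": agreement,
    }
    events.append({"stage": "report", "elapsed": time.perf_counter() - t0})

    result = TrialResult(
        cohort=cohort, risks=risks, report=report, curves=curves,
        records=all_records, oracle_calls=oracle_calls, events=events,
    )
    if config.outdir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: TrialResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.cohort.to_csv(outdir / "cohort.csv", index=False)
    result.risks.to_csv(outdir / "risks.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2))
    curve_dir = outdir / "curves"
    curve_dir.mkdir(exist_ok=True)
    for (subject_id, protector), curve in result.curves.items():
        arm = "protected" if protector else "unprotected"
        curve.to_csv(curve_dir / f"{subject_id}__{arm}.csv")
    with (outdir / "trace.jsonl").open("w") as fh:
        for event in result.events:
            fh.write(json.dumps(event) + "\n")
    with (outdir / "simulations.jsonl").open("w") as fh:
        for (subject_id, protector), records in result.records.items():
            for rec in records:
                row = {"subject_id": subject_id, **dataclasses.asdict(rec)}
                fh.write(json.dumps(row) + "\n")
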