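"""Cohort-level statistics for the in-silico hip-protector trial.

Covers risk classification (FRAX 10-yr hip-fracture probability vs the
model-based P_Fx), paired agreement (Cohen's kappa, McNemar), down- and
net-down-classification, ethnicity odds ratios with Fisher exact p-values,
the compliance-adjusted relative risk, and the two-sample power-based
sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementCounts",
    "ContingencyTable2x2",
    "PowerSpec",
    "classify_frax",
    "classify_pfx_tertile",
    "classify_rr",
    "cohens_kappa",
    "mcnemar_test",
    "reclassification",
    "odds_ratio",
    "compliance_adjust",
    "format_rr",
    "sample_size",
]

FRAX_HIGH_RISK_THRESHOLD = 2.0   # % 10-yr hip-fracture probability
RR_HIGH_THRESHOLD = 0.4          # pooled hip-protector RCT relative risk


@dataclass(frozen=True)
class AgreementCounts:
    """Paired high/low classifications: reference tool vs comparator.

    ``down`` = reference high, comparator low; ``up`` = reference low,
    comparator high.
    """

    both_high: int
    both_low: int
    down: int
    up: int

    def __post_init__(self) -> None:
        if min(self.both_high, self.both_low, self.down, self.up) < 0:
            raise ValueError("agreement counts must be non-negative")

    @property
    def total(self) -> int:
        return self.both_high + self.both_low + self.down + self.up


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = groups, columns = (high risk, low risk)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample design: standardized effect size, alpha, target power."""

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if not self.effect_size_d > 0:
            raise ValueError("effect size d must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")


def classify_frax(frax_hfp: float, threshold: float = FRAX_HIGH_RISK_THRESHOLD) -> str:
    """High risk iff FRAX-HFP strictly exceeds the threshold (default 2%)."""
    if frax_hfp < 0:
        raise ValueError("FRAX-HFP must be non-negative")
    return "high" if frax_hfp > threshold else "low"


def classify_pfx_tertile(pfx_values: Sequence[float]) -> tuple[list[str], float]:
    """Classify P_Fx values against their own top tertile.

    The threshold is the 66.67th percentile (linear-interpolation quantile);
    a subject is high risk iff strictly above it, so threshold ties are low
    risk.  Returns the labels and the threshold used.
    """
    values = np.asarray(pfx_values, dtype=float)
    if values.size < 3:
        raise ValueError("tertile classification needs at least 3 values")
    threshold = float(np.quantile(values, 2.0 / 3.0))
    return ["high" if v > threshold else "low" for v in values], threshold


def classify_rr(rr: float, threshold: float = RR_HIGH_THRESHOLD) -> str:
    """High RR (poor protector benefit) iff RR strictly exceeds 0.4."""
    return "high" if rr > threshold else "low"


def cohens_kappa(counts: AgreementCounts) -> float | None:
    """Chance-corrected agreement between the two classifiers.

    Returns None when the expected agreement is 1 (degenerate marginals).
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty agreement table")
    po = (counts.both_high + counts.both_low) / n
    ref_high = (counts.both_high + counts.down) / n
    cmp_high = (counts.both_high + counts.up) / n
    pe = ref_high * cmp_high + (1 - ref_high) * (1 - cmp_high)
    if pe >= 1.0 - 1e-15:
        return None
    return (po - pe) / (1 - pe)


#: Below this many discordant pairs McNemar uses the exact binomial test.
MCNEMAR_EXACT_LIMIT = 25


def mcnemar_test(counts: AgreementCounts) -> float:
    """Two-sided McNemar p-value on the discordant pairs.

    Exact binomial when down + up < 25, otherwise chi-square with
    continuity correction.  No discordance gives p = 1 by convention.
    """
    n_disc = counts.down + counts.up
    if n_disc == 0:
        return 1.0
    if n_disc < MCNEMAR_EXACT_LIMIT:
        return float(sps.binomtest(counts.down, n_disc, 0.5).pvalue)
    chi2 = (abs(counts.down - counts.up) - 1) ** 2 / n_disc
    return float(sps.chi2.sf(chi2, df=1))


def reclassification(counts: AgreementCounts) -> tuple[float | None, float]:
    """(down-classification %, net down-classification %).

    Down % is among reference-tool high-risk subjects (None if there are
    none); net down % is (down - up) over all subjects.
    """
    n = counts.total
    if n == 0:
        raise ValueError("empty agreement table")
    ref_high = counts.both_high + counts.down
    down_pct = None if ref_high == 0 else 100.0 * counts.down / ref_high
    net_down_pct = 100.0 * (counts.down - counts.up) / n
    return down_pct, net_down_pct


def odds_ratio(table: ContingencyTable2x2) -> tuple[float | None, tuple[float, float] | None, float]:
    """(OR, 95% CI, two-sided Fisher exact p) for a 2x2 table.

    The OR and its Wald log CI use Haldane-Anscombe +0.5 on every cell iff
    any cell is zero; Fisher's p is computed on the raw counts.  Tables
    with an empty margin have undefined OR/CI (None) but still a p-value.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if min(a + b, c + d, a + c, b + d) == 0:
        return None, None, p
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se))
    return or_, ci, p


def compliance_adjust(rr: float, compliance: float) -> float:
    """Mix the full-compliance RR with no effect: c*RR + (1 - c).

    A subject wears the protector a fraction ``compliance`` of fall
    exposures; unworn exposures carry baseline risk (RR 1).
    """
    if rr < 0:
        raise ValueError("RR must be non-negative")
    if not 0 <= compliance <= 1:
        raise ValueError("compliance must be in [0, 1]")
    return compliance * rr + (1.0 - compliance)


def format_rr(rr: float, decimals: int = 2) -> str:
    """Format an RR rounding half away from zero (0.715 -> '0.72')."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(rr)).quantize(q, rounding=ROUND_HALF_UP))


def sample_size(spec: PowerSpec) -> int:
    """Per-group n detecting effect d: 2 (z_{1-a/2} + z_power)^2 / d^2.

    Normal approximation, rounded to the nearest integer, floored at 2.
    """
    z = sps.norm.ppf(1 - spec.alpha / 2) + sps.norm.ppf(spec.power)
    raw = 2.0 * z**2 / spec.effect_size_d**2
    return max(2, int(math.floor(raw + 0.5)))
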