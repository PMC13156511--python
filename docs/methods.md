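# Methods

## The fracture-length oracle

The package replaces a subject-specific finite-element fall solver with a
parametric response surface chosen to be the simplest one with an exact,
closed-form limit state:

    FxL(v, θ) = slope · max(0, v − v_c(θ))                     [mm]
    v_c(θ)    = v_c0 · (1 + κ_a (θ/90)²)                       [m/s]
    with protector:  v_c(θ) += s · cos²(θ)

where θ is the fall angle in degrees (0 = lateral), `slope` the
fracture-length growth rate above onset (default 10 mm per m/s), `v_c0` the
lateral onset velocity, `κ_a ≥ 0` the angular curvature (default 0.6;
lateral impacts are the worst case, anterior/posterior progressively safer)
and `s ≥ 0` the protector shift, maximal laterally and vanishing at ±90°,
reflecting that soft-shell protectors attenuate lateral and
posterior-lateral impacts. The true critical velocity (smallest v with
FxL ≥ 10 mm) is exactly `v_c(θ) + 10/slope`, which is what every surrogate
test validates against. Gaussian observation noise (SD `noise_sd`, floored
at 0 mm) is off by default — the finite-element analogue is deterministic
per configuration — and exists as an opt-in stress test for the white-noise
kernel term.

Covariates enter through a linear link with a floor:

    v_c0 = b0 + b_T·T-score + b_S·TSTT − b_A·(age − 70),  clamped ≥ 0.3 m/s

with defaults b0 = 1.6, b_T = 0.25, b_S = 0.15 (m/s per unit) and
b_A = 0.02 m/s per year. These encode the directions reported for real
cohorts (higher fracture risk with lower T-score, thinner trochanteric soft
tissue, higher age) and were set once so that stratum-mean subjects land at
lateral fracture-onset speeds of roughly 2.4–3 m/s, i.e. fracture
probabilities of the order observed clinically (single-digit percent),
with the Chinese > Malay > Indian risk gradient emerging from the stratum
covariate means rather than being coded in. The protector shift is drawn
per subject from N(0.5, 0.1²) m/s floored at 0.05, giving mean relative
risks around 0.3–0.45 under full compliance. Magnitudes are emulations,
not calibrations: no per-subject finite-element response surfaces exist to
fit against, so only orderings and mechanisms are meaningful.

## Synthetic cohort

Subjects are drawn per sex × ethnicity stratum (three ethnicities, 35 per
stratum by default) from independent truncated normals per covariate, with
physiological truncation bounds (age 55–100 yr, weight 30–150 kg, height
130–200 cm, TSTT 0.5–8 cm, T-score −5–2, aBMD 0.2–1.5 g/cm², FRAX-HFP
0–30%). Because truncation shifts the mean of a normal centred at the
target (severely so for FRAX-HFP, whose mean sits within one SD of zero),
the sampler solves for the location parameter whose truncated mean equals
the target, so per-stratum sample means converge to the specified values;
the realized SD is then somewhat below the nominal one for heavily
truncated covariates — a deliberate trade, since downstream statistics key
on means and orderings. BMI is always recomputed from sampled weight and
height. Covariates are sampled independently within stratum (only marginal
moments are specified); correlation structure of real cohorts is not
emulated, so tests passing here say nothing about covariate-interaction
effects in real data. Degenerate SD = 0 strata reproduce the means exactly;
negative SDs are rejected.

## Surrogate and active learning

The GP uses `C · RBF · DotProduct + WhiteKernel` on scaled inputs: angle
divided by 90 (→ [−1, 1]) and velocity centred at the domain midpoint and
divided by the half-range. Scaling happens only inside the GP so the
acquisition's 10³ mm⁻² rate acts on raw millimetres. Hyperparameter bounds:
constant variance 10⁻⁴–10⁴ mm², length scale 10⁻²–10² (scaled units),
dot-product σ₀ 10⁻³–10³, white noise 10⁻⁸–1 mm². The velocity domain is
0.5–4.5 m/s (≈ mean + 3.75 SD of the impact-speed distribution, covering
effectively all exposure mass); angles span the full ±90°.

The initial design is fixed and deterministic: (0°, v_lo), (0°, v_hi),
(−60°, v_mid), (+60°, v_mid), truncated to `n_initial` (≥3) points. The
first fit maximizes the marginal likelihood from 5 seeded random restarts;
each subsequent refit warm-starts from the incumbent hyperparameters with
one extra random restart (`refit_restarts`), since adding a single point
rarely moves the optimum basin — this keeps a full two-arm trial of 210
subjects within minutes while measurably *improving* curve recovery over
cold restarts in our tests.

The acquisition value f = −exp(−10³(10 − μ)²)·σ underflows to exactly zero
except in a sub-millimetre band around the predicted limit state, so the
optimizer works on the strictly monotone transform
log(−f) = −10³(10 − μ)² + log σ, which has the identical optimum and finite
gradients everywhere. It is evaluated on a 19 × 9 (angle × velocity) grid;
bounded L-BFGS-B polishes from the best eight grid starts plus the
incumbent best, ties resolved to the first-found point in row-major grid
order. The search domain is shrunk by a 10⁻⁶ relative margin so proposals
are strictly interior. If σ vanishes everywhere the first grid point is the
documented fallback. With a noiseless oracle the acquisition tends to
re-query points already pinned to the level set once the curve is resolved;
the budget beyond that is spent confirming, not exploring, which is the
acquisition's stated intent.

Curve extraction scans 200 velocities per grid angle (1° grid by default),
brackets the first upward crossing of the 10-mm posterior mean and bisects
it to 10⁻⁴ m/s, taking the *smallest* root when several exist. Angles whose
posterior mean never reaches 10 mm in range get a +inf sentinel
(serialized literally as `inf` in curve CSVs); angles at or above threshold
at the lower bound get the lower bound.

## Risk integration

The fall-angle density is piecewise uniform over the three directional
segments — uniform-within-segment is the maximum-entropy choice given only
segment masses. The impact speed is normal (2.14, 0.63²) m/s truncated at
zero and renormalized; the untruncated mass below zero is 3.4 × 10⁻⁴,
negligible but formally required for a speed. A critical velocity at or
below the truncation point maps to exceedance probability exactly 1, and
the +inf sentinel to exactly 0. The quadrature is trapezoid on the curve's
grid, composite per segment so the density discontinuities at ±30° are
handled exactly; the result is scaled by the 0.4 hip-impact factor and
clamped to [0, 40]%. A Monte-Carlo mode samples (angle, speed) pairs and
interpolates the curve linearly in velocity; it exists as an independent
cross-check and rejects curves containing the +inf sentinel, for which
interpolation is ill-defined (the quadrature path handles those).

Per-subject RR = P_Fx_HP / P_Fx is undefined at zero baseline and such
subjects are excluded from cohort RR means. Compliance adjustment is the
mixture c·RR + (1 − c), i.e. a fraction c of fall exposures protected;
formatted RRs round half away from zero.

## Cohort statistics

- FRAX classification: high iff FRAX-HFP strictly greater than 2%.
- Model classification: high iff P_Fx strictly above its top tertile
  (66.67th percentile, linear-interpolation quantile); ties at the
  threshold are low risk. The tertile is used because no established
  absolute P_Fx threshold exists and it is robust to outliers.
- Cohen's κ from the 2 × 2 agreement counts with marginal-product expected
  agreement; undefined (None) when expected agreement is 1.
- McNemar: exact two-sided binomial on the discordant pairs when their
  number is below 25, otherwise chi-square with continuity correction;
  p = 1 by convention at zero discordance.
- Down-classification is the share of reference-high subjects the model
  down-classifies; net down-classification is (down − up)/N. Note
  (162 − 27)/700 = 19.29% at two decimals.
- Odds ratios ad/bc with Haldane–Anscombe +0.5 on every cell only when a
  cell is zero; Wald log CI on the (possibly corrected) cells; Fisher exact
  p on the raw counts (delegated to scipy, and verified against a full
  hypergeometric enumeration in the tests).
- Sample size: normal-approximation two-sample formula, rounded to the
  nearest integer (d = 0.81, α = 0.05, power 0.90 gives raw 32.03 → 32),
  floored at 2 per group.

## Problem sizes and numerical choices

Default test and acceptance runs use 20 subjects for curve-recovery
properties, 10⁶ draws for Monte-Carlo cross-checks, 10⁴ subjects for
law-of-large-numbers cohort checks, and exhaustive 2 × 2 enumeration up to
N = 40 — sizes chosen so the full suite completes in a few minutes while
keeping each check statistically meaningful. Determinism: every stochastic
component takes an explicit seed; per-subject and per-arm seeds are derived
from the trial seed by fixed integer arithmetic, and identical configs give
byte-identical outputs.

## Limitations

- Oracle magnitudes are uncalibrated (no subject-level simulation data
  exist to calibrate against); cohort-level fracture probabilities are
  order-of-magnitude emulations only.
- No fall-frequency or fall-initiation modelling: P_Fx is per-fall, not
  per-year, and physiological/environmental determinants of falling are out
  of scope.
- Covariate independence within stratum; no age adjustment of odds ratios
  (a routine covariate regression, omitted as the per-subject data it needs
  are synthetic here anyway).
- The ramp-with-quadratic-angle oracle is smooth and monotone by
  construction; surrogate performance on it bounds nothing about
  non-monotone or discontinuous real response surfaces.
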