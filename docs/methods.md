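# Methods

## The problem

EU pig-carcass grading predicts lean meat percentage (LMP) from probe
measurements instead of dissecting every carcass.  A device's prediction
equation must be established in an authorization trial: a stratified
dissection sample, a reference LMP per carcass, a regression fit, and a
cross-validated error bound.  Since 2018 the reference LMP must correct
the partial (four-cut) dissection result with a scaling factor estimated
from a total-dissection subsample run in parallel.  `leangrade` models
this workflow end to end.

## Synthetic population model

Each carcass carries (hot weight `W` kg, backfat `F2` mm, loin depth
`M2` mm) drawn from a trivariate Gaussian, truncated by rejection to
`W ∈ [60, 120]`, `F2 ∈ [3, 55]`, `M2 ∈ [21, 99]` (the observed range of
the national survey the defaults emulate).  Defaults: `W ~ 95.0 ± 10.6`,
`F2 ~ 13.86 ± 4.26`, `M2 ~ 62.20 ± 8.40`, corr(W, F2) = 0.15 (fatter pigs
are heavier; survey group summaries show fat rising across weight groups),
corr(F2, M2) = 0 and corr(W, M2) = 0 (no marginal evidence either way; both
correlations are configurable).  Sex is i.i.d. Bernoulli with a 0.5 gilt
fraction, reflecting the half-gilts / half-castrates selection rule.

The latent total-dissection LMP is linear in the measurements,

```
YTD = b0 + b_F·F2 + b_M·M2 + eps,   eps ~ N(0, sigma_ytd)
```

with the 2023 CGM coefficients (60.7538, −0.6465, +0.1243) as the
generating truth and `sigma_ytd = 2.2` LMP points, matching the trial's
reported prediction error level.  The observable partial-dissection LMP is

```
YPD = YTD / sf_true + delta,   delta ~ N(0, sigma_delta)
```

with `sf_true = 0.89` (the partial/total dissection ratio the EU has used
since 2008) and `sigma_delta = 0.5` LMP points — the between-butcher
repeatability of partial dissection is reported only qualitatively
(correlation with total dissection "very high"; inter-butcher differences
up to ~2 pp), so a small default was fixed once and left configurable.
Noise draws that would push an LMP outside (0, 100) are redrawn.

**Truncation bias.** Because the marginals are truncated, their means/SDs
differ slightly from the requested Gaussian parameters (the weight
marginal's truncated mean is ≈ 94.75 vs the requested 95.0).  The
moment-recovery tests therefore compare sample moments against the
truncated-normal expectation, not the raw parameters; at the default
correlation of 0.15 the 1-d truncated normal predicts the box-truncated
multivariate marginals to < 0.05 units.

**Cut weights.** For dissection arithmetic the generator realizes joint
weights for tenderloin/shoulder/loin/ham/belly as Dirichlet-perturbed
shares (base proportions 0.015/0.25/0.23/0.30/0.20 of a 0.75 cut-out
fraction of the half carcass; concentration 200).  These proportions are
not published; they only shape internal consistency, never a reported
statistic, because lean weights are then allocated proportionally across
the four cuts and scaled so that the partial-dissection formula reproduces
the carcass's `YPD` exactly, and the total lean weight so that the
total-dissection formula reproduces `YTD` exactly (round-trip tolerance
1e−9).  Infeasible demands (required lean above the joint mass) are
refused.

**What the generator does not emulate:** genetics, farm or breed
structure, growth, seasonal drift, butcher identity, carcass-splitting
asymmetry, and the extreme non-Gaussian tail of the real population (the
real survey contains carcasses down to 30.5% LMP that a Gaussian at these
moments essentially never produces).  Tests passing on this generator
therefore validate the *arithmetic and statistical machinery* of the
workflow, not the biological representativeness of any particular trial.
In particular, the generator is not expected to reproduce the real
population's exact SEUROP class shares.

## Stratified selection

The plan is a 3×3 grid: fat groups with upper-inclusive boundaries at 10
and 18 mm, weight groups at 84.4 and 105.5 kg within the admissible range
60–120 kg.  Published group labels are integer-gapped ("0–10", "11–18");
upper-inclusive half-open bins were chosen so every positive measurement is
classifiable, and the same rule maps the weight gap (84.4, 84.5) to the
middle group.  Required counts default to

```
            fat 1   fat 2   fat 3
weight A      7      18       7     (32)
weight B     16      30      16     (62)
weight C      7      18       7     (32)
             (30)    (66)    (30)   total 126
```

with a 1/2/1-per-row total-dissection subsample totalling 12 (≈10% of the
sample).  Selection within a cell is uniform without replacement with a
fixed seed — trials select on the slaughter line with no published
tie-break rule, so an unbiased draw is the neutral choice.  Under-filled
cells are recorded as shortfalls, not errors: real trials tolerate
deficits of a few carcasses per cell, and the pipeline mirrors that by
flagging and continuing.  `validate_plan` checks the 1:2:1 marginals and
the ~10% subsample share (default relative tolerance 0.2) as a report,
never a gate.

## Scaling factor and reference LMP

`SF = mean(YTD) / mean(YPD)` over the paired subsample — the ratio of
means, not the mean of per-carcass ratios.  The two conventions agree at
two decimals on typical data but differ in the third decimal; ratio of
means is used because the factor is defined through the two subsample
means.  SF is rounded **half-up to 2 decimals before application**
(`round_to=None` keeps full precision): the published corrected subsample
mean is reproducible only if 67.12 × 0.89 uses the rounded factor.  The
unrounded means stay available for diagnostics.  `LMP_ref = YPD × SF` is
linear, so the corrected mean equals SF times the uncorrected mean exactly.

## Calibration and cross-validation

"PLS-PCR" is implemented as PLS regression (scikit-learn, `scale=False`);
with two centred predictors at full rank, PLS with 2 components, PCR and
OLS coincide, which makes an independent normal-equations solve the
correctness oracle (agreement to 1e−8 is asserted on random instances).
The intercept is derived as `ȳ − β·x̄`.  `n_components ∈ {1, 2}`, default
2.  The cross-validation flavour behind PRESS is taken as leave-one-out —
the classical PRESS definition; `press_loo_rmsep` offers both the explicit
refit loop (valid for any component count) and the closed-form hat-matrix
shortcut `e_i / (1 − h_ii)` (full-rank only), which are verified to agree
to 1e−8.  Authorization is the strict inequality `RMSEP < 2.5`.

Degenerate inputs: collinear predictors are rejected for 2-component fits
(rank check at tolerance 1e−10); LOO needs n ≥ 4; fits need n > number of
components.

## Grading and comparison

SEUROP thresholds (60/55/50/45/40, lower-inclusive) are configuration with
the standard EU scale as default — authorization reports do not restate
them.  Out-of-range predictions are clamped to [0, 100] with a warning
rather than rejected, because real populations do contain extreme
carcasses.  `compare_equations` reports the per-carcass mean shift (which,
by linearity, equals the coefficient deltas evaluated at the sample means
— asserted to 1e−9), the 6×6 class-migration matrix whose marginals
reproduce the two class structures exactly, and LMP histograms in
1-point bins spanning [30, 75].

## Problem sizes and reproducibility

Default test/demonstration sizes: 20 000-carcass populations for
moment-recovery and selection checks, 126-carcass calibration sets, and
200 replicated end-to-end trials (population 3 000 each — enough to fill
the sparsest plan cell, light-weight/fat, with margin) for parameter
recovery.  Estimated coefficients fall within 3 estimated standard errors
of the generating values in ≥ 90% of replicates (unbiasedness), and the
LOO-RMSEP distribution covers the generating residual level: note that
`LMP_ref = SF·(YTD/sf_true + delta)` carries residual SD
`sqrt(sigma_ytd² + (SF·sigma_delta)²) ≈ 2.24` about the linear model, so
RMSEP centres slightly above `sigma_ytd`.

Every stochastic stage takes an explicit integer seed; a pipeline run is
byte-identical across repeats for a fixed config and seed (per-carcass cut
weights use per-index derived seeds; stage timings are logged but kept out
of the report files for this reason).

## Known limitations

- The fitted-equation workflow supports exactly the two-predictor linear
  form; devices with more measurement sites are out of scope.
- One backfat site is modelled; trade names for it (point F, F1, F2) are
  treated as aliases of the same measurement.
- No payment-grid or pricing logic, no device driver integration, no
  modelling of carcass rejection (veterinary confiscation, bad splits)
  beyond strata shortfalls.
- k-fold PRESS is not implemented; leave-one-out only (`cv="loo"` /
  explicit `refit`).
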