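# Methods

`felhoma` implements the statistical machinery used to characterise
insulin-resistance surrogates — HOMA-IR and fasting insulin — in cats:
biological-variation indices from a nested random-effects model, robust
population reference intervals, CT-based body-fat estimation, and the
cohort-level comparisons and regressions that tie adiposity to the
surrogates. This note records the models, the tunable constants and the
design decisions, and what the synthetic-data generators do and do not
emulate.

## HOMA-IR and adiposity classes

HOMA-IR = fasting insulin (mU/L) × fasting glucose (mmol/L) / 22.5, carried
at full precision and rounded to one decimal only in reports. Insulin
assayed in ng/L is converted at the IO boundary (×0.023) and stored in
mU/L only. Clinical adiposity uses the body condition score (BCS): lean is
≤5 on the 1–9 scale or ≤3 on the 1–5 scale. CT adiposity uses body fat
percentage (BF%): lean <35, overweight [35, 45), obese ≥45 — half-open
intervals closed on the left.

## Cohort filtering

Exclusion reasons are evaluated in a fixed order (stressed, underage,
pregnant, non-fasted, diabetes-suspected, assay interference) and each
excluded cat is reported once, under the first reason that applies, which
makes reports deterministic. "Stressed" is an input flag, never inferred.
A cat is diabetes-suspected only when glucose exceeds the threshold
(default 10 mmol/L) *and* fructosamine exceeds the configured laboratory
reference upper bound (default 340 µmol/L — a plausible site value; the
bound is site-configurable and intentionally not hard-coded science).
Hyperglycemic cats with normal or missing fructosamine are retained and
listed for follow-up. The filter is pure and idempotent.

## Biological variation

For an analyte measured in C cats on O occasions with R duplicates, the
model on the natural-log scale is

    ln y_cor = μ + g_c + w_co + e_cor,

with independent Gaussian effects of variance σ²_G (between cats), σ²_I
(within cat, between occasions) and σ²_A (between duplicates, analytical).
Estimation is **unbounded REML**: the restricted likelihood is maximised
without non-negativity constraints, subject only to every stratum variance
(σ²_A, σ²_A + Rσ²_I, σ²_A + Rσ²_I + ORσ²_G on balanced designs) staying
positive. Balanced complete designs use a closed-form likelihood in the
nested-ANOVA sums of squares, so the optimum coincides exactly with the
classical mean-square estimators; unbalanced designs (e.g. one lost
duplicate) use per-cat dense covariance blocks. Optimisation is
Nelder-Mead from a moment-based start; convergence is reported.
Standard errors come from the finite-difference observed information at
the optimum.

Conversions and indices:

* CV (%) from an ln-scale SD by Cole's equation, CV = 100·√(exp(SD²)−1);
  negative point estimates are floored to zero **only** at this conversion
  step (with a warning), preserving the unbounded fit itself.
* 95% confidence intervals are Wald intervals on the *variance* scale
  (estimate ± 1.96·SE), each endpoint mapped through Cole's equation, with
  negative lower endpoints set to zero. The alternative — a delta-method
  interval on the CV scale — was not used because the procedure is defined
  as variance-scale intervals "expressed as CVs".
* Index of individuality II = CV_G/√(CV_I² + CV_A²); values below 0.7
  favour population reference intervals, above 1.7 favour within-subject
  monitoring.
* Reference change value, two-sided at probability 1−α (z = 1.96 by
  default) for ln-normal analytes:
  RCV(%) = 100·exp{±z√(2(σ²_I + σ²_A))}. The increase and decrease limits
  multiply to exactly 100², i.e. the change is symmetric on the ln scale
  and asymmetric in original units. Per-individual monitoring bounds are
  the baseline times these percentages.

An optional pre-fit screen flags (cat, occasion) cells whose ln-scale
duplicate spread lies beyond the Tukey fences of all duplicate spreads.
It is OFF by default and every removal is logged, because outlier
exclusion in repeated-measures panels is a judgement call that should be
visible.

Reporting precision mirrors clinical-chemistry convention: CVs to 1
decimal, II to 2 decimals, RCV to whole percent.

## Reference intervals

The pipeline follows the CLSI EP28-A3 robust procedure for small reference
panels:

1. **Tukey fences**, one pass, on the original scale: values beyond
   1.5×IQR from the quartiles are removed (quartiles by linear
   interpolation).
2. **Box-Cox** power transform; λ maximises the profile log-likelihood on
   the grid [−3, 3] in steps of 0.01 (reproducible, adequate for n up to a
   few hundred). Requires strictly positive data; when the sample contains
   non-positive values (possible for general inputs, not for these
   analytes) the pipeline falls back to the untransformed robust method.
3. **Robust limits**: iterated Tukey-biweight location (c = 3.7, weights
   from MAD-scaled residuals, tolerance 1e−9, ≤100 iterations) and the
   biweight midvariance (c = 9) divided by its asymptotic value at the
   normal (1.01844, obtained by numerical integration) so the scale is
   consistent for σ. Limits are location ± t(0.975, n−1)·s·√(1+1/n),
   giving the central 95%.
4. Back-transform to original units; the lower limit is floored at zero
   for non-negative analytes.
5. **Bootstrap 90% CIs** of both limits: nonparametric resampling of the
   post-screen sample, the full transform+robust pipeline per resample,
   percentile intervals (default B = 5000; a seed is mandatory). The
   adequacy flag is false when either CI is wider than 0.2× the interval
   width (CLSI guidance) — small skewed panels typically fail it, which is
   informative, not an error.

Degenerate spread raises an explicit error. Below n = 40 a warning notes
the limits will be imprecise; below n = 20 the fit is refused.

## Body fat from CT

Pre-masked Hounsfield-unit voxels within [−250, +250] are binned (default
1 HU). After moving-average smoothing (default 5 bins) the fat peak is the
argmax over [−250, −10] HU and the lean soft-tissue peak over [+10, +250]
HU (fat attenuates near −100 HU, lean near +40..60 HU, so the regions are
well separated); ties break toward the window centre, and peak positions
use the bin-centre convention. The split point is the arithmetic midpoint
of the two peaks: voxels at or below it are fat (closed boundary), above
it lean, and BF% = 100·n_fat/(n_fat+n_lean). One-sided histograms raise an
error by default; a documented opt-in returns the degenerate 0%/100%
answer for inputs known to be single-tissue. Segmentation (table, bladder
urine, external objects) is upstream and out of scope.

BCS screening performance against BF% is summarised as NPV
(P(BF-lean | BCS-lean)) and PPV (P(BF-overweight-or-obese |
BCS-overweight)), with BF% as the reference method.

## Cohort statistics

Group differences use the Wilcoxon rank-sum test: exact enumeration when
min(n1, n2) ≤ 12 and the pooled data are tie-free, otherwise the normal
approximation with midranks, tie-corrected variance and continuity
correction (the continuity correction is configurable; which variant the
original analysis software used is not documented). Power is expressed via
Noether's large-sample relation
N = (z_{1−α/2}+z_power)²/(12c(1−c)(p″−½)²), with p″ = P(X<Y) and
c = n1/N; the implementation counts both rejection tails so power tends to
α as p″→½. Associations with BF% use OLS on ln-transformed responses,
reporting the slope, its SE, R², the two-sided p-value, residual
skew/kurtosis diagnostics, and the percent-change reading
100·(exp(10·β)−1) per 10 BF% units. The significance convention is
p < 0.05 with no multiplicity correction, matching the source analysis; an
optional second regressor (e.g. a locomotor-signs flag) is supported as a
covariate, not a separate model family.

## Synthetic data

The generators are pure functions of their parameters (seed included) and
define the test conditions:

* **Cohort**: BF% is truncated normal on [15.3, 61.9]; the parent mean/SD
  are calibrated by root-finding (≈ N(37.3, 17.4²)) so the *truncated*
  distribution has exactly mean 38.0 and SD 11.9. ln(insulin) is linear in
  BF% (slope 0.0225) with Gaussian noise (SD 0.693, giving R² ≈ 0.13);
  ln(glucose) carries the weak slope 0.004 with noise SD 0.29 (CV ≈ 30%,
  matching the observed glucose spread). HOMA-IR is **derived** as the
  exact product formula — never given independent noise — so its implied
  slope is 0.0225 + 0.004 = 0.0265 and its R² lands near 0.15. Keeping the
  small glucose slope (rather than zeroing a non-significant coefficient)
  is what makes the derived HOMA-IR slope sit at the observed value while
  preserving the product identity; setting it to zero is one parameter
  away. BCS classes are the true BF% class corrupted at rates
  P(overweight|BF-lean) = 0.5 and P(lean|BF-overweight) = 0.025, chosen to
  reproduce NPV ≈ 93% and PPV ≈ 74% at the cohort's lean fraction.
  Intercepts put the median insulin at 5 mU/L and glucose at 5.8 mmol/L
  for a cat of average adiposity. Ages are uniform on [1, 14] years;
  flags (stress ~5.6%, assay interference ~0.6%, locomotor signs ~20%)
  are Bernoulli at the study's observed fractions.
* **Repeated measures**: values are grand_mean·exp(g_c + w_co + e_cor)
  with effect SDs from the inverse of Cole's equation at the target CVs
  (defaults 52.3/51.0/7.4%, 7 cats × 5 weekly occasions × duplicates,
  geometric mean 0.78); optionally one duplicate is dropped to mimic a
  pipetting loss.
* **CT phantom**: a two-mode Gaussian mixture (defaults −100/+60 HU,
  σ = 20 HU, 8σ separation) with an exact fat-voxel count and optional
  out-of-window contaminants to exercise the HU windowing.

What the generators do **not** emulate: breed/age structure in the
analytes, longitudinal progression to diabetes, assay drift between runs,
partial-volume and beam-hardening effects in CT, or correlation between
stress flags and glucose. Passing recovery tests therefore demonstrate
that the estimators recover the *generating* structure at the study's
scale — not that real cats satisfy the model.

## Problem sizes used in the test suite

Simulation sizes were chosen as the smallest that make the Monte-Carlo
error comfortably smaller than the asserted tolerance: CV-recovery uses
500 replicates of the 7×5×2 design (median recovered CVs within 15% of
truth); Wald-CI coverage uses 400 replicates of a 20×4×2 design with a
dominant within-cat component (±4 points around 95%, MC SE ≈ 1.1 points);
the Gaussian robust-limit check uses n = 10⁴ with a B = 1000 bootstrap;
phantom recovery uses 10⁶ voxels. Generator moment checks at n = 10⁴ cats
use tolerances of 4%/1.5%/1% for the G/I/A components, i.e. ≈3 standard
errors of a variance estimate with the corresponding degrees of freedom.

## Known limitations

* The Reference Value Advisor software's exact internals are not public;
  this package implements the CLSI EP28-A3 robust algorithm with the
  tuning constants above, and exact numerical replication of that
  program's output is out of scope.
* Wald intervals for variance components are poor at very small C (7 cats
  gives honest but wide, occasionally zero-floored CIs — visible in the
  outputs as lower limits of 0).
* The single-pass Tukey screen, applied to a continuous heavy-tailed
  sample, removes legitimate tail observations and shrinks the interval
  slightly; this mirrors the specified procedure rather than a bug.
* Exact Wilcoxon enumeration is limited to tie-free pooled samples; with
  ties the midrank normal approximation is used regardless of size.
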