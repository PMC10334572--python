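# Methods

## Survey model and censoring

A survey is a collection of single-egg ICP-MS measurements indexed by
brand, season, replicate and metal, in µg/kg wet weight. The analytical
limits default to LOD = 0.0003 and LOQ = 0.001 µg/kg. Values below the
LOD are substituted before any statistic is computed; the default policy
replaces them with 0, which is consistent with survey tables that report
minima of 0.00, and `half_lod` (LOD/2) and `lod` are available as the
usual sensitivity alternatives. Zero-substitution can only lower a group
mean; LOD/2-substitution can raise it by at most LOD/2 (when raw values
sit below LOD/2), which at these limits is three orders of magnitude
below the concentrations of interest.

Group summaries report n, min, max, the arithmetic mean and its standard
error using the n−1 sample standard deviation (the estimator is not
prescribed by the source conventions; n−1 is the standard choice). A
constant group has SE exactly 0 — degeneracy is detected on the value
range, not on the floating-point standard deviation, which can carry
~1e−16 of summation residue. The pooled two-season mean is the mean over
all records; report tables additionally derive their "mean" rows as the
average of the two seasonal means, which coincides with the pooled mean
for the balanced default design.

## Seasonal inference

Normality screening is a one-sample Kolmogorov–Smirnov test against a
normal with mean and SD estimated from the sample. The uncorrected KS
p-value is reported by default; it is conservative when parameters are
estimated, which is acceptable for a screen that should rarely reject
genuinely normal data. A Lilliefors-corrected variant (statsmodels) is
available behind a flag.

The seasonal comparison is a classical two-sided paired t-test at
α = 0.05. The pairing unit defaults to the brand-level mean per season
(21 pairs): replicate eggs within a brand batch are not individually
matched across seasons, so averaging them is the defensible pairing;
`pairing="replicate"` pairs on (brand, replicate) for users who want the
42-pair variant. Zero-variance differences (e.g. two point-mass seasons)
raise a degenerate-test error rather than producing an infinite t; the
pipeline records such rows with a note instead of aborting.

## Deterministic risk metrics

Equations and defaults are in the README. Numerical conventions:

- **Unit convention.** Published intake tables for this commodity
  multiply F_IR (g/day) by C_M (µg/kg) with no g→kg conversion; the
  default `paper` convention reproduces those numerals so outputs can be
  compared digit for digit, while `strict` divides by 1000. The pipeline
  logs a warning whenever paper-convention numerals are active. THQ and
  ILCR embed their own unit conversions and do not depend on the choice.
- **Rounding.** Table values are rounded half-away-from-zero on the
  decimal representation (2 decimals for intakes, 2 significant figures
  for THQ, 3 for ILCR, matching how such values are conventionally
  printed); raw unrounded values are always retained alongside.
- **ILCR bands** are half-open exactly as stated: negligible < 10⁻⁶ ≤
  acceptable ≤ 10⁻⁴ < threshold_exceeded ≤ 10⁻³ < moderate_risk.
- **PTMI** defaults to PTWI × 30/7 when a monthly guideline is requested
  but none is configured.

A known discrepancy is documented rather than imitated: published
arsenic THQ figures for this commodity (0.00385 mean / 0.00252 winter /
0.00518 summer) are ≈ 4.0× what the THQ equation yields at
RfD = 0.0003 mg/kg/day (0.000956 / 0.000629 / 0.00129); the mercury
figures match the equation exactly. The factor is not recoverable from
the published material (it is numerically close to using the As RfD with
a further ≈ 4× scaling, but no stated parameter produces it), so this
package reports the equation's values, and the test suite pins both the
equation values and the ≈ 4× ratio so the discrepancy stays visible.

## Monte Carlo

Input distribution families are an explicit modelling choice, since
point-estimate workflows rarely publish them. Defaults: lognormal for
concentrations (non-negative, right-skewed survey data), fitted by
moment matching so the analytic mean equals the survey mean exactly;
point masses for consumption rate and body weight, so uncertainty is
propagated through the concentration only (normal/uniform/triangular
are available for sensitivity runs, truncated at 0 by rejection). A
zero-spread summary downgrades any requested family to a point mass.

Simulation uses numpy's PCG64 generator with an explicit seed; 10,000
iterations by default. Percentiles use linear interpolation between
order statistics at rank 1 + (n−1)p (numpy's `linear` method), chosen
for determinism across implementations; the cumulative curve is the
empirical CDF on sorted draws. With point-mass inputs the simulation
reproduces the deterministic engine to full precision — this degeneracy
is both a test invariant and a runtime cross-check in the acceptance
script. Because THQ and ILCR are linear in the concentration, simulated
quantiles can be validated against closed-form lognormal quantiles; the
test suite does so within three Monte Carlo standard errors of the 95th
order statistic.

## Synthetic surveys

The generator emulates the reference study design — 21 brands, 2
replicate eggs per brand and season, both metals, 42 eggs per cell —
with i.i.d. draws from the moment-matched family at each cell's target
(mean, SE), SD = SE × √42, followed by the same censoring step as real
data. Default targets are the reference seasonal moments (As 0.52/1.07,
Hg 0.26/0.10 µg/kg); summer Hg is a point mass at 0.10, mirroring a
uniform reported cell. Each cell draws from an independent child seed so
streams are decoupled; identical configs are bit-reproducible.

What it does *not* emulate: instrument noise and recovery rates,
digestion variability, and (by default) brand-level correlation.
Replicates are treated as independent measurements; an optional
multiplicative lognormal brand intercept with unit mean
(`brand_effect_sd`) adds within-brand clustering for exercising the
paired test without biasing cell means. Passing tests on synthetic data
therefore demonstrate correctness of the statistical machinery under the
stated design, not robustness to instrument artefacts or non-lognormal
field data.

## Pipeline and problem sizes

The pipeline seeds every random stage from the configured MC seed (one
offset per metal × metric task, in fixed order) and stamps a SHA-256 of
the canonicalized configuration into the manifest; identical configs
produce byte-identical report files. Default problem sizes — 84 records
per metal, 10,000 MC iterations, 100-replicate detection studies and
300-replicate unbiasedness checks in the tests — were chosen so the full
suite exercises every claim at meaningful statistical resolution while
completing in seconds.

## Limitations

- Single food item, single exposure route, adults only; no hazard index
  across foods and no age stratification.
- The paired t-test with a near-constant season (summer Hg) leans
  entirely on the other season's variance; it is reported, but fragile
  designs like this deserve a sensitivity check.
- Published seasonal p-values cannot be reproduced exactly without the
  original sample-level data; the package instead verifies detection
  behaviour on synthetic surveys with the same moments (the built-in
  mercury shift is detected in ≥95 of 100 seeded runs).
- No variance-decomposition/sensitivity analysis of the Monte Carlo
  inputs (rank correlation, Sobol); uncertainty is carried by the
  concentration alone by default.
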