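# Methods

## Poisson inversion of droplet counts

A well partitions the reaction into N accepted droplets; a droplet is
positive when it received at least one template copy. Under Poisson
occupancy at rate λ copies/droplet the positive probability is
1 − e^(−λ), and inverting the observed positive fraction gives the
maximum-likelihood estimate λ̂ = −ln(1 − P/N). This is unbiased to well
below 1 % for the droplet counts and rates in scope (verified by
simulation in the test suite at λ ∈ {0.01, 0.1, 1.0}, N = 20,000).

Saturated wells (P = N) have no finite estimate and raise a distinct
`SaturatedPartitionError` so batch pipelines flag the well instead of
propagating infinities.

Concentration is λ̂ divided by the droplet volume. The default volume is
0.85 nL, the conventional partition volume for 20,000-droplet instruments;
it is configurable and cancels out of every ratio-based quantity (K and
all mass fractions), so its exact value only affects absolute copies/μL
reporting.

Per-well confidence intervals transform a normal-approximation binomial
interval on P/N through −ln(1−·) and scale by volume. They are a
reporting aid describing within-well sampling error, not the
replicate-to-replicate spread laboratories usually quote. For P = 0 the
upper bound is the exact one-sided bound −ln(1 − conf)/N (≈3/N at 95 %).
Simulated coverage at λ = 0.1, N = 20,000 is within 2 points of nominal.

## Transfer-coefficient calibration

For single-copy nuclear targets the copies per gram of meat (C_T for the
adulterant, C_B for beef) are constants under a fixed
extraction/assay protocol, so K = C_B/C_T converts copy ratios to mass
ratios: M_T/M_B = K·Q_T/Q_B. K is estimated from gravimetric mixtures of
known fraction w as K = (w/(1−w))·mean(Q_B)/mean(Q_T) and pooled by
arithmetic mean, with the sample (n−1) RSD quantifying its stability
across compositions.

Three conventions are fixed deliberately, because they reproduce
published calibration tables of this assay class exactly:

* replicates are aggregated as a **ratio of means**, not a mean of
  ratios;
* per-mixture K is rounded to 2 decimals **before** pooling (the pooled
  RSD of the 2-decimal values is what such tables print; unrounded values
  are kept on the result object for transparency);
* report-boundary rounding is half-away-from-zero on the exact decimal
  value (`decimal.Decimal`), since binary-float `round()` misrounds
  half-way cases such as a deviation of exactly 3.725 %.

The number of calibration levels is taken from the supplied design, never
hard-coded. At least two mixtures are required (RSD undefined otherwise).

## Quantification and label screening

The binary-mixture assumption (sample = target + beef only) turns a mass
ratio r into a mass fraction 100·r/(1+r); all bundled reference tables
and the simulator satisfy it. For multi-species samples only the pairwise
ratio is meaningful and the fraction should not be interpreted as "of
total meat".

Signed relative deviation against a known/declared composition is
100·(measured − actual)/actual, reported to 2 decimals; against a
declared value of zero the relative deviation is undefined and the
absolute difference is the meaningful quantity (a measured 65.9 % against
a "100 % beef" label is a flag, not a percentage deviation).

Label screening flags a product when |measured − declared| exceeds a
configurable tolerance, default 5 percentage points. The default is
deliberately conservative: confirmed mislabelling cases in commercial
surveys exceed declarations by well over 12 points, while honest
formulation and measurement scatter stays within a few points. Labels
lacking a defined content are reported with status "LC" and never
flagged — there is no claim to contradict.

## Validation battery

* **LOD** — smallest level at which every replicate gives a positive
  qualitative result *and* every higher tested level does too. The
  stability clause is our reading of "stably detected": it prevents a
  lucky fully-detected dip below a failing level from defining the LOD.
* **Positivity rule** — at least one positive target droplet in a well
  passing a minimum accepted-droplet QC (default 10,000). Vendor software
  leaves this rule implicit; it has to be fixed somewhere for simulation
  and reanalysis, and one droplet is the natural digital threshold.
* **LOQ** — smallest level with 100 % detection, replicate RSD ≤ 25 %
  *and* absolute mean bias ≤ 25 %, stable at higher levels. The bias arm
  matters: near the detection limit droplet quantisation can make
  replicates tightly clustered around a badly wrong value, so RSD alone
  admits levels that are precisely unquantifiable. Both 25 % thresholds
  follow DNA-method validation guidance for food testing.
* **Repeatability / reproducibility** — within-run RSD per level, and RSD
  of run means across independent runs (days/operators); acceptance at
  ≤ 25 % for both.
* **Linearity** — OLS of measured on actual fraction; r² is the squared
  Pearson correlation. Noiseless pipeline output is exactly linear
  (slope 1, r² = 1); at the default noise level simulated 1–90 % series
  give r² ≈ 0.998.

LOD ≤ LOQ whenever both are defined, by construction (the LOQ criteria
include the LOD criterion).

## Generative model (simulator)

One simulated well draws positives ~ Binomial(N, 1 − e^(−λ)) with
λ = c·V_droplet, where the expected concentration c is w·C_T (target
channel) or (1−w)·C_B (beef channel), times a degradation factor and a
lognormal replicate-noise multiplier with unit mean.

Defaults define the emulated study conditions:

| parameter | default | rationale |
|---|---|---|
| droplets/well | 20,000 | standard droplet-generator output |
| droplet volume | 0.85 nL | conventional for the instrument class |
| C_T, C_B (pork-like) | 300, 357 copies/μL per unit fraction | K = 1.19; a 10 % mixture yields ≈30/321 copies/μL, the magnitude real single-copy assays report from 50 ng template |
| C_T, C_B (chicken-like) | 2300, 874 | K = 0.38; 10 % → ≈230/787 copies/μL |
| replicate CV | 5 % (lognormal) | replicate spreads in real tables scale with magnitude, i.e. multiplicative error |
| degradation factor | 1.0 (none) | thermal treatment modelled as a single multiplicative copy loss, equal in both channels by default — ratio-based quantification is then unaffected, matching the observed robustness of the method to cooking; a differential reference-channel factor is available to emulate unequal damage |

The accepted-droplet count is held fixed at the configured value rather
than jittered per well: droplet-count variability affects only the
(negligible) sampling-error term. Not modelled: "rain"
(intermediate-amplitude droplets), droplet-volume variability,
cross-channel leakage, inhibition, and any background signal at w = 0.
Passing tests therefore demonstrate the statistical machinery under the
model's assumptions; they do not certify gating quality or matrix effects
in real reactions.

An expected-value mode disables all sampling and returns closed-form
expectations, giving a deterministic oracle: the full pipeline then
recovers the true mass fraction and K to machine precision (up to the
documented 2-decimal K convention).

## Problem sizes and numerical choices

Simulation-based checks use 20,000 droplets per well; 500 replicates for
estimator-bias checks, 1000 for interval coverage, 20 seeded runs
(5 levels × 6 replicates) for K recovery, 200 runs per level for
mass-fraction bias, and triplicate 11-level series for linearity — the
designs of the emulated study wherever it states one, and conventional
validation designs elsewhere. All simulations are seeded and
bit-reproducible.

Degenerate inputs are rejected explicitly rather than propagated: empty
replicate lists, non-positive concentrations, saturated wells, zero-mean
RSDs, single-value RSDs, regression on fewer than three distinct levels.

## Known limitations

* K is protocol-specific: a different extraction kit, template mass or
  target gene requires recalibration. No model of K drift with
  processing state is attempted (none is supported by the data the
  approach rests on).
* The binary-mixture assumption makes fractions meaningful only for
  two-species samples.
* Bundled dilution-series records carry mean ± SD summaries, so LOQ
  decisions on them use summary RSD; per-replicate inputs are supported
  and preferred.
* No parsing of vendor amplitude/plate files; droplet gating is upstream
  of this package.
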