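# Methods

## The problem

Soluble-solids content (SSC, % — refractometer °Brix-equivalent) is the
main internal quality index of peach fruit. In online grading, a fruit
crosses a light source/detector pair in full-transmittance geometry and
yields a *sequence* of raw transmittance scans `T_raw` rather than a
single spectrum; the number of scans is set by fruit diameter, belt
speed `v` and integration interval `Δt`:
`n_raw = round(d / (v·Δt))` (one scan per 2.4 mm of travel at the
defaults v = 480 mm/s, Δt = 5 ms). The analysis question this package
addresses is twofold: *which scans of the sequence should be averaged*
(the whole fruit, or only the zones away from the pit?) and *at which
orientation should the fruit be scanned*, before standard chemometric
calibration.

## Pipeline

1. **Zone split.** The ordered scan sequence is divided contiguously
   into S1, S2, S3 with `n_S1 = n_S3 = ⌈n_raw/3⌉` and
   `n_S2 = n_raw − 2⌈n_raw/3⌉`. `n_raw < 5` is rejected: at `n_raw = 4`
   the middle zone would be empty, contradicting its definition as the
   pit-containing zone. Zone assignment is contiguous in scan order
   because the zones are spatial thirds of the traversal.
2. **Combination mean.** The unweighted mean over the scans of the
   chosen combination (S1–S3, S2, or S1–S2–S3). The S1–S2–S3 mean is
   identical to the plain all-scan mean spectrum (the "whole fruit"
   route), so both preprocessing routes share one code path.
3. **Truncation** to 652.25–1026.25 nm (1497 of 2048 channels),
   removing low-signal band edges. Truncation precedes smoothing, so
   the smoother never sees out-of-band noise.
4. **Moving average**, window 9, centred. At the edges the window
   shrinks symmetrically to the largest centred window that fits; this
   preserves vector length (the truncated grid stays 1497 points) and
   passes linear trends through unchanged. Alternatives (padding,
   truncating the output) were open choices; shrinking was selected for
   the length-preservation property.
5. **SNV**: per spectrum, subtract the mean and divide by the standard
   deviation. The divisor is the *sample* sd (n−1), the dominant
   chemometrics convention; a `ddof=0` flag provides the population
   variant since the defining formula fixes neither. Constant spectra
   raise an error rather than emitting NaN.

## PLS and model selection

PLS1 by NIPALS on mean-centred `X` and `y`; no column scaling (rows are
already SNV-normalised; autoscaling columns would distort relative band
intensities). Coefficients are returned on the original scale via
`b = W(PᵀW)⁻¹q`, `b₀ = ȳ − x̄ᵀb`, so a fitted model is a plain affine
map. Rank exhaustion (zero-norm weight vector) truncates the model to
the attained components with a warning.

Latent-variable count: a single seeded 10-fold cross-validation
(shuffled indices, near-equal contiguous blocks, no stratification);
for each candidate count 1..20 the held-out predictions of all folds
are pooled and scored with the package RMSE; the minimiser wins, ties
going to fewer LVs. R_CV is the Pearson correlation of the same pooled
predictions. One NIPALS pass per fold at the maximum count provides all
smaller counts, which a test verifies is numerically identical to
refitting each count from scratch.

## Wavelength selection

**SPA.** For every starting channel, a projection chain of length up to
`m_max = 25` is grown by repeatedly taking the channel with the largest
norm orthogonal to the span of those already chosen (channels are
norm-normalised for the projection geometry only). Every
(start, length) candidate subset is scored by the pooled 10-fold-CV
RMSE of ordinary least squares with intercept — SPA subsets are small
and decorrelated, which is exactly MLR territory. Winner: lowest RMSE,
then fewer channels, then lower start index. Implementation detail: the
chains are built in Gram-matrix space (modified Gram–Schmidt on inner
products, O(m·p) per step) and the OLS scores reuse fold-wise Gram
prefixes, which keeps the full 1497-channel search at seconds.

**CARS.** `N = 50` Monte-Carlo runs. Run *i* fits PLS (LV count by CV
on the subsample, capped at 20) on a random 80 % subsample of the
calibration fruit restricted to the currently retained channels, and
weights each channel by `w_j = |b_j| / Σ|b|`. Two elimination steps
follow: the enforced exponentially decreasing retention ratio
`r_i = a·e^{−k·i}` with `k = ln(p/2)/(N−1)`, `a = e^k` (so r₁ = 1 and
r_N = 2/p) keeps the ⌈r_i·p⌉ top-weighted channels, then adaptive
reweighted sampling draws ⌈r_i·p⌉ channels with probability ∝ w_j with
replacement and keeps the unique draws. Each run's surviving subset is
scored by the full-calibration 10-fold RMSECV; the best run (ties →
earlier) supplies the final subset. Hyperparameters (50 runs, 80 %
subsampling, m_max = 25) are package defaults, configurable in
`RunConfig`.

## The synthetic-data generator

No raw study data are publicly available, so the generator emulates the
statistical structure the pipeline assumes, not fruit optics. Per scan,
absorbance is

```
A(λ) = path · [ baseline(λ) + SSC·g·(1−α_pit·1_pit)·S(λ) + W(λ) + β_pit·1_pit ]
T(λ) = T₀·10^(−A(λ))·s + ε
```

with `S` the sugar response (Gaussian bands 910 nm/σ25 and 840 nm/σ30,
amplitudes 0.035 and 0.025 absorbance per % SSC — the O–H/C–H overtone
region), `W` fixed water bands (760 nm/σ15, amplitude 0.5; 970 nm/σ30,
0.6), a linear baseline (0.90 + 5·10⁻⁴/nm), `s` a per-scan log-normal
scatter factor (σ = 0.10; multiplicative in transmittance, hence
removable by SNV), and ε additive detector noise (sd 2·10⁻⁴
transmittance units, ≈0.7 % of a typical transmitted intensity).
`path = d/d̄` scales with fruit diameter, times 1.15 for orientation O2
(longer horizontal path), which also deepens the 760 nm water band by
0.15 — the qualitative orientation signature.

Three per-fruit effects, shared between a fruit's two orientations,
carry the realism that matters for the comparison:

* `g ~ N(1, 0.05)` — fruit-to-fruit variability of the absorbance
  response per % SSC (flesh structure, temperature). This is the main
  irreducible error source: without it, absorbance is an exact function
  of SSC and PLS recovers SSC essentially perfectly (R_P = 1.00), which
  no real NIR calibration achieves. At SSC ≈ 10.7 % the implied floor
  is ≈ 0.5 % SSC, i.e. R_P ≈ 0.93 against an SSC sd of ≈ 1.25 — the
  regime of real transmittance calibrations.
* pit-effect variability (relative sd 0.10) on both the pit attenuation
  `α_pit` (default 0.6) and the pit scatter boost `β_pit` (default
  0.2). A *fixed* attenuation would merely rescale the S2 signal — a
  linear transformation PLS inverts exactly — so the fruit-varying pit
  is what makes the middle zone genuinely less informative, as the
  zone-comparison design presupposes. Setting attenuation and boost to
  0 disables the zone effect entirely (the zones become exchangeable),
  which the tests exploit as a negative control.

SSC truth is a truncated normal, parameters from the emulated study's
calibration table (μ = 10.70, σ = 1.54, range 7.40–14.50 %); note the
realised sd after truncation is ≈ 1.25 %. Diameters are N(75, 5²) mm —
a convention, not a reported value. The 150 fruit are split 100/50 into
calibration/validation by a seeded permutation. Each fruit's
sub-generator derives from `(seed, fruit index)`, so datasets are
reproducible and order-independent.

What the generator does **not** emulate: radiative transfer, fruit
shape and skin optics, wavelength-dependent detector response,
instrument drift, or chemistry beyond one sugar response (acids,
water-content gradients). Passing tests therefore demonstrate that the
*pipeline* recovers the structure it assumes at realistic noise — not
that the specific published performance numbers transfer, which would
require the original fruit.

## Numerical and I/O conventions

* Grid membership uses a 10⁻⁹ nm absolute tolerance; off-grid
  truncation bounds are errors.
* All file formats are plain text (CSV / JSON), comma-delimited,
  UTF-8, floats at 17 significant digits (exact float64 round-trip);
  readers parse with round-trip precision. Writers are deterministic,
  so identical config + seed gives byte-identical outputs.
* Every stochastic stage (dataset split, CV folds, CARS, SPA fold
  assignment) takes an explicit seed; pipeline-level runs derive
  per-stage seeds from the global seed via fixed spawn keys, so stages
  can be rerun independently yet reproducibly.
* Argmin ties: LV count → fewer LVs; SPA → fewer channels, then lower
  start index; CARS → earlier run.

## Problem sizes

Default analyses use the full study geometry: 150 fruit × ≈31 scans ×
2048 channels, 1497 after truncation. The unit-test fixtures use a
coarse 101-point grid and 30 fruit, which exercises every code path at
a fraction of the cost; the acceptance-style checks (parameter
recovery, zone ordering, SPA conditioning) run at the full 1497-channel
size.

## Known limitations

* PLS1 only (single response); no PLS2, no nonlinear variants.
* No preprocessing alternatives (MSC, derivatives, detrending) — the
  pipeline is deliberately the fixed published chain.
* CARS diagnostics record one trace per run; repeated-CV LV selection
  is not implemented (a single seeded 10-fold CV is used throughout).
* The generator's orientation effect is a smooth path-length/band
  change; it induces no systematic performance gap between O1 and O2,
  so orientation comparisons on synthetic data are expected to come out
  near-equal (as, qualitatively, they did in the emulated study).
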