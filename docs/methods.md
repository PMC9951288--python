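# Methods

`dadkit` analyzes HPLC–DAD raw data: time × wavelength absorbance
matrices in which every retention-time point carries a full UV–Vis
spectrum. This note documents the models, the tunable parameters, the
synthetic-data generator used for validation, and the numerical choices
made where the design was genuinely open.

## Signal model and preprocessing

A chromatogram is modeled as a sum of bilinear compound contributions
plus baseline and noise:

    X[t, λ] = Σ_c  a_c(t) · s_c(λ)  +  b(t, λ)  +  ε[t, λ]

where `a_c` is compound *c*'s elution profile (mAU·min⁻¹ scale after
integration), `s_c` its unit-norm UV–Vis spectrum, `b` a slowly varying
baseline and `ε` detector noise.

**Baseline correction** is asymmetric least squares (AsLS) per
wavelength column: minimize `Σ w_t (y_t − z_t)² + λ Σ (Δ²z_t)²` with
`w_t = p` where `y > z` and `1 − p` elsewhere, iterated to a fixed
point. Defaults: smoothness `λ = 1e5`, asymmetry `p = 1e-3`, 10
iterations (config keys `baseline.*`). Because the asymmetric weights
make the fit settle on the *lower envelope* of the noise rather than its
mean, the median residual of each column is restored after fitting;
without this, every corrected trace carries a small positive offset that
inflates small peak areas and lets blank runs trigger the peak picker.
The 2nd-difference penalty passes linear drift exactly; strongly curved
baselines need a smaller `λ` at the cost of more area bias under wide
peaks.

**Noise** is estimated on the wavelength-summed trace as
`σ = 1.4826 · median|Δy| / √2` — successive differencing removes smooth
signal, and the MAD scaling is consistent for Gaussian noise. Estimating
on the summed trace (not per wavelength) matches where the estimate is
consumed: peak picking.

## Peak detection and integration

Detection runs on the wavelength-summed trace, so the full spectral
dimension is reserved for purity checking and deconvolution. Local
maxima of a 3-point-smoothed trace become apexes when their height
reaches `max(rel_height · max(trace), snr_min · σ)` (defaults 0.01 and
10) and their prominence exceeds `3σ`; the prominence guard prevents
shot noise on a peak's crown from spawning duplicate apexes. Borders
start at the flanking local minima and are pushed outward while the
trace stays above `3σ` and keeps descending (3-point smoothing), never
crossing a neighboring apex. Windows that intersect are merged — by
construction, expanded borders of genuinely separated peaks stop at the
noise floor and never touch, so any contact marks real overlap.
Integration is trapezoidal over the window with negatives clipped at
zero; a window of fewer than 3 points is an error. Saturation is
flagged when any cell exceeds `peaks.saturation_mau` (default 2000 mAU);
saturated peaks are excluded from calibration.

## Peak purity

A window is **pure** when both of the following hold (defaults
`purity.r_min = 0.95`, `purity.ev_min = 0.995`):

1. the minimum Pearson correlation between the apex spectrum and the
   spectrum at every in-window point with ≥ 10% of the apex height is at
   least `r_min`;
2. the first principal component of the time-mean-centered window slab
   explains at least `ev_min` of the variance.

Two compounds with (near-)identical spectra that coelute pass both tests
— a documented false-positive mode that no analysis of the data alone
can resolve; only better chromatographic separation helps.

## Component counting and PARAFAC deconvolution

For an impure window the number of coeluting components *k* is the
smallest number of principal components of the mean-centered slab whose
cumulative explained variance reaches `0.995`, capped at
`deconv.k_max = 4`. The counter deliberately shares the purity check's
centered variance decomposition: an impure-flagged window then always
yields `k ≥ 2`. Windows wider than 120 points are 2× time-subsampled
for PCA only, never for integration.

The window slab is stacked with the corresponding windows of pure
calibration runs of every library compound whose retention time falls
inside the window, giving a trilinear `time × wavelength × slab` tensor
(slab 0 = the impure sample). The rank-*k* non-negative PARAFAC model

    T[t, λ, m] ≈ Σ_r  A[t, r] · B[λ, r] · C[m, r]

is fitted by alternating least squares with HALS (hierarchical
column-wise) updates, which keep factors non-negative and make the loss
non-increasing at every iteration. The best of 10 seeded random
initializations plus one SVD-based initialization is kept; iteration
stops when the relative loss change falls below `1e-8` or after 500
iterations (config `deconv.*`). Factors are returned with unit-norm
elution and spectrum columns and all magnitude in the slab loadings.
PARAFAC's essential uniqueness under mild conditions (Kruskal) is what
resolves the rotational ambiguity an ordinary bilinear factorization of
a single window would have; with no reference slab available the fit
degrades to exactly that bilinear case, which still separates strongly
dissimilar spectra.

**Reference alignment.** Reference slabs are shifted along time by the
run's known retention correction (see internal standards below),
converted to grid points. A data-driven alignment search was evaluated
and rejected: under coelution, any matrix-based criterion — plain
summed-trace cross-correlation or a spectrally gated matched filter —
is biased toward the coeluting impurity's mass, because non-negative
spectra always overlap (s₁·s₂ > 0); a misaligned reference detaches
from its own compound in the fit and can hand the whole window to the
impurity. An optional bounded matched-filter refinement
(`build_tensor(..., max_refine=n)`) exists for campaigns with residual
drift; it is off by default. Campaigns without an internal standard and
with real retention drift are therefore a known limitation.

**Quantification of components.** Component *r*'s area in the impure
sample is `C[0, r] · ∫A[:, r] dt · Σ B[:, r]`, and all component areas
are rescaled so that their sum equals the window's summed-trace
integral. This conservation anchor makes deconvolved areas commensurate
with ordinary pure-peak integration and hence with the calibration
curves. Each component is assigned to the library compound with the
highest spectral Pearson correlation if it reaches
`deconv.match_r_min = 0.90`, with at most one component per compound
(higher correlation wins); the rest become campaign-stable unknowns.

## Campaign orchestration

Calibration runs build the library: the largest pure, unsaturated,
non-internal-standard peak of each calibration run is assigned to the
declared compound; the entry keeps the average apex spectrum, the median
apex time, one reference chromatogram (highest-area run) and the
(area, concentration) calibration points. Calibration is linear through
the origin (Beer–Lambert at low absorbance): `slope = Σxy / Σx²`, with
`R²` computed about the through-origin fit. Relative mode regresses
area ratio to the internal standard on concentration ratio;
quantification then multiplies by the run's internal-standard
concentration.

The internal standard, when declared, also anchors retention: the peak
matching the istd spectrum (r ≥ 0.95 within ±0.5 min of its reference
time) defines a per-run shift applied to peak times for matching and to
reference alignment in deconvolution. A run whose istd cannot be found
is flagged, not silently processed.

Pure peaks are assigned to the library compound maximizing spectral
correlation subject to `assign.spec_r_min = 0.97` and a retention window
of `assign.rt_window = ±0.1 min` (sized for sub-3-minute methods);
conflicts keep the better match. Unassigned signals get first-seen
identifiers `unknown_001, …` from a campaign registry keyed by spectrum
(r ≥ 0.97) and retention window, so the same impurity keeps one identity
across a campaign.

## Synthetic campaigns and the validation benchmark

The simulator renders each compound as
`outer(elution, spectrum / Σspectrum)`, so the compound's
wavelength-summed trace integrates exactly to its declared area —
ground-truth areas are analytic. Elution profiles are exponentially
modified Gaussians (EMG), the standard model of tailing peaks, computed
via the scaled complementary error function for numerical stability and
reducing to a Gaussian for `τ < σ/100`. Spectra are sums of Gaussian
bands; a companion constructor produces a spectrum at a requested
Pearson correlation to a reference by mixing it with a seeded
band-spectrum (searching random and anti-correlated band placements) and
bisecting the mixing weight. Since both endpoints are non-negative the
mixture needs no re-clipping.

The validation benchmark pairs a fixed main compound (tR 0.45 min,
σ 0.015 min, τ 0.004 min, response factor 20 mAU·min per concentration
unit, three calibration runs at 0.5/1.0/2.0) with an impurity whose

- spectrum is constructed at the level's target correlation
  (high ≈ 0.86, medium ≈ 0.47, low ≈ −0.06),
- relative area is uniform in [0.2, 2],
- apex separation follows a resolution `Rs = Δt / (2(σ₁+σ₂))` sampled
  uniformly in [0.1, 2.5], on either side of the main peak,
- tailing τ is uniform in [0, 0.008] min,

on a 0–1 min grid at 0.002 min sampling and a 200–400 nm grid at 5 nm.
Noise is i.i.d. Gaussian, 0.05 mAU per cell (a conservative figure for
modern DAD short-term noise, which vendors specify around 10⁻⁵ AU), and
each case carries a linear baseline drift up to 5 mAU. All randomness
derives from one master seed by counter-based seed splitting, so every
granularity is reproducible.

A ground-truth pair counts as **baseline-separated** when the noiseless
summed trace between the apexes drops below 1% of the smaller apex
height. Analysis outcomes are scored into four categories: (i) the pair
is separated, windows are pure and the main compound assigned; (ii) an
impure window was deconvolved and the main compound assigned and
quantified; (iii) deconvolution triggered but missed the main compound;
(iv) an overlapping pair was labeled pure (purity false positive). The
benchmark summary reports category counts and the median and third
quartile of `|estimated − true| / true` of the main compound over
category-(ii) cases.

What the generator does *not* emulate: nonlinear retention effects of
coeluting analytes (competitive adsorption), gradient distortion of peak
shapes, detector saturation physics, wavelength-dependent noise, and
retention-time drift between runs. Passing the benchmark therefore
demonstrates the correctness of the signal-processing and decomposition
chain under realistic noise and overlap, not robustness to every
instrumental artifact of real campaigns.

## Problem sizes used in the shipped checks

The test suite analyzes 200 cases per similarity level (600 total) for
the benchmark-level checks, 50 seeded tensors per rank for PARAFAC
factor recovery, a 100-case grid for the purity truth table, and
5-level calibration sweeps with 2% multiplicative area noise; the
acceptance script repeats the 3 × 200-case benchmark from a single
master seed. These sizes keep the full validation comfortably
desk-scale while leaving the category statistics stable to within a few
counts across seeds.

## Known limitations

- Deconvolution quality depends on the trilinear assumption: retention
  profiles must be reproducible between the sample and the reference
  runs. Campaigns without an internal standard and with retention drift
  lose the reference anchor (see above).
- The purity check's thresholds are method-scale dependent; very low
  signal-to-noise peaks (< ~20:1 at the apex) can fail the flank
  correlation test spuriously.
- `k` is capped at 4 components; more complex co-elution clusters are
  resolved only partially.
- Quantification of a deconvolved component inherits any error in the
  window integral through the conservation anchor; a badly drawn window
  biases all components proportionally.
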