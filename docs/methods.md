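# Methods

`paleodendro` re-creates, over synthetic data with known ground truth, an
analysis chain for inferring paleoclimate from fossil (floating) tree-ring
chronologies and paleosol major-element chemistry. This note documents the
models, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Ring-width model and the synthetic forest

Each radius of each tree is generated as

```
width(t) = max(floor, w0 · exp(−decay · age)) · exp(g · C(year) + ε(age)) · m(year)
```

* `w0` (default 2.5 mm), `decay` (0.01 /yr) and `floor` (0.3 mm) define a
  negative-exponential juvenile-to-mature age trend. The defaults are
  generic conifer-like values; fossil taxa provide no growth-curve
  calibration, so they are exposed in config and nothing downstream depends
  on their exact values (detrending removes the trend).
* `C(t)` is the shared climate signal, a sum of sinusoids
  `Σ aᵢ sin(2πt/pᵢ + φᵢ)`, each optionally gated to a sub-interval to
  emulate non-stationary oscillations. `g` (`signal_gain`) couples it into
  log-width.
* `ε` is per-radius AR(1) noise with Gaussian innovations of standard
  deviation `noise_sd` (so marginal sd `noise_sd/√(1−φ²)`), run through a
  50-step burn-in so the first emitted ring is already stationary.
* `m(t)` are multiplicative marker years — anomalously narrow or wide rings
  shared by all trees on the chronology axis, applied after the noise.

All noise is multiplicative/lognormal so widths stay strictly positive and
right-skewed, as ring widths are. A single `SeedSequence(seed)` is spawned
into one child stream per radius in (tree, radius) order, so individual
series are reproducible and adding trees does not reshuffle existing ones.
Emitted series all start at relative year 0; the germination offsets are
retained only as recoverable metadata.

### Reference study conditions

Recovery experiments use a frozen configuration
(`reference_forest_config`): 6 trees × 2 radii × 100 years, offsets
0/4/9/13/18/25 (assembled span 125 yr, minimum pairwise overlap 75 yr),
`signal_gain` 0.5, AR(1) φ = 0.4, innovation sd 0.3, and a climate signal
consisting of a 30-yr oscillation (amplitude 1) over a 12-component
random-phase comb of periods 2.3–9.7 yr (amplitude 0.35 each) plus 13
aperiodic marker years.

The comb and the markers are not decoration: a pure sinusoid is
self-similar at every near-multiple of its period, so a tone-only climate
signal makes lag recovery ill-posed — candidate alignments at alias lags
score as well as the truth. Broadband shared interannual variability and an
aperiodic anomaly fingerprint are precisely what makes real cross-dating
work, and the generator reproduces both. With this design the alias
correlation structure stays far below the true-lag match statistics, and
the reference experiment recovers all offsets in 300/300 seeds.

What the generator does **not** emulate: false/missing rings, measurement
error on ring boundaries, within-stand ecological asynchrony (gap dynamics,
competition releases unrelated to climate), taphonomic truncation, and
age-dependent climate sensitivity. Passing recovery tests therefore shows
the statistics and assembly logic are correct under the stated noise model,
not that any particular fossil data set would cross-date.

## Cross-dating

Candidate lags are scanned exhaustively wherever the raw overlap is at
least `min_overlap` (default 20 yr, the conventional minimum for a
replicable match). Statistics per lag:

* **t_BP** — Student t of the Pearson correlation of Baillie–Pilcher
  transformed series, `ln(width / 5-yr centred moving mean)`;
* **t_HO** — the same t on Hollstein growth values,
  `100·log₁₀(w_{t+1}/w_t)`;
* **r** — the correlation underlying t_BP;
* **GLK** — percent parallel covariation of first differences, ties scored
  ½ (whether historic implementations scored ties as ½ varies; this is the
  common modern convention).

Acceptance gates (config-exposed defaults): t_BP ≥ 3.5 **and** t_HO ≥ 3.5,
GLK ≥ 65%, r ≥ 0.5. Both t statistics are gated because the two transforms
are quasi-independent; with a single t the rate of spurious acceptances on
independent noise roughly doubles. A further rule: a pair is matched only
when the *top-ranked* lag (by t_BP; ties broken by higher GLK, then smaller
|lag|) itself passes the gates. Falling back to a lower-ranked lag that
happens to clear the gates would knowingly prefer a worse-supported
alignment, and empirically poisons the master graph with small-overlap
flukes.

Measured false-positive pair-acceptance on independent AR(1) (φ = 0.4)
series of length 100: ≈ 4.4 ± 0.5% (it is ≈ 7.6% for pure white noise —
small overlaps at the scan edges dominate, and the max-t selection favours
them; the red-noise figure is the relevant one for tree-like series).

Replicate radii of a tree are cross-matched and averaged (arithmetic
per-year mean) before inter-tree matching; radii whose best-supported lag
fails the gates are dropped from the average. Master assembly composes the
accepted pairwise lags over the match graph (breadth-first from the largest
connected component); every closing edge is checked, and a cycle whose lags
are inconsistent raises an alignment-conflict error rather than silently
choosing. Series outside the component are reported excluded.

## Chronology

Each aligned series is detrended with a cubic smoothing spline. The
roughness penalty is set from the requested 50%-response wavelength
`p = 0.67 · n` by `λ = (p/2π)⁴`: for unit annual spacing the smoother's
amplitude response is `1/(1 + λω⁴)`, which is ½ at wavelength `p` (verified
numerically to three decimals). 0.67 of series length is the dominant
dendro convention; the fit is floored at 10⁻⁶ mm so the index is always
defined. RWI = width / fitted width; indexing is by ratio, not difference,
consistent with the multiplicative noise model.

Per-year values are combined with a Tukey biweight robust mean (c = 9,
iterated from the median/MAD) where at least four series contribute, else
the arithmetic mean — the biweight is unstable at tiny n. `rbar` is the
mean pairwise Pearson correlation of RWI over common years (pairs with
< 10 yr overlap skipped). Subsample signal strength uses the standard form

```
SSS(n) = n(1 + (N−1)·rbar) / ( N(1 + (n−1)·rbar) )
```

with per-year sample depth n, whole-chronology rbar, and cutoff 0.5
(config-exposed; 0.85 is the stricter common choice, 0.5 is deliberately
permissive). A Shapiro–Wilk normality diagnostic with probability-plot
quantiles is advisory only and never blocks the transform.

One caveat found while validating: the biweight mean of RWI across
*misaligned* trees sits visibly below 1 (robust location of a right-skewed
distribution), so the mean-RWI ≈ 1 property is asserted only for properly
cross-dated chronologies.

## Wavelet analysis

The continuous transform follows the standard FFT formulation on a dyadic
scale grid `s_j = s0·2^(j/16)` (16 voices per octave, `s0 = 2 yr`, largest
Fourier period ≤ series length), with zero-padding to the next power of
two. The input is mean-removed and variance-normalized, so power is in
units of σ². Wavelets: Morlet with ω₀ = 6 (analytic/Heaviside form;
Fourier period 1.033 s) and DOG(2)/Mexican hat (real; Fourier period
2πs/√2.5). One implementation subtlety: the Nyquist bin must be assigned a
*positive* angular frequency, or the Heaviside zeroes the Morlet's
contribution there and small-scale coefficients are badly wrong; the FFT
path is verified cell-by-cell (rtol 10⁻⁸) against an O(N²) time-domain
circular-convolution oracle in the test suite.

The cone of influence uses the e-folding time √2·s, ramping symmetrically
from both edges. Red-noise significance defaults to the theoretical test:
background `P_k = (1−α²)/(1+α²−2α cos 2πk/N)` at each scale's Fourier
frequency, threshold `P_k·χ²_ν(1−level)/ν` with ν = 2 (Morlet, complex) or
ν = 1 (DOG, real). A Monte-Carlo alternative takes per-scale quantiles of
power over AR(1) surrogates with matched lag-1 coefficient; the two agree
on > 90% of in-cone cells, and the theoretical test is empirically
calibrated (5 ± 2% flags on pure AR(1) input over 500 simulations at
φ ∈ {0, 0.4, 0.7}). The AR(1) coefficient is estimated as the lag-1 sample
autocorrelation, floored at 0.

Cross-wavelet: `W^XY = W^X·conj(W^Y)`; phase follows the arrow convention
(0 = in phase, π = anti-phase, ±π/2 = quarter-period lead/lag). Squared
coherence smooths `W^XY/s` with a Gaussian in time (σ = scale) and a 0.6
octave boxcar in scale; edge handling is reflective in time and
nearest-neighbour in scale. Unsmoothed coherence is identically 1, so
disabling smoothing is an error; DOG spectra are refused (the smoothing
kernel is Morlet-specific). Coherence significance is Monte-Carlo over
AR(1) surrogate *pairs* (per-scale cell quantiles, and a separate quantile
for the COI-interior per-period mean), deterministic given a seed.

## Growth-response statistic

Given a DOG(2) spectrum of the chronology, a year is *significant* in a
period band (default 20–40 yr) when any cell at that year, with period in
the band and inside the cone, passes red-noise significance. Significant
years are classified by RWI: suppressed (< 1), enhanced (> 1), neutral
(= 1, excluded from both numerator classes). The statistic is the percent
of significant years in each class; an epoch contrast is the difference of
suppressed fractions with a seeded bootstrap CI (resampling significant
years with replacement).

A structural fact worth recording: with purely multiplicative symmetric
coupling, flipping the *sign* of `signal_gain` is equivalent to a
half-period phase shift of a sinusoidal forcing, and DOG significance
depends only on squared power — so the suppressed fraction is blind to the
gain sign (its distribution is identical in both arms; the residual
harmonic asymmetry is ~1% of band power at g = 0.3 and favours enhanced
years in both arms). The direction-carrying mechanism, in this model as in
wood, is the anomaly fingerprint: the direction experiment
(`growth_coupling_config`) couples the 30-yr oscillation to growth through
7-year episodes of anomalously narrow (×0.55) or wide (×1.8) rings centred
on the oscillation crests, plus a matching gain of ∓0.3. Under those
conditions the suppressed fraction averages ≈ 62% (negative coupling,
> 50% in ~100/100 seeds) versus ≈ 41% (positive, < 50% in ~98/100) — a
~21-point contrast. A second caveat: because the spline tracks the local
*mean* of a right-skewed index, slightly more than half of all years sit
below RWI = 1 regardless of coupling; single-year markers therefore cannot
drag the positive arm below 50%, and only multi-year anomaly episodes
(which dominate the flagged windows) produce an enhanced majority.

## Paleosol proxies

Molar conversion divides oxide wt% by molar mass (Al₂O₃ 101.96, CaO 56.08,
Na₂O 61.98, K₂O 94.20, MgO 40.30, MnO 70.94 g/mol). Indices (molar):

```
CIA   = 100·Al₂O₃ / (Al₂O₃ + CaO* + Na₂O + K₂O)
CIA-K = 100·Al₂O₃ / (Al₂O₃ + CaO* + Na₂O)
```

CaO* defaults to total CaO (appropriate for carbonate-free profiles; a
McLennan-style cap `CaO* = min(CaO, Na₂O)` is available by config). The
authigenic-K correction takes the parent's molar K fraction
`m = K/(Al+Ca*+Na+K)` as the pre-metasomatism proportion and replaces the
horizon's K with `m·(Al+Ca*+Na)/(1−m)` before recomputing CIA; the map is
idempotent by construction.

Transfer functions are configuration, not code constants:

* MAP = 221.1·exp(0.0197·CIA-K) mm/yr — the standard published
  exponential calibration;
* LST = 0.56·CIA − 25.7 °C — a provisional linear default, flagged as
  such; studies with their own calibration should override it (strict mode
  refuses all shipped defaults);
* Eppt = MAP[kg·m⁻²·yr⁻¹] · c_w · (LST − T_ref) MJ·m⁻²·yr⁻¹, the sensible
  heat delivered by rain (c_w = 4.186·10⁻³ MJ·kg⁻¹·K⁻¹, T_ref = 0 °C);
* ET uses a temperature-scaled annual potential-evapotranspiration mass
  flux (58.93 mm/°C, Holdridge-style) in the same energy form, so
  Eppt/ET reduces to the familiar MAP/PET aridity ratio.

The Eppt/ET forms and the humidity-province boundaries are *synthetic
stand-ins* with the right structure and units, shipped so the
classification chain is runnable and testable; the boundaries are straight
lines Eppt = r·ET at r = 0.05/0.2/0.5/0.65/1.0 separating
hyperarid/arid/semiarid/dry-subhumid/humid/perhumid provinces (desert →
rainforest floral regimes), supplied as ordered polylines and fully
config-replaceable. Points on a boundary classify to the wetter side.
Profile QC: the mean CIA-K of B horizons must differ from the parent CIA-K
by more than 5% (relative) for pedogenic chemistry to be considered
preserved.

The paleosol simulator builds horizons over a known parent by depleting Ca
and Na (proportionally) and enriching Al (1% per CIA-K point) to hit
requested CIA-K increments exactly before analytical noise, so the QC rule
and index arithmetic can be tested end-to-end against ground truth.

## Problem sizes and determinism

All experiments are sized to run on one CPU in minutes: 100-seed ensembles
for offset and direction recovery, 500 simulations per φ for significance
calibration, 300 surrogate pairs for coherence significance. Every
stochastic step takes an explicit seed (`SeedSequence`-derived streams);
the pipeline writes a manifest of config hash, seed and artifact digests,
and identical config + seed reproduces byte-identical artifacts.

## Known limitations

* Floating chronologies only: no calendar anchoring, no dating against
  reference masters, no regional-curve standardization or variance
  stabilization.
* The acceptance gates are fixed-threshold, not overlap-adaptive; very
  short overlaps at scan edges are the dominant false-positive source.
* Coherence smoothing choices (reflective edges, boxcar width rounding)
  follow common practice but are not the only defensible ones; absolute
  coherence values near the cone edge should not be over-interpreted.
* LST, Eppt/ET and province boundaries are provisional defaults pending a
  study-specific calibration; MAP's exponential calibration saturates
  logically at CIA-K → 100 and is only as good as its source regression.
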