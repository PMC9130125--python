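# paleodendro

Statistical tooling for inferring paleoclimate from fossil wood and
paleosols: cross-dating of floating ring-width series, smoothing-spline
ring-width-index (RWI) chronologies with signal-strength diagnostics,
continuous and cross wavelet analysis against red-noise nulls, a
growth-suppression coincidence statistic, and paleosol major-element
climate proxies — together with a synthetic forest/paleosol generator so
the whole chain is testable against known ground truth.

**Who it is for.** Deep-time dendrochronology works with *floating*
chronologies: fossil wood from a single bed, cross-matched ring by ring
without any calendar anchor. The scientific questions are whether
statistically robust chronologies can be assembled at all (cross-match
statistics, subsample signal strength), whether they carry oscillatory
climate signals (wavelet power above a red-noise background), and how the
trees responded (do significant oscillation years coincide with narrow or
wide rings?). Paleosol geochemistry from the same strata provides an
independent climate estimate. This package implements each of those steps
as a library with a CLI, plus numbered analysis drivers that reproduce the
whole chain on synthetic data.

## Core statistics

* **Cross-matching** of series a, b at candidate lag L over their overlap:
  t statistics on Baillie–Pilcher (`ln(w / 5-yr moving mean)`) and
  Hollstein (`100·log₁₀ w_{t+1}/w_t`) transforms,
  `t = r√(n−2)/√(1−r²)`, plus Gleichläufigkeit (percent parallel
  covariation). Defaults accept a match when t_BP ≥ 3.5, t_HO ≥ 3.5,
  r ≥ 0.5, GLK ≥ 65 at the top-ranked lag.
* **RWI chronology**: cubic smoothing spline with 50% frequency response
  at 0.67·series length; RWI = width/fit; per-year Tukey biweight mean;
  `SSS(n) = n(1+(N−1)r̄) / N(1+(n−1)r̄)` with cutoff 0.5.
* **Wavelets**: Torrence–Compo-style FFT implementation, Morlet(ω₀=6) and
  DOG(2), 16 voices per octave, cone of influence at e-folding time √2·s,
  significance against the AR(1) spectrum
  `P_k=(1−α²)/(1+α²−2α cos 2πk/N)` via χ²_ν or Monte-Carlo surrogates;
  cross-wavelet power/phase and smoothed squared coherence.
* **Growth response**: fraction of years with significant in-cone DOG
  power in a period band (default 20–40 yr) that fall on RWI < 1
  (suppressed) versus > 1 (enhanced).
* **Paleosol proxies**: molar CIA / CIA-K with authigenic-K correction,
  MAP = 221.1·e^(0.0197·CIA-K), a linear CIA→LST transfer, Eppt/ET energy
  terms and humidity-province classification (all coefficients in config).

## Worked example

```bash
python analysis/01_simulate_forest.py --seed 1
python analysis/02_crossdate.py
python analysis/03_build_chronology.py
python analysis/04_wavelet_analysis.py
```

prints

```
wrote 12 series (6 trees x 2 radii x 100 yr), true assembled span 125 yr -> results
15 accepted matches; mean r 0.85, mean GLK 85.0%
assembled span 125 yr (truth 125), mean overlap 89 yr, excluded: none
offsets recovered exactly
chronology of 125 yr from 6 trees; rbar 0.85; mean RWI 0.990; SSS >= 0.5 from year 1
AR(1) alpha 0.30; in-cone power peaks at 31.7 yr; 9.3% of in-cone cells significant at the 5% level
```

Reading this: twelve simulated radial transects (all starting at relative
year 0, germination offsets hidden) cross-match into a single 125-year
master whose pairwise statistics (r ≈ 0.85, GLK ≈ 85%) would be called
strong in real material; every hidden offset was recovered exactly. The
resulting RWI chronology has high inter-series correlation (r̄ = 0.85), so
its subsample signal strength clears the 0.5 cutoff from the first year.
Morlet wavelet power of the chronology, tested against an AR(1) background
of α ≈ 0.3, peaks at ≈ 31.7 yr — within one voice of the 30-yr oscillation
the generator injected.

The remaining drivers run the other experiments:
`05_growth_response.py` (suppressed-growth fractions of ≈ 62% vs ≈ 41%
under negative vs positive oscillation–growth coupling),
`06_coherence_replicates.py` (replicate chronologies coherent > 0.95 at
their shared 32-yr and 10-yr periods), and `07_paleosol_proxies.py`
(CIA-K contrast QC and the MAP/LST/province chain).

The same stages are available as a CLI over a YAML config:

```bash
paleodendro run --config my_run.yml --seed 1 --out-dir results
```

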