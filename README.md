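# nicospec

Band-difference correlation mapping and classification of
nickel-hyperaccumulator leaf reflectance spectra.

## The problem

A small number of plant species ("hyperaccumulators") concentrate
extraordinary amounts of transition metals in their leaves — for nickel,
at least 1000 µg g⁻¹ dry weight, with typical foliar concentrations around
10,000 µg g⁻¹, versus under 100 µg g⁻¹ in ordinary plants. Ni²⁺ has three
electronic absorption bands in the VNIR region (near 360, 600 and
1000 nm), so extreme foliar Ni should leave a visible imprint on leaf
reflectance between 350 and 2500 nm. If it does, field spectrometers and
drone-mounted imagers become screening tools for discovering new
hyperaccumulator species.

`nicospec` implements that analysis as a tested pipeline for
spectroscopists and chemometricians:

1. **Band-difference correlation mapping.** For a set of N leaves with
   reflectance R_i(λ) on a B-channel grid and Ni concentrations c_i, form
   per sample the difference D_i(α, β) = R_i(β) − R_i(α) for every ordered
   channel pair (α the *subtractor*, β the *subtracted* channel), and
   correlate each cell against concentration across samples:

       r(α, β) = corr( D(α, β), c )

   with a two-sided t-test p-value per cell and masking at the 95%
   confidence level. Materializing the N × B × B difference stack at
   B = 2151 costs over a gigabyte, so the production path uses the
   covariance identity

       r(α, β) = (S(β,c) − S(α,c)) / sqrt( (S(α,α) + S(β,β) − 2·S(α,β)) · S(c,c) )

   where S are sample covariances: one B × B channel covariance matrix
   (~37 MB) yields the whole map. The literal stacked implementation is
   retained as a guarded test oracle.

2. **Hyperaccumulator-vs-normal classification.** Spectra are
   baseline-subtracted at 1350 nm (removing per-sample offsets), split
   75/25 with stratification, and all 2151 channels are fed to a
   100-tree random forest; per-band impurity importance is summarized as
   the shortest wavelength interval holding half the total importance.

Because no public spectral library accompanies this kind of study, the
package includes a first-class synthetic leaf-spectrum generator
(chlorophyll-darkened visible region with a green peak at 550 nm, NIR
plateau, water absorptions at 975/1200/1400/1900 nm, dehydration
brightening, and concentration-coupled Ni absorption dips) that all tests
and analyses run against.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts and write their tables and figures to `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_summary_spectra.py
python analysis/03_correlation_map.py
python analysis/04_classification.py
```

Output of a run:

```
cohort A: 60 hydrated hyperaccumulator spectra, Ni 1527-43404 ug/g (median 10128)
cohort B: 200 dehydrated spectra, groups {'hyper': 100, 'normal': 100}
map: 2151x2151 cells, 2425008 unmasked (52.4%) at 95% confidence
hotspot: alpha=2014 nm, beta=995 nm, r=-0.994 (p=1.30e-56); |beta - 1000| = 5 nm
validation accuracy: 1.000 (50 held-out samples); confusion {'true_hyper_pred_hyper': 25, ...}
dominant importance region (50% of importance): 950-1150 nm
```

Reading this: the correlation map's strongest cell pairs a SWIR reference
channel (α = 2014 nm) with β = 995 nm — within 5 nm of the injected Ni
absorption band — at r = −0.994 (reflectance there *drops* as Ni rises).
The classifier separates hyperaccumulator from normal leaves perfectly on
the held-out 25%, and its feature importance concentrates at 950–1150 nm,
i.e. the Ni band again.

The same pipeline is scriptable (`nicospec simulate | corrmap | classify |
report | demo`) and usable as a library; `nicospec demo --out-dir demo`
runs everything from nothing in well under a minute.

To run it on real data, supply a wide CSV (first column wavelength in nm,
one column per sample, reflectance as fraction 0–1) plus a metadata CSV
with columns `sample_id, species, state, ni_conc, method`.

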