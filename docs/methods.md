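# Methods

## The statistic

Each sample is a reflectance spectrum R_i on a shared B-channel wavelength
grid (canonically 350–2500 nm at 1 nm, B = 2151) paired with a foliar Ni
concentration c_i (µg g⁻¹). The band-difference correlation map assigns to
every ordered channel pair (α, β) the Pearson correlation, across samples,
between the difference D_i(α, β) = R_i(β) − R_i(α) and c_i. α is called
the subtractor channel and β the subtracted channel; the map is
antisymmetric, r(α, β) = −r(β, α), and its diagonal is undefined.

Working with differences rather than raw reflectance makes the statistic
invariant to per-sample additive offsets (illumination level, scattering
baseline) — the same invariance that the classification stage obtains by
subtracting each spectrum's value at 1350 nm. Both facts are asserted as
tests: the difference matrix is unchanged by baseline subtraction, and the
correlation map is unchanged by adding any constant to a spectrum or
rescaling all concentrations.

### Streaming evaluation

Because D is linear in R, every cell's correlation collapses to channel
(co)variances:

    r(α, β) = (S(β,c) − S(α,c)) / sqrt((S(α,α) + S(β,β) − 2 S(α,β)) · S(c,c))

so a single B × B channel covariance matrix, a length-B
channel–concentration covariance vector and the concentration variance
produce the entire map in O(N B² ) time and O(B²) memory (~37 MB at
B = 2151, versus >1 GB for the N×B×B stack at N ≈ 70). Covariances use the
n−1 denominator (it cancels in r; fixed for testability). The covariance
matrix is explicitly symmetrized, (S + Sᵀ)/2, which makes the map exactly
antisymmetric in floating point and hotspot ties between mirror cells
exact. Computed r is clipped to [−1, 1].

The literal formulation — build all N difference matrices, stack,
correlate cell by cell with `scipy.stats.pearsonr` — survives as
`brute_force_map`, guarded to B ≤ 256. It is the independent oracle: the
two paths must agree within 1e−10 on seeded random instances, and because
`pearsonr` derives its p-value through the beta distribution while the
streaming path uses the Student-t transform, the p-values are
cross-checked between two independent routes as well.

### Significance masking

Each cell's two-sided p-value comes from t = r·sqrt((n−2)/(1−r²)) with
n−2 degrees of freedom; cells with p ≥ 0.05 are masked, matching a
per-cell 95% confidence rule applied over all ~4.6 M cells with **no
multiple-testing correction** — deliberately, since that is how such maps
are conventionally screened; Benjamini–Hochberg adjustment over the strict
upper triangle (mirrored down) is available behind an `fdr` flag. Cells
with zero difference variance (including the diagonal) are NaN and always
masked. At n = 24, the smallest per-species group size the pipeline is
sized for, the unmasking boundary corresponds to |r| ≈ 0.404.

The *hotspot* is the unmasked cell with maximal |r|; exact ties resolve to
the smallest β wavelength, then the smallest α wavelength. Note the tie
rule only matters in degenerate situations (for noise-free linear synthetic
data every in-band/out-of-band cell saturates at |r| = 1, and the rule then
picks the shortest-wavelength band); under any realistic noise the maximum
is unique.

## Classification stage

Features are the full baseline-subtracted channel vectors (value at the
channel nearest 1350 nm subtracted per sample; 1350 nm sits on a
reflectance peak between the 1200 and 1900 nm water bands). Labels come
from the Ni hyperaccumulation threshold (≥ 1000 µg g⁻¹, a closed bound;
Mn 10,000, Zn 3000, Co 300 and Cu 300 are also tabulated) or from the
metadata group column. The split is stratified 75/25 with a fixed seed —
stratification is a design choice preventing degenerate single-class
validation sets at small n. The classifier is a scikit-learn random forest
with 100 trees and otherwise default hyperparameters, all echoed verbatim
into the report. Importance is impurity-based, normalized to sum to 1
(permutation importance on the validation set available behind a flag).
The "dominant region" is operationalized as the shortest contiguous
wavelength interval capturing ≥ 50% of total importance, widened outward
to whole 100 nm blocks — this turns an
identified-by-inspection wavelength region into a testable quantity.

## The synthetic leaf model

No public spectral library exists for this problem, so the generator is a
first-class, tested component whose defaults define the study conditions
for every analysis and test.

A baseline spectrum is built from: a scattering continuum at the NIR
plateau level (default 0.50 reflectance); a pigment absorbance term
(dimensionless strength 2.5) covering 400–700 nm with a Gaussian
transmission window at 550 nm (width 35 nm, relief 0.65) that produces the
green reflectance peak; a logistic red edge at 710 nm (width 8 nm); a
gentle SWIR decline (4×10⁻⁵ per nm beyond 1300 nm); and Gaussian water
absorptions at 975/1200/1400/1900 nm with depths 0.10/0.12/0.30/0.38 and
widths 40/40/60/90 nm. Dehydration scales water-band depths by 0.1 and
raises the continuum by 0.08 — applied to the continuum *before* pigment
attenuation, so dried leaves brighten in the NIR/SWIR while the visible
region stays pigment-dark. That detail matters: it is what keeps the
360/600 nm Ni bands masked by chlorophyll in both hydration states, so
visible-region correlations with Ni stay weak, as observed in real leaf
data.

Ni²⁺ absorption is three subtractive Gaussians at 360/600/1000 nm (widths
40/50/60 nm, truncated at 4 widths so distant channels are bit-identical)
whose depth is linear in concentration, k = 5×10⁻⁶ reflectance per
µg g⁻¹ (a log-concentration mode exists behind a switch). Linear depth is
the simplest model consistent with the qualitative physics, and it makes
the noise-free correlation map exactly ±1 at in-band/out-of-band cells —
a closed-form oracle the tests assert. Reflectance is floored at 0, which
is also the mechanism by which the dark visible baseline saturates (and
thus masks) the two visible Ni bands at high concentration.

Concentrations are log-normal with geometric sd 2: hyperaccumulators with
median 10,000 µg g⁻¹ truncated below at 1000 (truncation by resampling,
so no atom forms at the bound), normal plants with median 20 µg g⁻¹
truncated above at 100. Channel noise is i.i.d. Gaussian, sd 0.005
reflectance, added after the Ni dips, with final clipping to [0, 1].

**Two species pools.** The normal class emulates an independent reference
library of ordinary foliage — in surveys of this kind the non-accumulator
spectra come from entirely different species, often a different
measurement campaign — so it carries its own baseline
(`NORMAL_LEAF_PARAMS`): NIR plateau 0.53, dry water retention 0.18, SWIR
slope 5×10⁻⁵, pigmentation equal to the hyperaccumulator pool. Equal
pigmentation is deliberate: across a broad many-species library the
visible pigment signature does not separate the pools consistently, so
the class contrast is placed in NIR–SWIR leaf structure and water
features plus the Ni band. This reproduces the observed structure of the
real analysis — a classifier that separates the classes perfectly while
its importance concentrates near 1000 nm rather than in the visible. A
flat reflectance offset would be unusable as a class signal anyway, since
1350 nm baseline subtraction cancels it.

### What the generator does not emulate

No radiative-transfer realism (no PROSPECT-class leaf model), no
transmittance/absorptance partitioning, no wavelength-correlated or
detector-splice instrument noise, no within-species biological variation
of the baseline (with noise set to zero, two same-group spectra differ
only inside Ni band supports — an invariant the tests rely on), and no
ligand-dependent shifting of the Ni band centres. Consequently, passing
tests demonstrate that the *pipeline* recovers what the generator plants
where it plants it; they cannot certify performance on real leaves, where
baselines vary per sample and absorption features shift and overlap.

## Numerical and interface choices

- Reflectance is stored as fraction in [0, 1]; the CSV reader rejects
  files with values outside [−0.05, 1.5], catching percent-scaled input
  while tolerating minor calibration overshoot.
- Wavelength→channel lookup is nearest-neighbour with ties to the lower
  wavelength; the canonical grid contains 1350 nm exactly.
- Grid resampling is linear interpolation, refusing extrapolation; exact
  on affine spectra.
- CSV round-trips are guaranteed to 12 significant digits (`%.12g`).
- Cells whose difference variance is ≤ 1e−12 of the summed channel
  variances count as undefined (NaN, masked) rather than an error.
- Full-resolution r/p/mask CSV exports (~80 MB each) are opt-in
  (`--write-matrices`); hotspot summaries and figures are always written.
- Figures follow the min-red / mean-black / max-green convention for
  summary spectra; correlation maps use a diverging scale symmetric about
  0 with masked cells in neutral grey, α on x and β on y.

## Problem sizes

Default analyses use 60 hydrated hyperaccumulator spectra for the
correlation map (full 2151² resolution) and 100 + 100 dehydrated spectra
for classification; the oracle-equivalence checks run at N = 30, B = 50
over repeated seeds; hotspot-recovery stability is assessed over 20
generator seeds. These sizes mirror the per-species group sizes such
field campaigns produce (tens of samples per species) while keeping every
stage comfortably within a laptop's memory.

## Known limitations

- Pearson correlation assumes a linear difference–concentration
  relationship; a Spearman mode exists but only through the stacked path
  (ranking defeats the covariance shortcut), hence is guarded to small B.
- The per-cell 95% mask performs no multiplicity control by default; at
  ~4.6 M cells a sizable fraction of unmasked cells in null data are
  false positives. Use `fdr` for exploratory screening of weak signals.
- The hotspot is a single argmax; it summarizes but does not segment the
  elongated significant regions such maps typically show.
- With zero noise and linear depth, |r| saturates at 1 across entire
  band-pair regions and hotspot selection degenerates to the tie rule;
  this is a property of the idealized model, not of noisy data.
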