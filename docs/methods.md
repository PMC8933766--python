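# Methods

This note documents the models, numerical choices and known limitations of
the package, module by module. Problem sizes quoted here are the defaults
the tests and the acceptance script run at.

## Synthetic phantoms

The mouse head is reduced to the structures the morphometry chain needs: a
cerebellar ellipsoid with semi-axes `(r, 0.85r, 0.6r)` (default r = 3.0 mm,
analytic volume ≈ 57 mm³, in the range of the wild-type mouse cerebellum),
an arborized WM tree inside it, and a fourth-ventricle CSF ellipsoid
abutting the cerebellum. The grid defaults to 128 x 128 x 24 voxels at
0.0781 x 0.0781 x 0.5 mm — the in-plane resolution and slice thickness of
a high-field small-animal T2 protocol, deliberately anisotropic.

**WM tree.** Real cerebellar WM (arbor vitae) is a connected branching
structure, and contour-based segmentation is only a meaningful test if the
phantom has real internal contours. The tree is built from a trunk plus
three pairs of branches in the axial plane; WM is the set of cerebellar
voxels whose distance to this skeleton falls below the `wm_fraction`
quantile of all such distances (default 0.25). This makes the WM fraction
exact by construction, keeps the tree connected, and gives branch widths
of a few voxels — thin enough to be a genuine challenge for edge
localization.

**Ventricle.** The ventricle is rasterized from an ellipsoid of the target
volume (default 2.772 mm³, the 16-month patient-model group mean), then
trimmed or grown by ellipsoid-distance rank to exactly
`round(target / voxel_volume)` voxels, so label-derived volume matches the
target to within half a voxel (≈ 0.1%).

**Coil bias.** A surface receive coil gives a smooth monotone sensitivity
decay with depth. The generator uses `g(y) = exp(-ln(B) * y / (n_y - 1))`
along axis 1, so the peak-to-trough ratio is exactly the `bias_strength`
parameter B (default 2.0).

**Intensities.** Tissue means default to background 10, GM 100, WM 160,
CSF 230 (arbitrary grey levels; CSF brightest as in T2 contrast, WM set
brighter than GM so the two-class intensity rule has a definite sign),
with additive Gaussian noise (sd 2.0, i.e. a WM–GM contrast of 30 noise
SDs). The noise level and distribution are not taken from any measurement;
they are chosen for testability and flagged as an assumption. The
homogeneous calibration phantom uses the mean of the non-background tissue
means (163) as its single intensity.

## Bias-field estimation

The calibration phantom is a single tissue, so its log intensity is the
log gain field plus a constant plus noise. `estimate_bias` fits a 3D
polynomial (total degree 3 by default) to log intensity by least squares
and exponentiates, which is exact for exponential-of-polynomial fields —
including the generator's — and has no boundary bias, unlike kernel
smoothing, whose edge effects at a monotone field's boundary were measured
at ~1.7% error (right at the 2% recovery requirement) before this design
was chosen. The field is normalized to mean 1. After division the
calibration volume's residual CV is the noise CV (≈ 1.2% at defaults).

## Normalization and outlier exclusion

Intensity normalization maps the `low_tail` and `1 - high_tail` quantiles
to 0 and 10,000 and clips outside. The stated total exclusion of 1% is
split symmetrically, 0.5% per tail; both tails are configurable. On
phantom images the top tail lands inside the brightest tissue (CSF, then
bright WM), so a few hundred tissue voxels saturate at 10,000 — the same
behavior the rule has on real data, where the hottest CSF voxels clip.

## LoG segmentation

Within the cerebellar mask, edges are voxels where the LoG response
changes sign against a face neighbour and the response jump across the
crossing exceeds `edge_threshold` (default 1%) of the masked response
range. Regions are connected components of non-edge masked voxels; each
component is assigned WM or GM by comparing its mean intensity to an Otsu
split of the masked intensities, with an explicit per-region override
available (this replaces an interactive region-selection step; the mask
argument likewise replaces a manual whole-cerebellum outline — neither
manual step can live in a batch pipeline). Contour voxels and any fully
enclosed remainder are then assigned by their own intensity, so every
masked voxel ends up GM or WM and GM+WM exactly conserves the mask.

Two defaults were settled empirically on the package's own phantoms:

- **Per-slice (2D) filtering.** With 0.5 mm slices and 0.0781 mm in-plane
  voxels, the through-plane curvature term of a full 3D LoG dominates the
  response inside the mask (the masked response becomes single-signed and
  contains no zero crossings at all). The filter therefore runs per slice
  by default, with component connectivity restricted to in-plane
  neighbours; full-3D mode remains available for near-isotropic data.
- **Scale sigma = 1 in-plane voxel.** For thin bright ridges (WM branches
  a few voxels wide), the zero-crossing contour of a larger-scale LoG sits
  outside the ridge boundary; at sigma = 2 voxels this inflates WM roughly
  two-fold (Dice 0.70). At sigma = 1 voxel the contour stays on the
  boundary (Dice 0.998 at default contrast). Sigma is in mm and
  configurable; sub-voxel values warn and proceed.

Volumetry is exact integer voxel counting times the voxel volume
(product of spacings), with `cerebellum = GM + WM` reported alongside.

## Spectral quantification

Spectra live on a descending ppm axis (default 5.0 → 0.2, 1024 points).
The basis is synthesized as sums of Lorentzian lines at literature
chemical shifts (half-width 0.035 ppm; broader for macromolecule and lipid
humps) for a 17-metabolite panel: NAA, NAAG, Cr, PCr, Glu, Gln, Ins, Tau,
Cho, PCh, GPC, GSH, GABA, Lac, Ala, MM, Lip. The line catalogue is a
package data file and is synthetic — line positions follow the literature
but amplitudes and widths were chosen for a well-conditioned design, not
fitted to measured spectra; measured basis sets can be substituted through
the basis-directory format.

The fit solves bounded linear least squares (metabolite coefficients
non-negative, Legendre baseline coefficients free; default baseline order
2). A coefficient pinned at zero is recorded as an active constraint —
non-negativity is enforced by the solver, never by silently clipping a
negative solution. CRLB per metabolite is
`sigma * sqrt([(D'D)^-1]_mm)`, expressed as percent of the fitted
concentration; the design matrix D includes the baseline columns, so
baseline uncertainty propagates into the bound. The noise sd is estimated
from fit residuals in a signal-free window (default 4.4–5.0 ppm, above all
basis lines) with a leverage-corrected denominator
`n_w - tr(H_w)`, which removes the small downward bias from the design
absorbing window noise; a known sigma can be passed instead, making the
CRLB exactly linear in noise. For a zero-pinned metabolite the CRLB is
undefined (NaN) and the metabolite is excluded, matching the filter's
intent. The 24% exclusion rule is "higher than": CRLB exactly 24 is kept.
Monte-Carlo calibration at the default noise shows 2-CRLB coverage of
95.4% per metabolite-replicate cell (the Gaussian two-sigma value), i.e.
the bound is neither optimistic nor inflated.

Referencing is a pure rescaling (water: a nominal tissue-water constant
over the unsuppressed-water area; creatine: division by Cr+PCr), recorded
in metadata and invertible, so metabolite ratios are referencing-invariant.

## Cohort generator

Mouse cohorts default to 9 animals per (group, age) cell at ages 2, 4 and
16 months — 27 per group, the volumetric comparison's n. Volumes and the
five metabolites with reported group values (NAA, NAA+NAAG, Glu, Tau, Ins)
are drawn at the reported means and SDs (SEM x sqrt(n) where only SEM is
printed); the rest of the panel uses literature-plausible rodent levels
with little or no group shift. Metabolites are drawn independently within
group; real panels are strongly inter-correlated, which is why the
synthetic PCA concentrates less variance in PC1 (~15%) than a real cohort
would (~50%) — group separation along PC1 is preserved, the variance
profile is not, and tests assert only the former. Rotarod latencies are
linear in NAA (accelerated: 20 + 180*NAA + N(0, 72) seconds) with noise
sized so the NAA fit lands in the weak-to-moderate r² ≈ 0.35 regime at
study-scale n; 16-month animals have missing latencies, as they were not
tested in the study design this emulates.

Human cohorts default to 18 controls vs 16 patients. GM declines with age
at -0.39 mL/y (controls) and -0.72 mL/y (patients), WM at -0.11 / -0.28,
and patient CSF grows with age in a sex-dependent way (+0.15 M / +0.08 F
mL/y) — the reported slope regime. The patient clinical block (age of
onset, disease duration, CAG repeats, SARA) is drawn from a Gaussian
copula with target correlations onset–duration -0.85, onset–CAG -0.80,
duration–CAG 0.65 and moderate (0.20–0.35) SARA cross-correlations; GM
additionally depends on onset (+0.6 mL/y of later onset) and SARA
(-0.15 mL/point). These choices make the collinearity structure the
screening step faces unambiguous: duration and CAG exceed the |r| > 0.7
threshold against onset with margin (a target of 0.72 leaves sample
correlations below threshold in ~28% of n=200 draws, making the screen's
correct outcome irreproducible), and onset's direct effect dominates the
univariate-AIC contest against its correlated partners. At the real
study's n = 16 that contest is close to a coin flip — which is precisely
the small-sample instability the screening rule exists to resolve, and
why recovery tests run at n = 200.

## Statistics

- **Welch test** via the standard unequal-variance statistic with
  Satterthwaite degrees of freedom (scipy backend).
- **PCA** by SVD of the centred (and by default unit-variance-scaled)
  data; the correlation form is the default because the panel mixes
  scales. Loading signs are fixed by making each component's
  largest-magnitude loading positive.
- **PERMANOVA** from the distance partition: with squared Euclidean
  distances, `SS_total = sum d²/n`, `SS_within` summed per group,
  `pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a))`. The p-value counts
  permutations (seeded, default 9999) with statistic >= observed, the
  observed included, so p ∈ [1/(B+1), 1]. On univariate input this is
  algebraically one-way ANOVA, which the tests exploit as an oracle
  (agreement to 1e-10), alongside a cross-check against an independent
  implementation.
- **Collinearity screen**: pairs are visited in sorted-name order; for
  |r| > 0.7 the member with the lower univariate AIC
  (`n log(RSS/n) + 2k`, k = 2) survives, ties broken by lower p then by
  name; the drop log records r, both AICs and p-values, and flags
  AIC/p-value disagreements (the qualitative "lowest AIC and p" rule can
  conflict; AIC is given priority and the conflict is logged).
- **Covariate retention**: the full `group * age * sex` factorial is
  pruned backward, removing the least significant removable covariate term
  (p > 0.05) one at a time while respecting marginality; group is always
  retained. Per-group age slopes are reported as linear contrasts of the
  final coefficients, both sex-averaged (at the group's observed sex mix)
  and per sex when a sex-age interaction survives. Bonferroni adjustment
  multiplies term p-values by the number of tested terms in the final
  model.

## Pipeline

`run_all` executes synth → morphometry → spectroscopy → stats into one
output directory. The morphometry stage runs a small number of phantom
subjects (default 2 per group; an MJD-like geometry scaled to the reported
volume ratio) through the full imaging chain to document segmentation
quality, while cohort-level volumetric statistics come from the cohort
table — running a full imaging simulation per animal would add minutes of
runtime without changing what the statistics see. The stats stage requires
the spectroscopy stage's fitted metabolite table and fails with a
dependency error when it is missing. The manifest records the config,
seeds, per-stage timings and SHA-256 checksums of all tabular outputs;
deterministic stages reproduce bit-identically under a fixed seed.

## Limitations

- Phantoms have crisp single-tissue voxels: no partial-volume mixing, no
  Rician noise floor, no susceptibility or motion artifacts. Segmentation
  scores on them bound what the chain can do on ideal data, not expected
  in-vivo accuracy.
- The spectral model is exactly linear (no lineshape distortion, frequency
  drift or eddy-current residuals — those are upstream of this package's
  scope), so CRLB calibration results transfer to real spectra only to the
  extent the linear model holds.
- Human volumetry enters as a synthetic table; no human image segmentation
  is performed.
- The synthetic metabolite panel is drawn independently within groups;
  covariance-sensitive quantities (PCA variance profiles, PERMANOVA effect
  sizes) are therefore not comparable to real-cohort values, only their
  qualitative behavior is.
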