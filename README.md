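# mjdmri

Cerebellar MRI morphometry, ¹H-MRS quantification, and cohort statistics
for studying Machado-Joseph disease (MJD / spinocerebellar ataxia type 3)
in a transgenic mouse model and in patients.

MJD is caused by a CAG-repeat expansion in *ATXN3* and hits the cerebellum
hard: cerebellar volume shrinks, the fourth ventricle enlarges, white
matter is lost, and the neurochemical profile measured by proton magnetic
resonance spectroscopy shifts (NAA, glutamate and taurine fall, myo-inositol
rises). This package implements the complete analysis chain that turns raw
T2-weighted stacks, single-voxel spectra and cohort tables into those
biomarkers, together with a synthetic-data module that generates every
input with known ground truth, so the whole chain is testable end to end
without scanner data.

## What it computes

**Morphometry** (`mjdmri.morphometry`) — segmentation-based volumetry of
the mouse cerebellum:

1. surface-coil bias correction: the multiplicative gain field `g` is
   fitted from a homogeneous calibration phantom (low-order polynomial
   least squares on log intensity) and divided out;
2. grey-level normalization to [0, 10000] after excluding 1% of voxels as
   outliers (0.5% per tail);
3. WM/GM segmentation inside a cerebellar mask from zero-crossing contours
   of a Laplacian-of-Gaussian (LoG) response, with contour-bounded regions
   assigned to tissue by mean intensity (overridable per region);
4. volumes as `voxel_count x voxel_volume`, and group fold changes
   `max(m_a, m_b) / min(m_a, m_b)` with a direction flag.

**Spectroscopy** (`mjdmri.spectroscopy`) — a miniature linear-combination
quantifier: spectra are fitted as

    y(ppm) = sum_m c_m * basis_m(ppm) + polynomial baseline,  c_m >= 0

by bounded least squares. Per-metabolite reliability is a Cramér–Rao lower
bound in percent, `CRLB_m = 100 * sigma * sqrt([(D'D)^-1]_mm) / c_m`, with
the noise level estimated from fit residuals in a signal-free ppm window;
metabolites with CRLB above 24% are flagged for exclusion. Concentrations
can be referenced to water or to total creatine (Cr+PCr), and the
diagnostic ratios NAA/Ins and NAA/tCho (tCho = PCh+GPC) are reported.

**Statistics** (`mjdmri.stats`) — the cohort chain: Welch unpaired
t-tests; correlation-matrix PCA with loading reports; one-way PERMANOVA
(Euclidean pseudo-F with a seeded label-permutation p-value, the observed
statistic included in the reference set); behaviour–metabolite linear
regressions; collinearity screening (for predictor pairs with |r| > 0.7,
keep the member with the lower univariate AIC, `n log(RSS/n) + 2k`); and
group x age x sex multiple regression with backward removal of
non-significant covariates (group always retained), per-stratum age
slopes, and Bonferroni adjustment across model terms.

**Synthetic data** (`mjdmri.synth`) — labeled cerebellar phantoms on the
animal-scanner grid (0.0781 mm in-plane, 0.5 mm slices) with an arborized
WM tree, a volume-calibrated fourth ventricle and an exponential coil-bias
field; homogeneous calibration volumes; spectra forward-modeled from known
concentrations; and mouse (27 vs 27 across ages 2/4/16 months) and human
(18 controls vs 16 patients) cohort tables whose group shifts, age slopes
and clinical correlation block mirror the study design.

**Pipeline** (`mjdmri.pipeline`) — one JSON-configured run of
synth → morphometry → spectroscopy → stats writing TSV tables and a
manifest with seeds, checksums and timings.

## Worked example

```python
from mjdmri.pipeline import RunConfig, run_all
run_all(RunConfig(seed=1, out_dir="run_out"))
```

completes in a few seconds and writes `volumes.tsv`, `fold_changes.tsv`,
`metabolites.tsv`, `ratios.tsv` and `stats/*.tsv`. With seed 1 the fold
change table reads:

```
              measure  control_mean  mjd_mean  fold_change direction
cerebellum_volume_mm3      49.60550  20.98080      2.36433  decrease
        wm_volume_mm3      25.50030  18.82630      1.35451  decrease
 ventricle_volume_mm3       1.47188   2.80066      1.90278  increase
```

i.e. the synthetic MJD group shows a ~2.4-fold cerebellar atrophy, ~1.4-fold
WM loss and ~1.9-fold ventricle enlargement, each confirmed by the Welch
tests in `stats/welch_volumes.tsv` (cerebellum: t = 44.3, df = 34.2,
p ≈ 9e-32). The metabolite panel separates the groups multivariately
(`stats/permanova.tsv`: pseudo-F = 5.84, p = 1e-4 at 9999 permutations),
and per-subject diagnostic ratios are lower in the MJD group (mean NAA/Ins
0.13 vs 0.22; NAA/tCho 2.21 vs 4.16). `phantom_volumes.tsv` records the
imaging chain's quality on ground-truth phantoms (WM Dice ≈ 0.99).

The same steps are available from the shell:

```sh
mjdmri pipeline run --config run.json
mjdmri pipeline synth --preset mouse --out cohort.tsv --seed 1
mjdmri morph run --image t2.nii.gz --mask cere.nii.gz \
    --bias-calibration phantom.nii.gz --out volumes.tsv
mjdmri mrs fit --spectrum voxel.txt --basis-dir basis/ --crlb-max 24 --out fit.tsv
mjdmri stats screen --table cohort.tsv \
    --candidates age_of_onset,disease_duration,cag_repeats,sara \
    --outcome gm_volume_ml --out screen.tsv
```

### Cohort table columns

Mouse: `subject_id, species, group (control|MJD), age_months, sex`, tissue
volumes in mm³ (`cerebellum_volume_mm3, wm_volume_mm3,
ventricle_volume_mm3`), 17 metabolite columns in water-referenced units
(NAA, NAAG, Cr, PCr, Glu, Gln, Ins, Tau, Cho, PCh, GPC, GSH, GABA, Lac,
Ala, MM, Lip), and rotarod latencies in seconds (`rotarod_accel_s,
rotarod_stationary_s`; missing for 16-month animals). Human:
`subject_id, species, group, age_years, sex`, cerebellar volumes in mL
(`gm_volume_ml, wm_volume_ml, csf_volume_ml, total_volume_ml`), and the
clinical block (`sara, age_of_onset, disease_duration, cag_repeats`;
missing for controls).

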