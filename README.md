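# pancdwi

Quantitative diffusion MRI analysis of the pancreas: diffusion tensor
imaging (DTI), mean-signal diffusion kurtosis imaging (MSDKI), the
clinical two-point ADC, plausibility-based quality control, and
test–retest / inter-reader agreement statistics — together with a
synthetic acquisition phantom that emulates a clinical 3 T abdominal
protocol so that every stage can be validated by parameter recovery.

## Who this is for

Researchers working on abdominal diffusion MRI who need a tested,
scriptable re-implementation of the standard pancreatic DTI/DKI analysis
chain: denoising and Gibbs-ringing removal, model fitting on a
perfusion-suppressed b-value range, implausible-voxel exclusion, ROI
statistics, and repeatability/agreement summaries — without a scanner or
patient data, thanks to the built-in phantom.

## The models

**DTI** (fitted on b = 200 and 1000 s/mm², excluding b = 0 so IVIM-like
perfusion does not bias the tensor):

    S(b, g) = S0' · exp(−b gᵀ D g)

estimated per voxel by iteratively re-weighted linear least squares on
log-signal (OLS start, two passes with weights equal to squared
predicted signals). From the eigenvalues λ₁ ≥ λ₂ ≥ λ₃:

    MD = (λ₁+λ₂+λ₃)/3,   AD = λ₁,   RD = (λ₂+λ₃)/2,
    FA = √( 3/2 · Σᵢ(λᵢ−MD)² / Σᵢλᵢ² )

**MSDKI** (fitted on the direction-averaged signal MS at
b = 200/1000/1700 s/mm²):

    MS(b) ≈ S0 · exp(−b·MD + (1/6)·b²·MD²·MK)

linear in (ln S0, MD, MD²MK/6) on ln MS; with three shells the solution
is the exact interpolant.

**ADC** (clinical-style, one direction, two points):

    ADC = ln(S(200)/S(1000)) / 800

**QC**: per-map exclusion of voxels with negative diffusivity or
kurtosis, MK > 2.5, FA outside [0, 1], or diffusivity above a free-water
ceiling (default 3.0×10⁻³ mm²/s).

**Agreement**: coefficient of repeatability r = 1.96·√(Σd²/n),
Bland–Altman limits of agreement, ICC(2,1) with
poor/moderate/good/excellent bands, and quadratically weighted kappa
with Landis–Koch bands.

## Worked example

Simulate a two-subject cohort (24×24×6 grid, 6-direction protocol,
SNR 30, two repeats each) and run the full chain — denoising, unringing,
DTI, MSDKI, ADC, QC, ROI statistics:

```bash
echo '{"grid":[24,24,6],"n_subjects":2,"n_repeats":2,"snr":30.0}' > cfg.json
pancdwi all out/ --protocol 6dir --seed 3 --config cfg.json
```

prints the cohort summary (medians over subjects, repeats averaged):

```
     map protocol         units  cohort_median  cohort_iqr  cohort_min  cohort_max  n_subjects
      ad     6dir  x1e-3 mm^2/s       1.091304    0.001036    1.090268    1.092340           2
     adc     6dir  x1e-3 mm^2/s       0.865409    0.007228    0.858181    0.872636           2
      fa     6dir dimensionless       0.226535    0.000038    0.226497    0.226573           2
      md     6dir  x1e-3 mm^2/s       0.863966    0.000501    0.863465    0.864466           2
md_msdki     6dir  x1e-3 mm^2/s       0.993616    0.002029    0.991587    0.995645           2
      mk     6dir dimensionless       0.691821    0.001610    0.690210    0.693431           2
      rd     6dir  x1e-3 mm^2/s       0.748935    0.000172    0.748763    0.749107           2
```

The phantom's pancreas has MD = 1.0×10⁻³ mm²/s and MK = 0.66. The
kurtosis-corrected `md_msdki` recovers MD to within 1%; `mk` lands near
0.69 (the direction-averaged estimand plus a small noise-floor bias).
The plain DTI `md`/`ad`/`rd` sit ~10–15% lower — the expected kurtosis
contamination of a two-shell tensor fit, exactly as in vivo. `fa` ≈ 0.23
reflects the mildly anisotropic crescent (tensor FA 0.237).

The slice-thickness experiment behind the SNR trade-off:

```bash
pancdwi snr-experiment --seed 1
# sd(MK) @ SNR 30: 0.1529
# sd(MK) @ SNR 50: 0.0898
# reduction: 41.3%
```

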