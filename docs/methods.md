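# Methods

## Scope and data model

The package analyses 4-D magnitude diffusion-weighted MRI (NIfTI-1 with
FSL `.bval`/`.bvec` gradient tables) acquired on four shells
b = 0/200/1000/1700 s/mm² with 6 or 16 evenly spread diffusion
directions, six 3 mm axial slices of 3×3 mm voxels, and per-shell
scanner averages 2/4/5 (b = 200/1000/1700). Shell membership uses a
±25 s/mm² tolerance because scanners jitter nominal b-values. Voxel
coordinates are grid indices; the NIfTI affine is carried through
opaquely. Excluded or unfittable voxels are NaN in every scalar map, so
exclusion propagates unambiguously into statistics.

## Preprocessing

**MP-PCA denoising.** For every voxel a patch (default 5×5×3: 75 voxels,
enough spatial samples for up to 49 volumes) by volume matrix is
eigen-decomposed; the number of signal components p is the smallest p
for which the spread of the remaining eigenvalues fits inside the
Marchenko–Pastur noise-bulk width 4σ̂²√((N−p)/M), with σ̂² the mean of
those eigenvalues. Components below the bulk edge are suppressed and
only the centre voxel's series is kept (no overlapping-window
averaging). A slack of 10⁻¹⁰·λ_max in the bulk test classifies
numerically-zero tails of noiseless low-rank data as noise rather than
signal. A 1-voxel window carries no spatial redundancy and passes data
through unchanged (with a warning). The per-voxel σ̂ is returned as a
noise map. No Rician-bias correction is applied after denoising.

**Gibbs unringing** uses the sub-voxel shift principle: each slice is
split in k-space into two complementary cosine-weighted parts, each part
is resampled along its ringing-prone axis at 2·n_shifts+1 shifts
(default 20, i.e. steps of 1/40 voxel) by Fourier phase ramps, the shift
minimising a one-sided local total-variation measure (window 3, the
smaller of the left/right sums so genuine edges are not mistaken for
ringing) is chosen per voxel, and the value is linearly interpolated
back to the grid; the two axis results are summed. Both operations are
linear up to the final clip at zero, hence scale-equivariant.

Processing order is denoising first, then unringing. Motion/eddy and
susceptibility corrections are out of scope.

## Tensor fit and its estimand

DTI is fitted on b = 200/1000 only; the b = 0 volumes are excluded so
that perfusion (IVIM) does not bias the tensor, and the intercept is a
perfusion-suppressed pseudo-baseline. The fit is log-linear least
squares with two re-weighting passes (weights = squared predicted
signals), which matches a signal-domain nonlinear fit to ~1e-6 on
noiseless data. Negative eigenvalues are preserved — the plausibility
mask is the place where they are detected and excluded.

Two estimand caveats are deliberate properties, not defects:

* With tissue MK > 0, a two-shell tensor fit is kurtosis-contaminated:
  its diffusivities are the b-range-dependent secant slopes, ~10–15%
  below the underlying tensor at this b-range and MK ≈ 0.66. This
  mirrors the in-vivo situation; the kurtosis-corrected MD of the
  mean-signal fit (`md_msdki`) is the estimator that targets the tissue
  MD itself.
* The FA formula uses the standard (λ₁−MD)² + (λ₂−MD)² + (λ₃−MD)²
  numerator. (Printed versions of this formula sometimes duplicate the
  λ₂ term — that variant would not vanish at isotropy.)

## Mean-signal DKI and ADC

Mean signals per shell are the arithmetic direction averages; the number
of contributing measurements (directions × averages) weights the fit.
ln MS is regressed on [1, −b, b²]; MK = 6·θ₂/MD². With exactly three
shells the solution is the exact interpolant, so the weighting only
matters for ≥ 4 shells (it is implemented for generality, two
re-weighting passes as in the tensor fit). Voxels with non-positive MS
are NaN; a non-positive fitted MD flags MK as NaN for QC to exclude.
For anisotropic voxels the direction average of tensor-kurtosis signals
is not exactly of single-MD form, so the noiseless-fit values (the
estimand) differ from the tissue parameters by O(1%) at FA ≈ 0.24; the
phantom returns the estimand as ground truth alongside the tissue
values.

ADC is the clinical two-point estimate on a single direction (the first
listed by default, configurable): ln(S(200)/S(1000))/800.

## Quality control and ROI statistics

Per-map exclusion masks: diffusivities outside [0, 3.0×10⁻³] mm²/s
(free-water ceiling at body temperature; literature exclusion rules
phrased as "larger than 1" implicitly use ×10⁻³ mm²/s reporting units
and would exclude plausible voxels if read literally, so the ceiling is
explicit and configurable), FA outside [0, 1], MK outside [0, 2.5], and
NaN. Masks are per map: a voxel can fail MK yet count for MD. ROI
statistics (median, IQR, 10th/90th percentiles, linear-interpolation
convention) are computed over retained voxels only, with the excluded
fraction reported as a percentage of ROI voxels. Cohort summaries
average the two repeats within subject, then take medians/IQRs/ranges
across subjects.

## Repeatability and agreement

* Coefficient of repeatability r = 1.96·√(Σd²/n) (RMS form, no
  mean-centering) — reported alongside Bland–Altman mean difference and
  limits of agreement mean ± 1.96·SD (sample SD), plus a
  proportional-bias slope, so the two conventions stay distinguishable.
* ICC is the two-way random, absolute-agreement, single-measurement form
  ICC(2,1) from the mean-squares decomposition; absolute agreement
  matches the inter-reader question (a consistent but biased reader
  should not score 1). The consistency form is available for
  comparison. Bands: < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9] good,
  > 0.9 excellent.
* Weighted kappa uses quadratic disagreement weights (i−j)²/(k−1)² on
  the declared ordered category set (not merely the observed one).
  Landis–Koch bands are implemented as contiguous half-open intervals
  (≤ 0, (0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 0.8], > 0.8); kappa
  requires integer categories, so averaged half-step Likert scores are
  out of scope.

## The phantom

Anatomy: a pancreas-like crescent (a curved tube, head thicker than
tail, spanning the four middle slices) inside a body ellipse, in air.
The tensor principal axis follows the crescent tangent head-to-tail so
direction sampling is genuinely exercised; a constant-orientation debug
mode exists. Tissue defaults (healthy pancreas scale): AD = 1.3×10⁻³,
RD = 0.85×10⁻³ mm²/s (MD = 1.0×10⁻³, tensor FA 0.237), MK = 0.66,
S0 = 100; body tissue AD = 1.2×10⁻³, RD = 1.05×10⁻³, MK = 0.40,
S0 = 80. Cohort defaults: 12 subjects, 2 repeats, SNR 30.

Forward model per voxel and volume:
S = S0·[(1−f)·exp(−b·gᵀDg + (1/6)b²(gᵀDg)²·MK) + f·exp(−b·D*)], with a
single scalar MK applied to the directional diffusivity (only mean
kurtosis is estimated downstream) and an optional IVIM term (default
off; D* = 20×10⁻³ mm²/s). Noise: each scanner average is an independent
Rician sample — magnitude of complex Gaussian with σ = S0_pancreas/SNR,
SNR defined at b = 0 for a single average — and the delivered volume is
the mean of its averages' magnitudes, mirroring scanner magnitude
averaging. Repeats share the noiseless signal and differ only in the
seeded noise stream; the whole cohort is deterministic from one master
seed. Relaxation weighting, respiratory triggering, EPI distortion and
motion are not modelled: passing recovery tests shows estimator
correctness under Rician noise at protocol SNR, not robustness to
physiological artifacts.

Direction schemes: n = 6 is the icosahedral-vertex set (minimum pairwise
angle 63.43°); n ≥ 7 minimises the antipodal electrostatic-repulsion
energy from a fixed seeded start (n = 16 reaches a minimum folded angle
of ~37°).

## The slice-thickness / SNR experiment

With all else equal, SNR is proportional to excited slice volume, hence
to slice thickness: 5 mm vs 3 mm gives an SNR gain of 5/3. The
Monte-Carlo experiment simulates independent mean-signal decays — each
shell's MS averaging directions × averages Rician samples, as the
protocol's directional average does — at baseline SNR 30 and at
SNR·(5/3), fits MK voxel-wise by the exact three-shell solve, and
reports the percent reduction in sd(MK). At the protocol's effective
per-shell SNR the fit is in the linear error-propagation regime where
sd(MK) ∝ 1/SNR, so the expected reduction is 1 − 3/5 = 40%; the
simulation lands at ~41% (the residual Rician floor at b = 1700 keeps
the baseline slightly super-linear). Without direction averaging the
baseline fit leaves the linear regime and the reduction would be
overstated (~56%).

## Numerical choices and problem sizes

* Logs of non-positive signals: clipped to 1e-12 with a counted warning;
  all-zero voxel series yield NaN, not failures.
* Eigen-decomposition uses symmetric solvers; eigenvalues are sorted
  descending and never clamped.
* Batched voxel processing (4096-voxel chunks for MP-PCA) keeps memory
  below ~1 GB for the 16-direction protocol.
* Test problem sizes are desk scale by design: recovery suites run the
  default 64×64×6 grid for the 12×2 SNR-30 cohort (~90 s) and
  reduced grids (24–32 in-plane) where only contracts are exercised;
  Monte-Carlo checks use 8,000–10,000 voxels and fixed seeds.

## Known limitations

* The phantom's geometry is a stylised crescent; ROI labels are exact,
  so segmentation variability between readers is emulated only through
  externally supplied ROI variants.
* MSDKI estimand ≠ tissue parameters for anisotropic voxels (documented
  above); at FA ≈ 0.24 the MK offset is ~+0.02.
* Quantitative in-vivo normative values cannot be validated here; the
  pipeline validates parameter recovery under its own forward model.
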