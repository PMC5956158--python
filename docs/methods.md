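# Methods

This note records the models the package implements, the defaults it
chooses where the underlying methodology leaves the choice open, and what
the synthetic generators do and do not emulate.

## Acquisition model

The pipeline targets a six-b-value body DWI protocol: b = 0, 50, 100, 150,
600, 1000 s/mm², each acquired in three orthogonal directions, voxels of
1.56 × 1.56 × 5 mm, signal-to-noise ratio ≈ 60 at b = 0 and ≈ 30 at
b = 1000. Directions are combined before any fitting by the voxel-wise
geometric mean of the per-direction signals (the trace-weighted signal); a
zero in any direction annihilates the voxel and is logged. All parametric
maps use NaN — never a sentinel number — for invalid voxels, and all
diffusivities are held internally in mm²/s (published ADC group statistics
of magnitude ~1000 are on the 10⁻⁶ mm²/s scale).

## IVIM fitting

Signal model: `S(b) = S0·[(1−f)·e^(−bD) + f·e^(−b(D+D*))]`.

An IVIM fit is attempted only when the protocol is feasible: at least 4
distinct b-values, with at least 2 on each side of the segmentation
threshold b* (4 free parameters; each exponential segment needs two points
to fix its slope). b* defaults to 200 s/mm², putting {600, 1000} in the
pure-diffusion segment and {0, 50, 100, 150} in the perfusion-sensitive
one.

The fit is segmented: (i) ordinary least squares of ln S against b over
b ≥ b* gives D and an intercept A; (ii) f = 1 − A/S(0); (iii) holding D
and f, a bounded scalar minimisation over all b gives D*. Segmented
fitting is the robust standard for six-b protocols, but the literal
three-step estimate is biased when D* is small: at D* = 5×10⁻³ mm²/s the
perfusion term still contributes ~2% of the b = 600 signal, which can bias
the high-b slope by >10% in unfavourable corners of the parameter space.
The segmented estimate therefore seeds a bounded joint least-squares
refinement of (S0, D, D*, f) (scipy trust-region reflective; on by
default, `FitConfig(refine=False)` restores the pure segmented estimate).
With refinement, noise-free signals anywhere in the physiological box
D ∈ [0.3, 2.5]×10⁻³, f ∈ [0.05, 0.3], D* ∈ [5, 50]×10⁻³ mm²/s are
recovered to ≪0.1%.

Bounds: D ∈ [10⁻⁵, 4×10⁻³] mm²/s, D* ∈ [D, 0.5] mm²/s, f ∈ [0, 1].
Convergence outside the box clips the value and marks the voxel
`nonconverged` (NaN in maps); nonpositive or nonfinite signals mark it
`degenerate`. Fitting is fully deterministic.

ADC uses the two-point log-ratio on the (0, max b) pair by default and
errors, rather than substituting, when the requested pair is absent.
Negative decay rates (signal growth with b, only possible under noise) are
invalid and set NaN, keeping the map's nonnegativity invariant.

## ROI features

Quantiles are computed on the raw ROI values with linear interpolation at
rank h = (n−1)p — never on binned data. Skewness and kurtosis use
population (biased) moments, kurtosis in the Pearson (non-excess)
convention so a Gaussian scores 3; a flag switches to sample-corrected
moments. Entropy is Shannon entropy in bits of the normalised counts of a
256-bin equal-width histogram spanning [min, max] of the ROI; 256 bins
keeps the ceiling at 8 bits, consistent with tumour-ROI entropies of ~7
bits at typical ROI sizes. Bin count and conventions are recorded in every
repository record. Constant or single-voxel ROIs are flagged degenerate
with zero shape features rather than erroring. Whole-tumour ROIs including
cystic/necrotic tissue are the caller's responsibility; nothing is
excluded automatically.

Morphology: volume = voxel count × voxel volume; bounding lengths =
(index extent + 1) × spacing per axis; centre of mass = mean voxel index;
surface voxels counted by 6-connected erosion.

## Repository

JSON-lines, one record per line with a `schema_version`, append-only —
self-archiving with trivial diffing, no server, and deliberately no
connection to hospital record systems. Group summaries use population SD
(matching the moment convention above; a flag gives sample SD). The
case-vs-group report gives, per feature and group, the group mean ± SD,
the index value, its z-score (undefined at SD 0, reported as such) and an
inside-one-SD flag — the tabular equivalent of overlaying an index case's
histogram on a stored group band.

## Classification

**2-step threshold rule.** Step 1 assigns a case to a group when its value
falls within exactly one group's mean ± 1 SD interval. Step 2 handles both
ambiguous configurations — inside both intervals, and inside neither (the
latter is this package's extension; the rule as usually stated covers only
"within both") — by nearest group mean on raw absolute distance, flagged
ambiguous; exact ties go to malignant, the conservative call in cancer
triage. The rule is equivariant under positive affine rescaling of value
and statistics. LOOCV recomputes both groups' mean/SD with the held-out
case excluded at every fold and errors if a fold leaves fewer than two
cases in a group or a zero SD.

**Feature screening.** Two-sided Mann-Whitney U per feature; exact P by
full enumeration of all C(n1+n2, n1) labelings when both groups are ≤ 8
and tie-free, otherwise the tie-corrected normal approximation with
continuity correction. Bonferroni multiplies by the number of features
tested. Because screening every centile then correcting strictly would
contradict the common practice of raw-P thresholds in small cohorts, the
default selects on raw P < α and logs a warning; corrected selection is a
flag. Spearman-correlation pruning clusters selected features by
|ρ| > threshold (transitive closure) and keeps each cluster's smallest
raw P; a preset reproduces the manually pruned single-feature set
{mean, median, kurtosis, skewness, entropy, c15, c75}.

**KNN / SVM.** Stratified k-fold (default 10) cross-validation on z-scored
features (scaler fitted per training fold). SMOTE — synthetic minority
points x_i + u·(x_nn − x_i), u ~ U(0,1), x_nn one of the k = 5 nearest
minority neighbours — is applied to the training portion of each fold
only, oversampling to class parity; applying it before the split would
leak the held-out cases. KNN uses k = 5; SVM an RBF kernel with C = 1 and
internal probability calibration. The methodology being implemented states
none of these; they are recorded here and in the run configuration.
Predicted label is the more probable class; a case is *ambiguous* when the
winning probability does not exceed 0.8 (confident > 0.8, ambiguous in
(0.5, 0.8]). Accuracy is reported both as overall fraction correct and as
balanced accuracy, since single "accuracy" figures for imbalanced cohorts
are not interpretable without the definition. AUC comes from a threshold
sweep (trapezoidal), which provably equals U/(n1·n2) of the scores — a
cross-operation identity the tests assert.

**NRI.** event_net = (corrected − spoiled)/n among malignant cases,
likewise nonevent_net among benign; NRI is their sum, equal to
ΔSensitivity + ΔSpecificity for binary labels, antisymmetric under
swapping the two methods.

All stochastic steps (fold shuffling, SMOTE draws, cohort and phantom
noise) take explicit seeds; identical seeds give bit-identical outputs.

## Synthetic data

**DWI phantom.** Ellipsoidal lesions with per-tissue (S0, D, D*, f) in a
uniform background; the noise-free signal follows the IVIM model exactly,
then Rician corruption `S' = √((S+n₁)² + n₂²)`, n ~ N(0, σ), because
magnitude MRI noise is Rician. σ = background S0 / SNR_b0 with SNR_b0 = 60
by default; one σ per run (inter-scan SNR spread is not modelled). The
phantom is isotropic — the three "directions" are copies of the same decay
plus independent noise — so it exercises direction combination but not
anisotropy. Default grid 32×32×8 at 1.56×1.56×5 mm.

**Feature cohort.** Per group, each feature is drawn as an independent
Gaussian with the published two-group ADC-feature means/SDs as defaults
(malignant n = 37, benign n = 11, e.g. ADC mean 1098 (SD 295) vs 1443
(SD 462) ×10⁻⁶ mm²/s), with the centile-family values sorted per record to
preserve monotonicity. Independence is a deliberate simplification: real
ADC centiles are strongly correlated, and real feature distributions are
not Gaussian. Consequences worth stating: (a) passing tests on this cohort
show the *procedures* are correct, not that real tumours separate this
well; (b) conversely, features whose published group means sit within a
pooled SD of each other (kurtosis, skewness, entropy) overlap heavily
under the Gaussian surrogate, so single-feature LOOCV accuracy on the
synthetic cohort (~0.6 for kurtosis) is far below the near-perfect
separation reported on the real cohort — the surrogate carries the printed
means/SDs but not the real data's higher-order structure. An
`equicorrelation` parameter (shared latent factor) produces the correlated
variant used to exercise centile pruning.

## Problem sizes

The shipped tests and the acceptance script use desk-scale problems chosen
to exercise every code path with comfortable margins: 50 noise-free
parameter sets, a 500-voxel SNR-60 phantom, 100 random ROIs for the
feature oracle, a 40-case LOOCV replay, the 48-case synthetic cohort, and
a 20-phantom end-to-end cohort (10×10×1 grids). The full suite runs in
well under a minute on one CPU.

## Known limitations

- No motion/eddy correction, registration, kurtosis or tri-exponential
  models; masks must share the map grid up to opt-in nearest-neighbour
  resampling.
- The DICOM reader/writer handles the single-frame-per-slice layout the
  phantom writes and standard/Siemens b-value tags; it is not a general
  multi-vendor DICOM-MR harness.
- The 2-step threshold classifier is single-feature by construction;
  multi-feature decisions go through the KNN/SVM route.
- Exact Mann-Whitney enumeration is limited to groups of ≤ 8 without ties;
  beyond that the corrected normal approximation is used.
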