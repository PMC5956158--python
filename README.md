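# miror

Modular ROI analysis and repository for multi-b-value diffusion-weighted
MRI (DWI), built as a desk-scale clinical-decision-support pipeline for
discriminating benign from malignant solid tumours.

Radiologists reading paediatric body MRI face lesions that look alike on
conventional images. Quantitative diffusion parameters help: the apparent
diffusion coefficient (ADC) falls with tumour cellularity, and the
intravoxel-incoherent-motion (IVIM) model additionally separates capillary
perfusion from true tissue diffusion. `miror` turns a multi-b-value DWI
series into parametric maps, summarises a tumour region of interest (ROI)
as first-order histogram features, archives those features in a
self-growing repository, and uses the repository to support the
benign-vs-malignant call for a new case.

## The models

**IVIM biexponential signal decay.** For diffusion weighting *b* (s/mm²),

```
S(b) = S0 · [(1 − f) · e^(−b·D) + f · e^(−b·(D + D*))]
```

with tissue diffusion coefficient *D*, pseudo-diffusion coefficient *D\**
(both mm²/s) and perfusion fraction *f*. Maps are fitted voxel-wise with a
segmented strategy (log-linear fit of the b ≥ 200 s/mm² tail for *D* and
the intercept, *f* from the intercept deficit at b = 0, bounded 1-D search
for *D\**) followed by a bounded joint least-squares polish. The two-point
ADC is `ln(S(b_low)/S(b_high)) / (b_high − b_low)`, by default from the
b = 0 / b = 1000 pair.

**First-order ROI features.** mean, median, the 2nd–98th centiles
(linear-interpolation quantiles on raw values), population skewness
g1 = m₃/m₂^1.5, Pearson kurtosis m₄/m₂², and Shannon entropy in bits over a
256-bin histogram spanning the ROI's value range.

**Classification.** Three routes: (1) a 2-step threshold rule on one
feature — membership in a single group's mean ± 1 SD interval decides;
cases inside both intervals or neither go to the nearer group mean and are
flagged ambiguous — evaluated by leave-one-out cross-validation (LOOCV);
(2) SMOTE-balanced KNN / RBF-SVM on all features under stratified 10-fold
cross-validation with ROC/AUC; (3) net reclassification improvement (NRI)
of any method over a baseline read. Feature screening uses the two-sided
Mann-Whitney U test (exact by enumeration for small tie-free groups) with
optional Bonferroni correction and Spearman-correlation pruning.

## Worked example

```python
import numpy as np
from miror import (PhantomSpec, generate_phantom, fit_ivim_maps,
                   extract_roi_values, compute_features)
from miror.synthetic_phantom import TissueParams, Lesion

spec = PhantomSpec(
    shape=(16, 16, 2), snr_b0=60.0, seed=3,
    lesions=[Lesion(center=(7.5, 7.5, 0.5), radii=(5.0, 5.0, 1.0), label="tumor")],
    tissues={"tumor": TissueParams(S0=1200.0, D=0.9e-3, Dstar=18e-3, f=0.18)},
)
phantom = generate_phantom(spec)                     # 6 b-values × 3 directions
d_map, dstar_map, f_map, s0_map = fit_ivim_maps(phantom.dwi)
values, dropped = extract_roi_values(d_map, phantom.masks["tumor"])
fv = compute_features(values, voxel_volume_mm3=d_map.voxel_volume_mm3)
print(f"ROI n={fv.n_voxels}, D mean={fv.mean*1e3:.3f}e-3 mm2/s, "
      f"median={fv.median*1e3:.3f}e-3, entropy={fv.entropy:.2f} bits")
```

prints (seed 3):

```
ROI n=120, D mean=0.897e-3 mm2/s, median=0.897e-3, entropy=6.21 bits
```

i.e. the 120-voxel tumour ROI recovers the simulated tissue diffusion
coefficient 0.9×10⁻³ mm²/s to within ~1% under Rician noise at SNR 60, and
its histogram carries 6.2 bits of spread. The same stages are scriptable
from the shell via the `miror` command (`miror simulate phantom`,
`miror fit-maps`, `miror extract`, `miror repo`, `miror classify`,
`miror nri`; see `miror --help`).

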