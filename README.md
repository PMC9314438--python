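# polaristroma

Quantitative polarized-light microscopy of tumour stroma. Collagenous
stroma is birefringent: between crossed linear polarizers rotated
through 90° in 5° steps, its transmitted intensity follows
y(θ) = A·sin²(2(θ−φ)) + c while other tissue stays dark. This package
turns such 18-frame angular stacks into prognostic stromal biomarkers
and is aimed at researchers studying the desmoplastic reaction at
invasive tumour fronts (e.g. stage III colorectal cancer), where
stromal maturity correlates with 5-year survival.

The pipeline:

1. **Parametric images** — per pixel: intensity
   MIR = √(Σ(y−ȳ)²/(Z−1)); orientation B = argmax_θ y(θ); alignment
   MAD = mean pairwise min(|ΔB|, 90−|ΔB|) over a 5×5 window; abundance
   R² of the sinusoid-squared fit, thresholded at R² > 0.75
   (flood-field correction supported).
2. **Texture** — per ROI and per parametric image, symmetric 8-level
   GLCMs at distance 1 along 0°/45°/90°/135°, averaged Haralick
   contrast, correlation, energy, homogeneity, entropy.
3. **Features** — 3 polarimetric summaries + 5 texture features × 3
   images = 18 features per ROI; log transform then Z-score.
4. **Clustering** — K-means, Fuzzy C-means and a Gaussian mixture
   (k = 2) on the normalized ROI table; patient assignment by strict
   majority vote (exact ties unassigned) or by feature averaging
   (always assigned).
5. **Survival statistics** — 2×2 patient cluster × 5-year survival
   table; two-tailed Fisher exact test, sensitivity / specificity /
   accuracy / PPV / NPV, odds ratio ad/bc with Woolf 95% CI.

Everything is exercisable offline: a phantom generator renders
ground-truthed fiber stacks obeying the signal model, and a cohort
generator plants two-phenotype feature structure with
survival-probability differences. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
from polaristroma import (PhantomSpec, generate_stack, derive_parametric,
                          RoiRect, compute_roi_features)

spec = PhantomSpec(width=256, height=256, coverage_fraction=0.5,
                   fiber_orientation_concentration=5.0, seed=42)
stack, truth = generate_stack(spec)        # 18 frames, 0..85 deg
images = derive_parametric(stack)          # MIR, MAD, R2 maps
feats = compute_roi_features(images, RoiRect(16, 16, 224, 224))
```

prints (selected features):

```
median_intensity       0.0535
median_alignment       15.9333
abundance_ratio        0.5264
intensity_contrast     3.1871
abundance_entropy      2.9911
planted coverage       0.5
```

The abundance ratio (fraction of ROI pixels with R² > 0.75) recovers
the planted 50% fiber coverage; the median alignment of ~16° reflects
the moderately concentrated orientation distribution (0° would be
perfectly parallel fibers, ~22.5° fully disordered); median intensity
is in input-brightness units.

The same stages run from the shell:

```sh
polaristroma simulate cohort --seed 3 --out cohort.csv
polaristroma run --seed 3 --out results/
polaristroma simulate stack --seed 1 --out phantom/
polaristroma derive --stack phantom/stack.tif --out derived/
```

`polaristroma run` fits all three models on a (simulated or supplied)
cohort, aggregates by both rules, and writes a JSON report with the
diagnostic metrics, Fisher p and the odds ratios of the
polarimetry-only (3), texture-only (15) and combined (18) feature
subsets.

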