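# ardaceph

Ageing-related dynamic attention (ARDA) analysis on lateral-cephalometric-style
radiographs: train a CNN age regressor, extract Grad-CAM ageing-salience maps,
aggregate them into per-age attention maps, quantify attention per anatomical
instance, and feed the attention back as a constraint for adult age estimation
with a two-pass retest protocol.

## Who this is for

Researchers studying craniofacial development and degeneration who want an
objective, population-scale picture of *where* in a lateral skull radiograph
age-related change concentrates (teeth, craniofacial bones, cervical spine),
and forensic practitioners interested in age estimation from complete or
partial radiographs. Because clinical radiographs cannot ship with software,
the package includes a synthetic ageing phantom with known per-structure
change rates, so every stage is testable end to end without patient data.

## The method

1. **Age regression.** A CNN `f` maps a grayscale radiograph `x` to a decimal
   age `ŷ = f(x)`, trained with the L1 loss
   `L = (1/N) Σₙ |ŷₙ − yₙ|`.
2. **Ageing salience (Grad-CAM).** For the last convolutional feature maps
   `Fᵏ` (size h×w, Z = h·w), channel weights are the globally averaged
   gradients `wₖ = (1/Z) Σᵢⱼ ∂ŷ/∂Fᵏᵢⱼ`, and the subject's salience map is
   `M = ReLU(Σₖ wₖ Fᵏ)`, upsampled to the image grid and min–max normalised.
3. **ARDA maps.** The attention map of integer age `a` is the element-wise
   mean over the `N_a` subjects of that age: `A_a = (1/N_a) Σₙ M_{a,n}`.
4. **Quantification.** Pixels of `A_a` at or above its median / 75th / 90th
   percentile form the *ageing-significant region*; the quantified ARDA of an
   anatomical instance is the mean of `A_a` over the intersection of the
   instance mask with that region.
5. **Constrained estimation and retest.** Above an age cutoff `KA` (default
   25 y), a second two-channel model receives the subject's own salience map
   as an extra input channel. At inference the baseline predicts first; only
   if its prediction exceeds `KA` is the subject re-estimated by the
   constrained model, and that second estimate is final.

The regressor trains without a head intercept and salience is averaged over a
small ensemble of independently seeded extractors — both choices keep the
attention decomposition identifiable (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from ardaceph import (study_config, generate_cohort, SalienceEnsemble,
                      build_arda, significant_region, quantify_instances,
                      normal_band)
from ardaceph.phantom import label_names, render_subject

spec = study_config(n_subjects=600, seed=0)      # 64x64, ages 4-40
images, manifest = generate_cohort(spec)
X = np.stack([im.pixels for im in images])
y = manifest["age"].to_numpy()

ens = SalienceEnsemble(n_members=3, seed=0, epochs=20).fit(X[:500], y[:500])
mae = np.abs(ens.predict(X[500:]) - y[500:]).mean()
print(f"test MAE: {mae:.2f} years")

maps = ens.cohort_salience(X, manifest["id"], manifest["age"])
arda20 = [a for a in build_arda(maps) if a.age == 20][0]
labels = render_subject(spec, 20.0, 0).label_map
q = quantify_instances(arda20, significant_region(arda20, "p75"),
                       labels, label_names(spec))
print(q[["instance", "value"]].to_string(index=False))

print(normal_band(0.089, 0.015, 2.0))
```

prints:

```
test MAE: 3.24 years
instance    value
    fast 0.705315
    slow 0.668298
  static 0.484248
```

and `(0.059, 0.119, 95.45)` — i.e. on a quick 600-subject demo the regressor
recovers age to ~3 years (the 2000-subject study configuration reaches under
1 year), the fast- and slow-changing structures carry clearly more
quantified attention than the static distractor at age 20, and a
mandibular-bone attention value of μ = 0.089, σ = 0.015 implies a ±2σ normal
band of 0.059–0.119 covering 95.45 % of healthy subjects.

A command-line interface wraps the same library:

```bash
arda-ceph run --out runs/demo          # end-to-end phantom pipeline
arda-ceph regions -w 2144 -h 2304      # the three concentrated-region boxes
arda-ceph count-params resnet50        # comparison-family parameter counts
arda-ceph band --mu 0.089 --sigma 0.015
```

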