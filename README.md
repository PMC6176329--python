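# spinecurve

Unsupervised scoliosis screening from 2-D spine CT slices: detect vertebral
bodies with a cascade gentle-AdaBoost classifier over fused Haar/LBP/HOG
features, shrink each detected box onto the vertebral boundary with
distance-regularized level-set evolution (DRLSE), extract vertebral
centroids, fit the spinal curve, measure the tangent-angle spinal curvature,
and label the spine normal or abnormal from clinical curvature priors.

The package is aimed at medical-image-analysis researchers who want a
landmark-free curvature measurement: no vertebral endplates are annotated
(as Cobb-angle measurement requires), and no labeled curvature dataset is
needed — supervision enters only through vertebra/background patches for
the detector.

## Method

**Detection.** A sub-window (default 90×80 px) is described by a fused
feature vector `F = [F_Haar | F_LBP | F_HOG]` (rectangle contrasts from an
integral image, per-subregion 256-bin local-binary-pattern histograms, and
block-normalized histograms of oriented gradients), z-scored per feature.
Stages of a cascade are gentle-AdaBoost ensembles of decision stumps:
weights start at `1/(2m)` per negative and `1/(2l)` per positive, each
round selects the stump minimizing the weighted error
`ε = Σᵢ wᵢ |h(xᵢ) − yᵢ|`, and correct samples are down-weighted by
`β = ε/(1−ε)`. The stage score is `Σₜ αₜ hₜ(x)` with `αₜ = log 1/β`; its
threshold starts at `½ Σ αₜ` and is lowered to the largest cut meeting a
per-stage true-positive-rate target (0.9), subject to a false-alarm target
(0.03), for up to 10 stages trained on bootstrapped hard negatives. A
scanned window survives only if every stage accepts it; accepted windows
are grouped and averaged, and survivors are numbered in raster order.

**Segmentation.** Each detected box initializes a level-set function
(`φ = −c₀` inside, `+c₀` outside) on a CLAHE-enhanced region of interest
and evolves under

    ∂φ/∂t = μ div(d_p(|∇φ|) ∇φ) + λ δ_ε(φ) div(g ∇φ/|∇φ|) + α g δ_ε(φ)

with edge indicator `g = 1/(1 + |∇(G_σ ∗ I)|²)`, a cosine-smoothed Dirac
`δ_ε`, and the double-well potential factor `d_p` that keeps φ close to a
signed distance function without reinitialization. Defaults follow the
standard parameterization μ=0.04, λ=5, α=1.5, ε=σ=1.5, 200 iterations; the
positive area weight contracts the box onto the vertebra.

**Curvature and diagnosis.** Vertebral centroids `(k, l)` are binary-mask
centers of mass; a least-squares polynomial `col = f(row)` through the
ordered centroids gives the spinal curve, and the curvature angle is the
angle between the tangents at the two terminal centroids,

    φ = | ∫ₐᵇ y″/(1+y′²) dx | = | arctan y′(b) − arctan y′(a) |.

Coronal view: scoliosis iff φ ≥ 10°. Sagittal view: normal iff φ lies in
the region's physiologic range (cervical 35–45°, thoracic 20–45°, lumbar
40–60°).

A synthetic phantom module renders spines as superellipse blobs along an
analytic centerline with known centroids and closed-form curvature angle,
so the whole pipeline is testable without any external imaging data.

## Worked example

Train a phantom-scale detector (3 stages, 24×20 window) on six synthetic
spines and measure an unseen phantom with a ~30° lateral curve:

```python
import numpy as np
import spinecurve as sc
from spinecurve.phantom import (phantom_pipeline_config, generate_training_patches,
                                make_background_sampler)
from spinecurve.cascade import train_cascade, detect
from spinecurve.drlse import segment
from spinecurve.spine import analyze

cfg = phantom_pipeline_config()
train_specs = [sc.spec_for_angle(a, seed=100 + i)
               for i, a in enumerate([0, 5, 15, 30, 45, 15])]
pos, neg = [], []
for spec in train_specs:
    patches, labels = generate_training_patches(spec, 28, 56,
                                                window=cfg.features.window)
    pos.append(patches[labels == 1])
    neg.append(patches[labels == 0])
model = train_cascade(np.concatenate(pos), np.concatenate(neg),
                      cfg.features, cfg.detector,
                      neg_sampler=make_background_sampler(train_specs,
                                                          cfg.features.window),
                      rng=np.random.default_rng(0))

spec = sc.spec_for_angle(30.0, seed=2024)
image, truth = sc.generate_spine_phantom(spec)
detections = detect(model, image, cfg.detector)
masks = segment(image, detections, cfg.levelset)
report = analyze(masks, view="coronal")

print(f"true angle : {truth.phi_true:.2f} deg")
print(f"vertebrae  : {len(detections)} detected "
      f"(recall {sc.detection_recall(detections, truth, 0.5):.2f})")
print(f"measured   : phi = {report.phi:.2f} deg  (R^2 = {report.r_squared:.4f})")
print(f"diagnosis  : {report.diagnosis}  [{report.rule}]")
```

Output:

```
true angle : 29.68 deg
vertebrae  : 7 detected (recall 1.00)
measured   : phi = 29.50 deg  (R^2 = 0.9922)
diagnosis  : abnormal  [coronal: phi = 29.5 >= 10 deg (scoliosis)]
```

All 7 vertebrae are found, the level-set masks reproduce the built-in
tangent angle to within a fraction of a degree, and the ≥10° coronal rule
fires.

The same pipeline is scriptable from the shell:

```sh
spinecurve simulate --angle 30 --seed 7 --out sim/
spinecurve train-detector --pos patches/pos --neg patches/neg --out model.json
spinecurve run --image sim/phantom.png --model model.json --view coronal --out out/
```

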