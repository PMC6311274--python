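# mhmmseg — pathological vessel segmentation with multiple hidden Markov models

Segmenting vessels in 3-D CT is hardest exactly where it matters clinically:
where calcified plaque presses against the wall, where a stenosis narrows the
lumen, and where the boundary contrast collapses. `mhmmseg` implements an
axis-constrained statistical segmenter for that regime, aimed at researchers
in vascular image analysis: given a gray-scale volume and a vessel axis
(centerline), it delineates the lumen, the intima (vessel boundary),
pathological tissue and the outer adventitia along every cross-section, and
fuses them into a volumetric vessel mask.

## The model

For each axis point, 72 rays fan out every 5° in the plane orthogonal to the
axis; each ray carries n = 18 samples at the voxel pitch. Five multiscale
Hessian vesselness responses are evaluated at the samples — the Sato (f¹),
Frangi (f²), Shikata (f³), Li (f⁴) and Manniesing (f⁵) filters, each taken as
the maximum over the scale schedule s = 0.6·2^((w−1)/2) mm, w = 1…6 — and
quantized into N = 10 symbols with extra resolution in the value range where
the pathology distribution overlaps the lumen and intima distributions.

Each feature k feeds a discrete hidden Markov model
φ_k = (M, N, π, A, B) with M = 4 tissue states T₁…T₄ (lumen, intima,
pathology, adventitia), π = (1,0,0,0) because decoding starts on the axis
inside the lumen, row-stochastic transitions A and column-stochastic
emissions B (N×M). The forward–backward recursions give each ray an n×4
posterior *similarity map* P(T | φ_k, F^k). The multiple-HMM classifier is
the convex combination

    Φ = Σ_k α_k φ_k ,   P(T | Φ, F) = Σ_k α_k P(T | φ_k, F^k),
    α_k = Precision_k / Σ_w Precision_w,

where Precision_k = TP/(TP+FP) is HMM k's training precision for
vessel calls (decoded lumen ∪ intima). Per position the decoded state is
T' = argmax_T P(T | Φ, F); voxels visited by several rays receive the argmax
of their mean posterior, and the final vessel mask is the set of voxels
decoded lumen or intima. Accuracy is scored by Dice overlap (DOC, %) and
average symmetric surface distance (ASD, mm), with a paired t-test helper
for method comparisons.

Because no public data ships with the package, a first-class phantom
generator produces seeded ground-truthed volumes: bright tubes of 0.7–6.0 mm
diameter around straight, curved or bifurcating axes, 2–4-voxel wall shells,
stenosis dips, hyperdense calcified arcs, optional partial-volume rendering,
and additive Gaussian noise at variances 20–80.

## A worked example

Training five HMMs on pooled ray series from three noisy tube phantoms and
decoding a fresh ray (`python examples/04_hmm_similarity_map.py`) prints the
precision-derived fusion weights

```
fusion weights alpha_k (normalized training precisions):
  sato        alpha = 0.227  (precision 0.979)
  frangi      alpha = 0.193  (precision 0.830)
  shikata     alpha = 0.168  (precision 0.723)
  li          alpha = 0.190  (precision 0.818)
  manniesing  alpha = 0.222  (precision 0.955)
```

and the fused similarity map of one ray walking outward from the axis:

```
        lumen  intima  pathol  advent   decoded
  v1    1.000   0.000   0.000   0.000   lumen
  v2    0.567   0.433   0.000   0.000   lumen
  v3    0.038   0.942   0.000   0.021   intima
  v4    0.001   0.520   0.000   0.478   intima
  v5    0.000   0.257   0.000   0.743   adventitia
  v6    0.000   0.014   0.000   0.986   adventitia
```

The posterior mass hands over from lumen to intima between v2 and v3 and to
adventitia at v5: the vessel boundary on this ray lies between samples 4 and
5, i.e. at a radius of about 4 × 0.7 mm. The per-feature precisions show why
fusion helps — the weaker features (here Shikata, which spends most of its
symbols on small vessels) are down-weighted rather than discarded.

The other examples generate a pathological phantom (`01`), profile the five
vesselness filters and their scale selection (`02`), tabulate and quantize
ray series (`03`), and run a miniature noise sweep (`05`).

## Command line

A thin CLI mirrors the pipeline stages:

```bash
mhmmseg phantom --out ph/ --axis-spec helical --noise-variance 40
mhmmseg features --volume ph/phantom.nii.gz --feature all --out-prefix ph/resp
mhmmseg series --volume ph/phantom.nii.gz --axis ph/phantom_axes.json \
        --labels ph/phantom_labels.nii.gz --out series.csv
mhmmseg train --series series.csv --out model.yaml
mhmmseg segment --model model.yaml --volume ph/phantom.nii.gz \
        --axis ph/phantom_axes.json --out seg.nii.gz
mhmmseg evaluate --seg seg.nii.gz --ref ph/phantom_labels.nii.gz
mhmmseg --seed 1 experiment --out results/
```

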