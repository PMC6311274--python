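# Methods

This note documents the model, the numerical choices, the synthetic data the
package is validated on, and the known limits of both. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Vessel axis + cross-section model

The segmenter never searches the whole volume: it walks an externally
supplied vessel axis (an ordered 3-D polyline in world millimetres) and
reasons about one cross-section at a time. Axis extraction is out of scope;
axes are inputs (JSON polylines) or come from the phantom generator.

At each axis point an orthonormal in-plane frame is built by parallel
transport: the previous in-plane vector is projected onto the new
cross-section plane and renormalized. Unlike a Frenet frame this never flips
at inflection points; on a smooth axis consecutive frames differ by a few
degrees (tested). 72 rays leave the axis point every 5°, each carrying 18
collinear samples whose default radial step is the smallest voxel dimension
— the native resolution of the scan. Intensities and feature values are
trilinearly interpolated; tissue labels use nearest-voxel lookup. Rays that
leave the volume are dropped with an error (or counted and skipped in batch
mode), never zero-padded, because padded samples would contaminate the
emission statistics.

### Tissue labels along a ray

Four classes are used: lumen (T₁), intima (T₂), pathology (T₃), adventitia
(T₄). The intima is defined *operationally*: along each ray the last 2–4
consecutive vessel samples before the first non-vessel sample are relabeled
intima (the thickness follows the local radius — 2 voxels below 1.5 mm, 3 up
to 2.5 mm, 4 above; thresholds configurable). Pathology is only modeled
outside the intima, which reflects the physiology of calcified plaque being
wrapped by the internal elastic lamina. Rays whose first sample is not
vessel, or in which vessel reappears after the boundary (possible on
strongly curved vessels and near bifurcations), are flagged invalid and
excluded from training; the decoded state graph cannot return to lumen, so
those paths would be unlearnable anyway.

## The five vesselness features

All five responses derive from the eigenvalues λ₁ > λ₂ > λ₃ of the Gaussian
scale-space Hessian. Derivatives are taken in millimetres (the kernel width
per axis is s/spacing voxels); the image mean is subtracted first so the
truncated derivative-of-Gaussian kernels (truncate = 6σ) return exactly zero
on constants. Eigenvalues come from a batched symmetric eigendecomposition,
descending by value.

* Sato: |λ₂|·exp(−λ₁²/(2a²λ₂²)), a = α₁ = 0.5 for λ₁ ≤ 0, a = α₂ = 2
  otherwise; 0 where λ₂ = 0.
* Frangi: (1−e^(−R_A²/2α²))·e^(−R_B²/2β²)·(1−e^(−S²/2γ²)) with α = β = 0.5;
  0 where λ₂ > 0 or λ₃ > 0. The ratios R_A = |λ₂|/|λ₃|,
  R_B = |λ₁|/√(|λ₂λ₃|) and the structureness S use magnitude-sorted
  eigenvalues, as value-sorted ratios are ill-behaved; the sign guard uses
  the value-sorted ones.
* Shikata: s²·|λ₂|/I(x), with intensities shifted to ≥ 1 before division
  (CT values can be zero or negative).
* Li: |λ₂(λ₂−λ₃)/λ₁| where λ₁ < 0 and λ₂ < 0, else 0. Note the division by
  λ₁ makes this response diverge on perfectly straight bright tubes, where
  the axial curvature crosses zero; the robust normalization below absorbs
  this.
* Manniesing: the Frangi form times the noise gate exp(−2c²/(|λ₂|λ₃²)),
  zero where λ₂ ≥ 0 or λ₃ ≥ 0. c defaults to γ/2; the gate suppresses
  weak-curvature voxels and tends to 1 as c → 0.

Every response is returned as a nonnegative magnitude: the printed formulas
evaluate to negative numbers inside bright tubes under the λ-ordering above,
but downstream binning needs one positive scale, and a bright tube should
score high, not low.

**Scale normalization.** `hessian_eigenvalues` returns true second
derivatives (intensity/mm²). For the multiscale maximum over the schedule
s = 0.6·2^((w−1)/2) mm (w = 1…6, matching vessel diameters 0.7–6 mm), the
eigenvalues are γ-normalized (multiplied by s²) before the Sato, Frangi, Li
and Manniesing formulas; the Shikata formula carries its own explicit s²
factor and therefore receives raw eigenvalues. Without this normalization
the response of *any* structure is maximal at the smallest scale and the
"maximum response picks the matching scale" property is vacuous; with it,
the best scale tracks the tube radius to within one schedule step for all
five features (tested on analytic Gaussian tubes).

**Structureness scale γ.** γ is half the maximum Frobenius norm of the
(normalized) Hessian over the whole image *and the whole scale schedule*,
computed once per volume. Computing γ per scale would make the S-term
constant at the image's strongest structure and destroy the Frangi and
Manniesing scale selectivity. Consequence worth knowing: γ is a global image
statistic, so a single hyperdense object (a large calcification) rescales
the Frangi/Manniesing responses of the whole volume. Mixed populations where
only some volumes contain such objects therefore need the calibration below.

## Quantization

Feature values are mapped to a normalized scale on which the 99.5th
percentile of the training values equals 100 (fitted once on training data,
reused unchanged at test time), then binned into N = 10 symbols: one bin
below a₁, K₁ = 5 equal sub-bins on [a₁, a₂), K₂ = 3 on [a₂, a₃), one
overflow bin above a₃ — resolution concentrated where the pathology
distribution overlaps lumen and intima. Intervals are half-open and
left-closed; quantization is total on [0, ∞).

Two sources for the breakpoints are provided. The fixed per-feature defaults
(Sato 25/35/50, Frangi 15/20/30, Shikata 85/95/120, Li 40/45/55, Manniesing
15/25/45 on the normalized scale) are the package default. The `fitted` mode
re-derives them from the labeled training histograms — a₁ at the 10th
percentile of the intima values, a₂ at the median of lumen ∪ intima, a₃ at
the 90th percentile of the lumen values — and is what the experiment
pipeline uses, because fixed breakpoints presuppose a particular feature
scale: on the synthetic data the Shikata and Li values concentrate far below
their fixed a₁, wasting eight of their ten symbols.

## HMM training and decoding

Each per-feature HMM is discrete with M = 4 states and N = 10 symbols;
π is pinned at (1,0,0,0) and never re-estimated (decoding starts on the
axis, inside the lumen). Forward–backward uses per-position scaling, so
series of any practical length cannot underflow; an observation sequence
that is impossible under the model raises an error naming the first
impossible position. Baum-Welch accepts batches of equal-length series
(vectorized E-step) or mixed lengths (grouped), floors every probability at
ε = 10⁻⁶ after each M-step and renormalizes, and stops at relative
log-likelihood improvement < 10⁻⁶ (default) or 500 iterations.

Two initializations exist. Uniform init follows the general principle (A and
B uniform); because EM then fixes state *semantics* only up to permutation,
trained states are matched to tissue names by maximum-agreement (Hungarian)
assignment against training labels before precision is computed. Supervised
init — A from labeled transition counts, B from labeled emission counts — is
the default: it pins state semantics and is the exact maximum-likelihood fit
when the state series are observed, which in training they are. The
experiment pipeline therefore uses the supervised counts directly
(`max_iter = 0`): further EM iterations treat the states as hidden again and
demonstrably re-purpose them (the "lumen" state contracts onto the bright
core and the decoded boundary becomes duration- rather than evidence-driven),
degrading boundary accuracy. Tempering the counted transition matrix toward
uniform was tried and rejected for the same reason — the duration prior it
weakens is carrying real information.

Decoding is position-wise posterior argmax (not Viterbi), ties toward the
lower state index; a lumen/intima tie is immaterial because both count as
vessel. Training precision is per-voxel: TP/(TP+FP) of vessel calls
(decoded ∈ {lumen, intima}) against vessel labels, 0 (with a warning) when
nothing is called positive. The five per-feature posteriors are fused with
α_k = Precision_k/ΣPrecision_w; rows of the fused map still sum to 1.

## Volumetric fusion

Cross-sections are decoded at every axis point. Each ray sample contributes
its fused 4-vector posterior to its nearest voxel; a voxel's label is the
argmax of the mean of all contributions, voxels never touched by a ray stay
background (the method is deliberately axis-constrained), and the vessel
mask is the set of voxels labeled lumen or intima. The same mean rule
handles overlapping cross-sections on curved vessels. The whole chain is
deterministic given inputs and seeds.

## Metrics

DOC = 100·2|A∩B|/(|A|+|B|) (two empty masks agree perfectly). ASD extracts
boundary voxels by 6-connectivity erosion difference and averages
nearest-boundary distances symmetrically via a spacing-aware Euclidean
distance transform; exact for axis-aligned geometry to within half a voxel
diagonal. The paired t-test is two-sided with α = 0.05; all-zero differences
give p = 1.

## Synthetic phantoms: what they emulate, and what not

`PhantomConfig`/`generate_phantom` build seeded, ground-truthed volumes on
anisotropic grids (default 48³ at 0.7 mm): a bright lumen around a straight,
helical or bifurcating axis (children taper by Murray's law, r_child =
2^(−1/3)·r_parent), radii 0.35–3.0 mm possibly dipping along the arclength
(stenosis), a 2–4-voxel intima shell, optional calcified arcs hugging the
wall, optional partial-volume blending at the outer boundary, and i.i.d.
Gaussian noise of configurable variance. Default tissue intensities are
CT-like: background 40, wall 120, lumen 250, calcification 1100 (hyperdense,
ordered as the pathology demands). Sub-voxel-caliber segments voxelize to
the line of axis-containing voxels rather than a broken dash.

The intima shell has two realizations. `wall_mode="tissue"` (default) wraps
a distinct gray wall around the bright lumen — the clinical picture of a
low-contrast outer boundary. `wall_mode="stripped"` makes the intima the
outermost shell of the bright tube itself — the structure of synthetic
vascular-tree volumes, where the marked vessel *is* the bright object and
the boundary class is produced by stripping. The noise-sweep experiment uses
the stripped form, which is what its reference design corrupts with noise.

Phantoms are tubes and simple bifurcations, not full trees: no flow-related
intensity gradients, no organ context, no beam-hardening or streak
artifacts, and noise is white rather than CT-correlated. Passing the suite
therefore demonstrates the statistical machinery and its geometry handling,
not clinical-grade performance.

## The noise-sweep experiment

`run_experiment` mirrors the reference design at desk scale: 15 training and
5 testing geometries (configurable), each rendered at all four noise
variances 20/40/60/80; one MHMM is trained on the pooled labeled series of
all training volumes (60 at default scale), and each test volume is
segmented and scored per level. Test geometries are shared across levels so
the sweep isolates noise. Geometries are drawn as tree segments: straight
(45%), gently curved (35%, curvature radii ~20–40 mm), bifurcating with
Murray tapering (20%); calibers 0.9–2.8 mm (bifurcation parents 1.4–2.8).
Stenoses and plaques are available via `stenosis_fraction`/`plaque_fraction`
but default to 0 here, because the emulated sweep corrupts plain vascular
trees; pathological geometries are exercised in the module tests and
examples instead. All seeds derive from one experiment seed; training and
testing streams are disjoint by construction, and outputs (per-case CSV,
summary CSV, model YAML, box plot, provenance with config hash) are
bit-reproducible.

Problem sizes were chosen to keep a full sweep at a few minutes on one CPU
core; they scale up linearly via the config.

## Known limitations

* The boundary is resolved at ray-sample resolution (one voxel); systematic
  sub-voxel biases of a few tenths of a voxel remain and dominate the Dice
  deficit on thin vessels.
* The no-return state topology penalizes rays that re-enter a vessel
  (tight curves, bifurcation crotches); their samples are outvoted in
  fusion rather than recovered.
* γ's global definition couples feature scales across the whole image;
  populations heterogeneous in hyperdense content (plaque vs. no plaque)
  degrade unless the quantizer is re-fitted per population.
* Only the response functions of the five filters are implemented; the
  anisotropic-diffusion iteration of the original Manniesing scheme is out
  of scope, as are Viterbi decoding and a single joint HMM over concatenated
  features (which is known not to converge at this parameter count).
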