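# Methods

## Model

`MultiModalViT` is a two-stream pre-norm vision transformer.

**3D stream.** A gray-matter volume is brought to the configured input
shape (default 128³; inputs no larger than the target are zero-padded at
the trailing edge, anything else is resampled with cubic splines — both
routes are explicit in `ModelConfig.resize_mode`), tiled into
non-overlapping 16³ patches (512 tokens of 4096 voxels), linearly embedded
to width d with a learned per-token position table, and passed through M
encoder blocks. Each block is `x + MHSA(norm(x))` followed by
`x + MLP(norm(x))`; with all sublayer weights zero the block is exactly the
identity, which the tests exploit.

**2D stream.** The C × C connectivity matrix (C = 53) is zero-padded to
54 × 54, tiled into 27 × 27 patches (4 tokens), embedded, and passed
through N blocks of the same form.

**Fusion.** Three modes share one contract (n + m output tokens):
cross-attention (default) lets the n structural tokens query the m
functional tokens through one or more residual multi-head cross-attention
layers, then concatenates the updated structural tokens with the functional
tokens; `concat` concatenates verbatim; `weighted_mlp` applies
softmax-normalized learned scalar gates to each stream before
concatenation. There is no class token — the printed token counts are
exactly n, m and n + m — so classification mean-pools the fused tokens into
an MLP head with two outputs.

Attention scores are always computable as detached copies through a capture
argument; capture never changes outputs. Softmax subtracts the row maximum
before exponentiation and is finite for logits up to ±1e4.

**Defaults where the architecture is otherwise unconstrained:** d = 256,
M = N = 4, 8 heads per encoder, one cross-attention layer with 8 heads, MLP
ratio 2, head hidden width 64. All are configuration fields; the validation
suite and the recovery experiment run a d = 64, M = N = 2 instance.

**Implementation.** The network, backpropagation, and AdamW live on a small
numpy reverse-mode autodiff core (`vitfusion.autodiff`): broadcasting
arithmetic, batched matmul, reductions, reshapes, concatenation, softmax /
log-softmax, tanh and erf-form GELU, with gradients checked against central
finite differences in the test suite (relative error < 1e-4).

## Synthetic cohorts

The generator emulates a two-group case-control study with paired
modalities and exactly known effects.

**Volumes.** A shared template — a superposition of 12 random smooth
Gaussian bumps scaled to [0, 1], standing in for a gray-matter density map —
plus i.i.d. voxel noise (sd 0.1 by default, in template intensity units).
Patients use the same template with intensity multiplied by
(1 − effect) inside a chosen voxel set; the default set is a center-aligned
cube of side shape/4, which lands on one token of the 8³ patch lattice used
in testing so that attention recovery is interpretable at patch resolution.

**Connectivity.** Component time courses follow a domain-factor model:
component i in functional domain d is
`x_i(t) = √w · g_d(t) + √(1−w) · e_i(t)` with unit-variance domain factors
g_d, i.i.d. noise e_i, and within-domain coupling w = 0.5 (any two
components of one domain correlate at w in both groups — the strong
within-domain block structure real FNC matrices show). In patients the
factors of each planted domain pair are correlated at c = effect / w, which
makes the patient-minus-control correlation difference inside the planted
cross block equal the requested effect exactly in population while the
covariance is positive semi-definite by construction. Effects beyond the
attainable maximum w are clipped with a warning; combinations of several
planted blocks that make the factor correlation indefinite are projected to
the nearest PSD matrix, also with a warning. The empirical FNC is the
Pearson cross-correlation of the simulated time courses (200 timepoints by
default; the calibration test uses 2000 and tolerates 0.05).

The 53-component domain partition uses the standard sizes SC 5, AUD 2,
SM 9, VS 9, CC 17, DM 7, CB 4; other component counts get a proportional
split.

**What the generator does not emulate:** scanner/site effects, motion,
spatially correlated noise, hemodynamics, ICA estimation error (time
courses are generated directly at component level), age/sex structure, or
any realistic anatomy. Passing recovery tests therefore show that the
pipeline finds effects it was built to find under clean conditions; they do
not certify performance on clinical data.

## Training protocol

Label-stratified rotating folds: each class's shuffled indices are cut into
k = 10 chunks; fold f tests on chunk f, validates on chunk f+1, trains on
the rest — an 8:1:1 split at k = 10, class proportions within one subject
of the cohort's. AdamW (lr 3e-4, decoupled weight decay 1e-3, β = 0.9/0.999,
eps 1e-8) minimizes two-class cross-entropy for 200 epochs with a linear
warmup multiplier (epoch+1)/30 over the first 30 epochs — so epoch 0
already trains with a small nonzero rate — then step decay by γ = 0.5 every
50 epochs (both configurable). Augmentation touches volumes only — random
shift-crop (±2 voxels), small random rotation (±5°) and isotropic rescale
(±5 % log-scale), axis flip (p = 0.5), additive Gaussian intensity noise
(sd 0.02) — never the FNC matrices or labels. Model selection restores the
best-validation balanced-accuracy checkpoint. A non-finite loss aborts with
a diagnostic rather than training on.

Metrics are computed in-package: accuracy; balanced accuracy as the mean of
sensitivity and specificity; AUC as the Mann-Whitney rank statistic with
midranks for ties; precision and F1 from thresholding the positive-class
probability at 0.5. A single-class truth vector reports AUC as missing with
a warning. The suite cross-checks all five against scikit-learn on 100
random score/label vectors at 1e-10.

## Interpretability

Per-layer, per-head attention matrices are averaged over layers and heads,
then reduced over the query dimension by the mean (max is available) to one
weight per token; a multiplicative rollout variant composes head-averaged
layers as ∏ (W + I)/2 instead of averaging, for users who prefer the
composed formulation. Back-projection spreads token weight i uniformly over
its patch extent at weight/patch-volume per voxel: total mass is conserved
to 1e-9 and the map is linear in the weights. Cross-attention scores
(n × m) are reduced over the m keys by the mean before the same placement.
The combined map is α·A3D + β·ACA_3D with α = β = 0.5 by default.

Group statistics: per-subject maps are normalized to unit sum by default
(attention scales are arbitrary across subjects; raw testing is available
with `normalize=None`), then tested voxelwise — one-sample t against a
hypothesized mean (default: the grand mean) or a Welch two-sample t of
patients minus controls. The significance threshold defaults to p < 0.02,
uncorrected; Benjamini-Hochberg adjustment is available behind `fdr=True`
but off by default. Zero-variance voxels get NaN t/p and are excluded from
the mask rather than raising.

Connectivity-space attention back-projects the 2D stream's token weights
onto the padded 54 × 54 grid, crops to 53 × 53, symmetrizes by averaging
with the transpose, and by default multiplies elementwise by the subject's
FNC matrix. The weighting matters: with only 4 tokens the raw
back-projection is piecewise constant over quadrants, so every domain block
within a quadrant would tie; the attention-weighted form inherits the FNC's
block structure and makes per-block group differences well defined. The
group difference map is mean(patients) − mean(controls), summarized by
domain-pair block means (same-domain blocks exclude the unit diagonal).

## Study-scale experiments

`vitfusion.experiments` freezes the two canned studies the validation suite
and the reproduction script share.

**Recovery** (`run_recovery`): 120 subjects (60 per group) at 32³ voxels
with 8³ patches, a strong planted structural effect — 50 % intensity
reduction in one patch-aligned 8³ cube against voxel noise sd 0.05 — and a
+0.4 SC–SM connectivity shift; model d = 64, M = N = 2, 4 heads; 50 epochs
on the first stratified fold. Outputs: held-out AUC/balanced accuracy; the
Dice overlap between the planted mask and the top-k voxels (k = mask size)
of the two-sample attention t-map, with a permutation p-value from 100
label shuffles; and whether the planted block has the largest-magnitude
block mean of the attention-FNC difference. The effect strength is chosen
so that structural attention localization is achievable: classification
saturates at much weaker effects (the connectivity effect alone separates
the groups), but the attention map only concentrates on the lesioned patch
once the structural signal clearly dominates voxel noise.

Attention localization remains training-seed dependent even at this
strength. The group difference at the planted token is present at
initialization (patients' reduced patch content shifts its keys), and
training amplifies it on most seeds but erases it on some — the classifier
can solve the task through the connectivity stream or through the residual
pooling path without routing attention to the lesion, and which route
gradient descent takes varies with initialization. Classification and
connectivity-block recovery are stable across seeds; voxel-level attention
recovery is the fragile quantity. The recovery protocol is therefore
explicitly stochastic: it is evaluated over three seeds and judged on a
two-of-three basis, and the reproduction script reports the median over
three consecutive seeds.

**Null calibration** (`run_null_calibration`): 500 replicate no-effect
cohorts of 50 + 50 subjects at 12³ (pure noise volumes), each tested
voxelwise at α = 0.05 without normalization; the mean significant fraction
is reported with its Monte-Carlo standard error across replicates. Group
size 50 keeps the Welch approximation essentially exact so the check
isolates implementation error from small-sample approximation error.

These sizes are the package's own desk-scale choices; every dimension is a
configuration field and scales up unchanged.

## Numerical choices and degenerate inputs

- Token ordering is row-major over grid axes everywhere (tokenization and
  back-projection share one `PatchGrid`); coordinates 0-based, extents
  half-open.
- Padding is trailing-edge zeros, preserving voxel coordinates of tokens.
- Correlation matrices are symmetrized, clipped to [−1, 1], and forced to a
  unit diagonal against floating-point drift; a zero-variance time course
  raises an error naming the component.
- LayerNorm eps 1e-5; Xavier-uniform projections; position tables
  initialized at 0.02 · N(0, 1); all initialization flows from explicit
  `numpy.random.Generator`s so models are bit-reproducible from a seed.
- Attention-row stochasticity is validated at 1e-6; argmax over block means
  takes the first maximum on exact ties.
- All CLI randomness derives from one root seed split into per-stage child
  seeds (simulate / split / init / augment / interpret), each below 2³¹.

## Known limitations

- Pure-numpy training is single-threaded BLAS-bound; full-size (128³,
  d = 256) training is possible but slow — the package targets method
  development and desk-scale validation, not production training runs.
- The attention-based localization is at patch resolution by construction;
  sub-patch effects blur across their patch.
- With m = 4 functional tokens the cross-attention score matrix is highly
  aggregated; finer FNC patching (smaller 2D patches) is configurable but
  departs from the published 27 × 27 geometry.
- Synthetic validation only: no claim transfers to clinical cohorts without
  retraining and re-evaluation on real data.
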