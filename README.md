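# vitfusion

Multimodal vision-transformer fusion of structural brain volumes and
functional network connectivity (FNC) matrices, with attention-map
interpretability.

Case-control neuroimaging studies (for example schizophrenia vs. healthy
controls) usually collect two complementary measurements per subject: a 3D
voxelwise gray-matter volume from structural MRI, and a C × C matrix of
temporal correlations between ICA-derived brain networks from functional
MRI. `vitfusion` implements a two-stream vision transformer that classifies
subjects from both modalities at once and — the part that matters to a
neuroscientist — turns the model's attention back into voxel-space and
connectivity-space saliency maps that can be tested group-wise with
standard t statistics. Because clinical cohorts are rarely shareable, the
package ships a synthetic-cohort generator with planted, exactly calibrated
group effects, so the entire pipeline is testable end to end on any machine.

## The model

Each stream is a standard ViT encoder. A volume (default 128³) is cut into
non-overlapping 16³ patches giving n = 512 tokens; the 53 × 53 FNC matrix is
zero-padded to 54 × 54 and cut into 27 × 27 patches giving m = 4 tokens.
Tokens are linearly embedded with learned position embeddings and passed
through pre-norm encoder blocks built on multi-head self-attention,

    Q = X W_Q,  K = X W_K,  V = X W_V
    SA(Q, K, V) = softmax(Q Kᵀ / √d_k) V,

with heads computed on per-head projection slices, concatenated, and mixed
by W_O. Fusion is multi-head **cross-attention**: queries come from the n
structural tokens, keys and values from the m functional tokens, so each
brain-volume token interrogates the connectivity representation and the
n × m score matrix records which connectivity patches informed which brain
region. The n updated structural tokens are concatenated with the m
functional tokens (n + m = 516 fused tokens), mean-pooled, and classified
by an MLP head. Plain concatenation and a learned weighted-gate fusion are
available as baselines.

Interpretability aggregates the captured row-stochastic attention matrices
W_{l,h} by averaging over layers l and heads h (multiplicative rollout with
residual identity is available as an option), reduces the matrix to one
weight per token, and spreads each token's weight uniformly over its patch
extent — a mass-conserving back-projection producing a voxel map A3D from
the structural stream and ACA_3D from the cross-attention scores, combined
as

    Acomb = α · A3D + β · ACA_3D        (α = β = 0.5 by default).

Per-subject maps are compared with voxelwise one-sample or Welch two-sample
t-tests; the 2D stream's attention is back-projected onto the connectivity
grid, symmetrized, weighted by each subject's FNC, and summarized per
functional-domain block (SC, AUD, SM, VS, CC, DM, CB).

The transformer, backpropagation, and AdamW optimizer are implemented on a
small numpy reverse-mode autodiff core (`vitfusion.autodiff`), so the
package has no deep-learning framework dependency and runs anywhere numpy
does.

## Worked example

Train the small fusion model on a synthetic cohort with a planted
structural lesion (50 % gray-matter reduction in one 8³ patch) and a +0.4
correlation shift on the subcortical–sensorimotor (SC–SM) connectivity
block, then ask whether the model finds both:

```python
from vitfusion.experiments import run_recovery

result = run_recovery(seed=1)
for key in ("auc", "balanced_accuracy", "dice", "dice_null_p", "best_block"):
    print(key, "=", result[key])
```

which prints (about 70 s on one CPU):

```
auc = 1.0
balanced_accuracy = 1.0
dice = 1.0
dice_null_p = 0.019801980198019802
best_block = ('SC', 'SM')
```

Read: the held-out test subjects are classified perfectly (AUC and balanced
accuracy 1.0); the top-512 voxels of the two-sample attention t-map overlap
the planted lesion with Dice 1.0, significant against a 100-permutation
label-shuffled null (p ≈ 0.02, the smallest value 100 permutations can
resolve); and among all domain-pair blocks of the attention-weighted FNC
group difference, the planted SC–SM block carries the largest magnitude.

The same pipeline is scriptable from the shell:

```sh
vitfusion simulate  --config my_run.yaml --seed 1
vitfusion train     --config my_run.yaml --seed 1
vitfusion evaluate  --config my_run.yaml --seed 1
vitfusion interpret --config my_run.yaml --seed 1
# or all four stages at once:
vitfusion end-to-end --config my_run.yaml --seed 1
```

`simulate` writes one NIfTI volume and one FNC CSV per subject plus a TSV
manifest and the ground-truth masks; `train` writes a checkpoint and a
per-epoch TSV log; `evaluate` writes the metric table (accuracy, balanced
accuracy, AUC, F1, precision); `interpret` writes saliency and t/p maps as
NIfTI and the attention-FNC matrices (per group and patient-minus-control)
as CSV with domain labels.

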