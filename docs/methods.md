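# Methods

`mambaseg` implements a Mamba–CNN hybrid U-shaped network for binary lesion
segmentation of breast-ultrasound images, together with the compound loss,
the evaluation metric suite, a seeded synthetic-phantom generator, and a
small training/evaluation CLI.  This note records the model, the numerical
and design choices, and what the desk-scale experiments do and do not show.

## Model

**State-space core.**  Each channel of a token sequence is filtered by a
linear state-space model h'(t) = A·h(t) + B·x(t), y(t) = C·h(t) + D·x(t)
with diagonal-real A (S4D convention, initialised to −1…−N, stored as a log
magnitude so A stays negative).  Zero-order-hold discretization gives
Ā = exp(ΔA); the input weight is taken at first order, B̄ = ΔB.  Δ, B and C
are produced per token by learned linear projections (the Mamba selection
mechanism): Δ through a low-rank projection (rank ⌈d/16⌉ on the block dim d)
followed by a softplus, with the bias initialised so that softplus(bias)
spans [10⁻³, 10⁻¹] log-uniformly.  The recurrence
h_k = Ā_k h_{k−1} + B̄_k x_k (first-order; an index typo in the source
formula, "h_{k−2}", is read as h_{k−1}) is evaluated as an explicit
sequential scan — correctness over speed — in JIT-compiled kernels with a
NumPy fallback.  With A ≤ 0 and Δ > 0 every Ā lies in (0, 1], so bounded
inputs give bounded states (geometric-series bound).

**SS2D.**  A 2-D feature map is flattened along four traversal orders
(row-major forward/backward, column-major forward/backward); each direction
owns independent projections and state weights; the four scan outputs are
mapped back to their spatial positions and merged by elementwise sum (the
VMamba convention; the merge rule is not otherwise specified).

**VSS encoder.**  Input images are grayscaled (ITU-R BT.601 luminance),
split into non-overlapping 4×4 patches (16-vectors), linearly embedded to C
channels and layer-normalised.  Four stages of VSS blocks, with patch
merging (2×2 concat → LayerNorm → linear 4C→2C, the Swin ordering) between
stages, produce the H/4…H/32, C…8C pyramid.  A VSS block is
LN → linear expand (ratio 2, the VMamba-Tiny setting) into two branches:
(depthwise 3×3 conv → SiLU → SS2D → LN) gated elementwise by
(linear → SiLU), then a linear projection back and a residual add.  No
positional embedding and no MLP stage.  Zeroing all block weights makes
every block the identity.

**HAEM bottleneck.**  Channel branch: global average- and max-pooled
vectors through a shared MLP (C → C/r → C, ReLU between, r = 16 by
default), summed, batch-normalised → M_C (C×1×1).  Spatial branch: 1×1
conv to C/r, two 3×3 dilated convs (dilation 4, the BAM setting; no
activations between, a literal reading of the published formula), 1×1 conv
to one channel, BN → M_S (1×H×W).  S = M_C + M_S (broadcast outer sum),
M_H = σ(DWConv₃ₓ₃(S) + S) ∈ (0,1), output F + M_H⊗F — every entry of a
non-negative input is scaled by a factor in (1, 2).

**CFM skips.**  At each of the three skip levels: concat the encoder and
decoder maps (2C), 3×3 conv to C, BN, ReLU → X_E1; multi-head cross
attention with queries from the decoder map and keys/values from X_E1 over
the row-major token flattening (h = 8 heads by default, d_k = C/h, no
projection biases — the formulas show weight matrices only, and no
LayerNorm — the formulas show none); then R = AM + X_D and
X_F = R + FFN(R) with FFN hidden width 4C.  A zero-weight CFM passes X_D
through unchanged, so the skip degrades gracefully.

**Decoder and head.**  Three kernel-2/stride-2 transposed convolutions
(exact 2× upsampling, no output-padding ambiguity) halve channels and
double resolution, each followed by the matching CFM.  The head is a 1×1
projection to K = 2 class logits at stride 4 followed by 4× bilinear
upsampling; class probabilities come from a channel softmax.  A learned
patch-expanding head (stride-4 transposed convolution, and a deeper
two-stage variant with SiLU) was evaluated as the alternative reading of
"linear projection layer" and trained strictly worse at desk scale
(held-out Dice 0.44 vs 0.75 under identical budgets; the SiLU variant
collapsed to all-background), so the bilinear head is kept.

## Loss and metrics

Training minimises L = 0.4·L_wce + 0.6·L_wdice with class weights
w = (0.5, 0.5) normalised to sum 1 (so a perfect prediction gives exactly
zero loss) and ε = 10⁻⁷ guarding the log and the Dice denominators.

Evaluation reports Dice = 2TP/(2TP+FP+FN), Precision, Recall and HD95.
Conventions for degenerate masks: both-empty → 1 for the ratio metrics;
empty-vs-nonempty → 0; HD95 is undefined (NaN per image, NaN-aware
aggregation) when either boundary is empty.  HD95 boundaries are the
8-connected boundary pixels (mask minus its 3×3-cross erosion, image
border included); each directed nearest-neighbour distance set is reduced
at the 95th percentile with linear interpolation and the symmetric value is
the max of the two directions.  Distances are in pixel units; an isotropic
`spacing` converts to mm when known (default 1.0).

## Synthetic phantoms

The generator emulates the qualitative structure of B-mode breast
ultrasound so that every component is testable without clinical data: a
smooth tissue field (≈0.55 ± 0.08), one or two hypoechoic elliptical
lesions (radius 8–22% of the image side, aspect 0.6–1.0, intensity drop
35–65%, boundary blurred with σ = 1.5 px), an optional vertical
acoustic-shadow band below a lesion (probability 0.3, strength 0.4), and
multiplicative gamma speckle (shape 4, mean 1).  The mask records the
pre-blur lesion support.  Every sample is a pure function of its seed.

The speckle model is deliberately harsh: gamma shape 4 gives σ/μ ≈ 0.5
per pixel, the amplitude statistic of fully developed speckle *before*
the log compression a clinical display applies, and the noise is spatially
uncorrelated (real speckle has a resolution-cell grain).  Combined with
lesion contrasts sampled down to a 35% drop, the faintest lesions sit near
the detectability limit — a radius-6 lesion at minimum contrast has an
integrated SNR of only a few σ — which bounds the held-out Dice any
segmenter can reach on these phantoms.

What this does **not** model: physical wave propagation, depth-dependent
attenuation and focusing, real lesion morphology (spiculation, posterior
enhancement), annotation ambiguity.  Passing the desk-scale checks
therefore demonstrates that the architecture, loss, optimizer and metric
plumbing work end-to-end and can learn hypoechoic-blob segmentation under
speckle — not clinical-grade performance.

## Training recipe

SGD with momentum 0.9, initial learning rate 0.01, batch 8, per-step
polynomial decay lr₀·(1−step/total)^0.9 (the convex shape of the published
decay curve; the schedule itself is not named in the source), compound
loss above, everything derived from one seed (weight init, data order,
augmentation draws).  "300 iterations" is read as 300 epochs (the published
step counts are consistent with epochs over ~2,400 images at batch 8).
Flip and crop augmentation live in the data module; `TrainConfig.augment`
selects the policy (`none`, `flip`, `flip+crop`).  The default is `flip`:
at the 30-epoch desk-scale budget the crop's re-resize blurs lesion
boundaries and measurably slows convergence, while training without any
augmentation overfits (train Dice ≈0.94 vs held-out ≈0.72 in our runs;
flips give the best held-out Dice of the three policies).

## Desk-scale profile and problem sizes

The publication-scale profile (C = 96, depths [2,2,9,2], 224×224) is used
for complexity accounting only.  Tests and smoke training use the tiny
profile: C = 32, depths [1,1,2,1], state dim 16, expansion 1 (the
criterion-scale profile fixes C/depths/r/h; expansion 1 keeps the scan cost
proportionate at 64×64), r = 2, 2 heads, 200 phantoms at 64×64, 30 epochs
— chosen so a full training run finishes in minutes on one CPU core.

## Complexity accounting and the published figures

Parameters are the exact sum over learnable arrays.  FLOPs are analytic:
2 FLOPs per multiply-accumulate for conv/linear/attention matmuls, 6 per
token·channel·state for the scan recurrence plus output contraction;
normalisations and activations are not counted.

The full configuration counts **29.67 M parameters / 18.50 GFLOPs**.  The
published row reports 21.76 M / 39.19 G.  Two observations, documented
rather than reconciled: (i) this package's *encoder alone* counts 22.15 M
parameters and ≈4.8 GMACs at 224², matching the published VMamba-Tiny
backbone (~22 M, ~4.9 G) — and the published 21.76 M agrees with that
backbone figure to 1.8%, suggesting the printed row covers the encoder
only; (ii) no standard counting convention (MACs, 2×MACs, with or without
attention/scan terms) reproduces 39.19 G for this architecture, whose
decoder+CFM side adds ≈3.5 GMACs to the encoder's ≈4.8.  The per-layer
breakdown is available from `mambaseg complexity --breakdown`.

## Numerical choices

float32 throughout the network; float64 in the functional SSM reference
API and the metric suite.  BN layers follow standard running-statistics
semantics (momentum 0.1); unit tests pin BN to the identity (γ=1, β=0,
running mean 0, var 1) so oracles are deterministic.  Biases that feed a
BN directly (the MLP's second bias, the spatial branch's collapse bias)
are retained for fidelity to the published formulas although BN's mean
subtraction makes them redundant.  Softmax subtracts the (detached) row
max.  The scan is evaluated sequentially; a parallel prefix formulation
was rejected because exp-space cumulative products underflow for long
sequences.  Checkpoints are flat name→array `.npz` archives with a version
tag.

## Known limitations

No pretrained-encoder import is shipped (the published model initialises
from VMamba-Tiny weights; shapes are compatible by construction but no
checkpoint is bundled).  Attention is exact (L² memory) — fine at desk
scale, 3136 tokens at 224².  HD95 in mm requires a user-supplied pixel
spacing.  The training loop is single-device and synchronous.
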