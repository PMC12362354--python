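# Methods

## Data model and preprocessing

The unit of analysis is the patch–spot pair. Spot coordinates (x, y) are
0-based pixels with x = column and y = row; the patch for a spot is the
axis-aligned square covering the half-open window [c − s/2, c + s/2) on
each axis (s = `patch_size`, default 256 for real slides, 64 in the
desk-scale studies). Half-open windows make the crop exactly s×s, which the
vertex-style description of a patch leaves ambiguous by one pixel. Spots
closer than s/2 to an image edge get zero-padded patches; each occurrence
is logged. Zero-padding was chosen over reflection or clamping because it
is unambiguous and makes out-of-tissue pixels inert in the convolution.

Expression is library-size normalized per spot to `target_sum` (default
10⁴, the conventional default of the scanpy toolchain) and log1p-
transformed, via scanpy. All-zero spots are left at zero with a warning
rather than erroring: they occur in real Visium data and carry no usable
signal either way.

Gene panels: **HEG** ranks genes by mean normalized expression pooled over
every spot of every slice; **HVG** takes each slice's top-n genes by
population variance, pools the candidate lists, and re-ranks the union by
the variance over all spots pooled, keeping the top n (default 3500). The
pooling statistic for HEG is genuinely open (per-spot ranking "across all
spots" could also mean frequency-in-top-lists); pooled mean was chosen as
the simplest statistic that respects total abundance, and the choice is
configurable. Ranking ties break lexicographically by gene name so panels
are deterministic.

Batch correction between slices is an external-tool hook (a shell command
template over CSV in/out), applied after gene selection and before
training by default. Harmonization is a solved problem with published
tools and is orthogonal to the contrastive method, so it is never
re-implemented here; with no command configured the hook is the identity.

## Encoders

Both modalities map into a shared d_o-dimensional space (default d_o = 256,
a standard contrastive-embedding width that keeps desk-scale runs fast; the
value is not dictated by the method). The image path is a convolutional
backbone whose globally average-pooled features feed a projection head
(Linear→GELU, Linear→Dropout(0.1), residual add, LayerNorm with ε = 1e-5;
GELU is the exact erf form). The spot path is a single linear map d → d_o
plus an identical head.

The working backbone, `tiny_cnn`, is three stride-2 3×3 conv blocks
(16/32/64 channels, ReLU) with global average pooling — deliberately small
so the full pipeline trains end-to-end on one CPU core in minutes. The
full-scale architecture this mirrors is a pretrained ResNet-50 (2048-dim
pooled features) with the same head; that backbone requires a GPU
deep-learning runtime with pretrained weights and is reserved in the config
but not provided by this package. Pixels are scaled to [0, 1] for
`tiny_cnn`; backbone-conventional channel standardization would apply to a
pretrained backbone. Backbones are fine-tuned end-to-end by default, with a
`freeze_backbone` flag.

All layers are implemented in a small numpy core with explicit forward and
backward passes (convolutions via im2col so the work is BLAS matmul) and an
Adam optimizer with decoupled L2 decay on weight matrices. Evaluation-mode
encoders are pure functions; dropout is the only stochastic layer and is
inactive outside training.

## The contrastive objective

For batch embeddings h_p, h_s (rows aligned, same shape):

    logits  = (h_s h_pᵀ)/τ
    targets = row-softmax((h_p h_pᵀ)/τ)
    loss    = mean over rows k of  Σ_j −targetsᵀ[k,j]·log-softmax(logitsᵀ[k])[j]

The transposes are honored literally: the cross-entropy is taken row-wise
on the transposed matrices (rows indexed by image) and averaged over that
axis. τ defaults to 1.0 — it is applied to both logits and targets, so 1.0
is the neutral choice — and is logged with every epoch. The target matrix
is treated as a constant under differentiation by default: it defines the
reference distribution, and letting it move creates a degenerate shortcut
(the encoder can chase its own targets). A `targets_stop_gradient=False`
flag enables the full gradient; the analytic gradients in both modes are
finite-difference checked in the test suite.

The symmetric soft-target CLIP loss is kept as the ablation baseline.
Its targets are the row-softmax of the average of the two within-modality
similarity matrices — a symmetric matrix, so the same row-stochastic
target serves both directions — and the loss is the mean of the
spot→image term CE(logits, targets) and the image→spot term
CE(logitsᵀ, targets). This formulation (rather than using targetsᵀ in the
second term) makes the two directions coincide exactly when h_p = h_s,
which is the natural symmetry requirement for a bidirectional loss and is
frozen in a unit test.

Degenerate cases: a batch of one has a single-element softmax, so both
losses are exactly 0; such batches can arise as a last incomplete batch
and are kept (and logged) rather than dropped.

## Augmentation and training loop

Augmentations are restricted to expression-preserving, interpolation-free
geometric ops: horizontal/vertical flips and rotations by multiples of 90°.
Each epoch every training pair contributes `copies_per_epoch` (default 2)
independently augmented patches with the identical expression vector,
doubling the per-epoch data; the draw for (pair, copy) is a pure function
of (seed, epoch, pair index, copy index), so epochs are reproducible and
distinct. Paired image+expression augmentation is deliberately not the
default. Setting `copies_per_epoch=1` is the no-augmentation ablation.

Training splits the reference cohort 80/20 (round-to-nearest on the train
side, remainder to eval; the eval split never touches the held-out query
slice), optimizes both encoders with Adam (lr 1e-3 for tiny_cnn, weight
decay 1e-3, batch 128 — unprescribed by the method, declared here as
implementation defaults and recorded in every checkpoint), evaluates the
mean loss on the eval split after each epoch in evaluation mode, and keeps
the parameters of the lowest-eval-loss epoch. A non-finite loss aborts
with a diagnostic dump. Checkpoints are npz archives with a versioned JSON
manifest (config, gene panel, loss curves) and restore bit-exactly.

## Retrieval imputation

The reference index holds the frozen image encoder's embeddings of the raw
(unaugmented) reference patches plus their expression. Query scoring is
raw dot product by default (the literal reading of the ranking step); an
`l2_normalize_scores` flag switches to cosine, under which self-retrieval
is exactly guaranteed (with raw dot products a larger-norm neighbour can
outscore the query itself). Ties break by lower reference index via a
stable sort. The prediction is the unweighted mean of the K selected
expression rows (K default 50, logged; the method leaves K open). As
K → n_ref every prediction converges to the global reference mean — K
controls a bias/variance trade-off, not a free accuracy knob.

The reference set is the training cohort only. Indexing the query cohort
too would leak the very labels being imputed into the index; an
`include_query` option reproduces that alternative composition for
comparison and is off by default.

## Evaluation metrics

Per gene i across M spots: RMSE_i = sqrt(mean_j (pred − truth)²); Pearson
correlation (zero-variance columns return a 0 sentinel with a warning);
and SSIM computed after each gene column is divided by its own maximum:

    SSIM_i = (2·μ̃·μ + C1)(2·cov + C2) / ((μ̃² + μ² + C1)(σ̃² + σ² + C2))

with population (1/M) moments and C1 = C2 = 0.01 ("small constants";
recorded in every report). Scaling each side by its own maximum makes the
statistic scale-invariant per side; a flag scales the prediction by the
truth's maxima instead, since the scaling convention is genuinely open.
Per spot, Hit@T checks whether the argmax predicted gene is among the T
highest truly expressed genes (truth ranking ties to lower gene index);
Hit@T is non-decreasing in T and Hit@d ≡ 1. The RMSE formula indexes over
spots for a fixed gene — the prose description "within each spot"
notwithstanding — so the reported medians/means are over genes.

## Synthetic cohorts

The generator emulates exactly the structure the method exploits: a latent
cluster per spot drives a deterministic visual program (base color from a
golden-ratio hue palette, stripe frequency/orientation, dark nucleus-like
blob density — all functions of the cluster id alone, so a frozen encoder
can in principle separate clusters perfectly) and a cluster-specific mean
expression program on the normalized-log scale, with a contiguous marker
block per cluster and one dominant marker gene so cluster identity is
recoverable from the expression argmax. Gaussian noise is added to pixels
(sd 0.05 on the [0,1] scale) and expression (sd 0.3 log-units,
"moderate" relative to the ≳2.5 log-unit marker elevation); optional
per-slice per-gene mean shifts emulate batch effects (off by default).
Spots are dealt round-robin to slices so each slice sees every cluster.
Independent seed streams feed cluster assignment, expression noise, pixel
noise and batch shifts, so changing one never perturbs another. An
alternative `counts` mode draws Poisson counts around the de-logged means
and routes them through the standard normalize+log1p preprocessing.

What the generator does **not** emulate: H&E stain physics, nucleus-level
morphology, spatial autocorrelation between neighbouring spots, partial-
volume effects at cluster boundaries, and realistic gene–gene correlation
beyond the block structure. Passing the end-to-end study therefore shows
the machinery is correct and that morphology-determined expression is
recovered when it exists; it does not certify accuracy on real tissue.

## The standard study and problem sizes

The package's headline validation (`heclip.experiments`, also run by
`scripts/acceptance.py`) uses 2400 spots over 6 slices — one slice of 400
held out as the query, 2000 reference — with 200 genes, 4 clusters, 64×64
patches, tiny_cnn trained 5 epochs (batch 128). These sizes were chosen so
a scientist can re-run the whole study interactively on a laptop core; at
this scale the trained retrieval reaches Hit@1 near 1.0 and median
per-gene PCC around 0.65, while the permuted-reference null model (same
index with expression rows shuffled against embeddings) sits near chance
(Hit@1 ≈ 1/n_clusters, PCC ≈ 0).

## Numerical choices and limitations

- float32 network arithmetic; losses and metrics accumulate in float64.
  Reproducibility is bit-exact for data generation and exact to platform
  floating-point determinism for training (single-threaded BLAS order is
  fixed; across BLAS builds expect ~1e-6 relative drift in loss curves).
- LayerNorm ε = 1e-5; Adam (0.9, 0.999, ε = 1e-8); He-style init from a
  seeded generator, so identical seeds give identical models.
- Exact top-K by stable full sort — n_ref here is at most tens of
  thousands, so approximate nearest-neighbour indexing is out of scope.
- Whole-slide pyramidal formats (SVS/NDPI), stain normalization and
  nucleus segmentation are out of scope; images enter as PNG/TIFF arrays
  or pre-cut patch PNGs.
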