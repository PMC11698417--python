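# Methods

`octlayers` implements joint layered-tissue segmentation and boundary
regression for OCT-style B-scans, with attention-scored structured
pruning. This note records the model, the choices behind it, and what the
synthetic experiments do and do not show.

## The model

A single residual channel-attention encoder (4 levels + bottleneck,
default widths [32, 64, 128, 128, 128], 2×2 max-pooling between levels)
feeds two decoders: a **segmentation branch** ending in a 1×1 convolution
and channel softmax over the K classes, and a **boundary-regression
branch** ending in a 1×1 convolution and tanh, predicting one normalized
truncated signed distance map per class. Decoder levels upsample
bilinearly (factor 2, half-pixel centers).

At every decoder level a spatial-attention fusion block couples three
inputs: the encoder skip F_i, the segmentation features S_i, and the
boundary features B_i. Each branch applies two attention gates — for the
segmentation branch, `gate(S_i, F_i)` and `gate(S_i, B_i)`, where
`gate(q, g) = sigmoid(w3 relu(w1 q + w2 g)) · g` with 1×1 convolutions
w1, w2 (to half the level width) and w3 (to one channel) — concatenates
[S_i, gated F_i, gated B_i], and reduces back to the level width with a
3×3 convolution. Four gates per level in total. The gates' 1×1
convolutions accept differing input widths, so no separate alignment
projections are needed (this matters after pruning, when widths diverge).

Residual attention blocks are `conv3×3–CA–BN–relu → conv3×3–CA–BN`, plus
a 1×1-projection (+BN) residual, then relu. CA is channel attention
(squeeze-excitation style): pooled statistic z_c = max + mean over
pixels, gate α = sigmoid(W2 relu(W1 z)) with reduction ratio r = 4.
Three deliberate choices here:

* **Channel attention after every convolution** (both 3×3 convs of each
  block and each fusion conv), so that every convolution has its own
  data-driven importance signal for pruning.
* **Channel attention acts on the raw convolution outputs, before BN.**
  The α gates double as kernel-importance scores for pruning, and the
  per-channel activation scale is the signal they rank. After BN every
  channel is standardized, and we found α ranks computed there to be
  useless — worse than random — for pruning: removing the "least
  important" 20% collapsed held-out Dice from ≈0.95 to ≈0.3 and
  fine-tuning plateaued far below the unpruned model, while removing
  random kernels recovered fully. With CA before BN the ranking works
  and a pruned model recovers within a couple of fine-tune epochs. The
  attention MLP weights are damped (×0.2) at initialization so α starts
  near 0.5; raw conv activations would otherwise saturate the sigmoid
  and stall early training.
* **Projection residuals everywhere**, not only on width changes.
  Identity residuals would tie the surviving-channel sets of producer and
  consumer layers into one pruning group; a projection keeps every
  convolution an independently prunable "depth group" and makes pruning
  surgery exact (see below).

Convolutions followed by BN carry no bias (BN absorbs it; a bias there
would also receive an identically zero gradient, which would make
gradient-flow checks meaningless).

The network, training loop and pruning surgery run on a compact
reverse-mode autograd engine over numpy arrays (`octlayers.nn`):
elementwise ops with broadcasting, matmul, reductions, stride-1
convolution implemented as a sum of per-offset GEMMs, 2×2 max-pooling,
factor-2 bilinear upsampling, and a fused BatchNorm with closed-form
backward. Operator gradients are verified against central finite
differences in the test suite.

## TSDF supervision

For each class k, the target of the boundary branch is the truncated
signed Euclidean distance to the boundary of the class region: negative
inside, positive outside, magnitude clipped at τ (default 5 px) and then
normalized by the per-image maximum absolute value, giving values in
[-1, 1]. Boundary membership: a class-k pixel with at least one
4-neighbour of another class; image borders alone do not create boundary
pixels, so the zero level set is a one-pixel curve. An absent class gets
the constant +τ map (-τ if the class fills the image) so the regression
target is always defined. Distances use an exact Euclidean distance
transform (scipy) to the boundary-pixel set; a brute-force double loop
over boundary pixels serves as the oracle in tests.

## Adaptive entropy weight

Where the largest and second-largest of the K per-pixel TSDF values are
close — near boundaries, and wherever a model has not learned the layer
topology — training should pay more attention. The two values are
softmaxed into (p1, p2) and the weight is their binary entropy in bits:
w = −(p1 log p1 + p2 log p2)/log 2 ∈ (0, 1], equal to 1 exactly at a tie
and decreasing monotonically in the gap (it depends on the pair only
through d1 − d2). By default w is computed from the network's *predicted*
TSDF, detached from the gradient; a ground-truth source and an off switch
are provided. Ties in the argmax resolve to the lowest class index.

## Losses

`L = Lce + Ldice + λ · Lbou` with λ = 1 by default (configurable; no
canonical value exists for it).

* Lce: pixel-weighted cross entropy, averaged per pixel and per image;
  probabilities are clamped to [ε, 1] (ε = 1e-7) inside the log so the
  loss is exactly zero at a perfect prediction.
* Ldice: summed over classes and images, `1 − 2Σyp/(Σy + Σp + ε)` per
  class; its ceiling is N·K. The weight map does not multiply this term.
* Lbou: pixel-weighted mean squared error between predicted and target
  TSDF stacks, averaged like Lce.

The same weight map multiplies Lce and Lbou. N is the number of images
in the batch.

## Synthetic data

`octlayers.synthetic` draws flattened-retina-like scenes: K−1 smooth,
non-crossing interface curves (sums of low-frequency sinusoids plus
smoothed noise, projected to keep a ≥1 px gap, optionally with local
bumps/depressions), background above the first interface, tissue layers
spanning the full width, the last layer running to the image bottom.
Per-class mean intensities follow a canonical pattern — dark background,
tissue layers taking evenly spaced gray levels assigned from alternating
ends of the brightness range, mimicking the alternating hyper-/hypo-
reflective retinal bands — plus a small per-image jitter (σ = 0.02).
The consistency of this class→intensity mapping across images is what
makes class identity learnable from local appearance, as it is in real
OCT; an earlier design that shuffled intensities per image made the task
unlearnable at any scale. Additive Gaussian noise is the default; a
multiplicative unit-mean speckle toggle exists but real OCT speckle
statistics are out of scope. "Weak boundaries" are emulated by
compressing the class intensities toward their mean within column ranges.

What passing tests on this generator do **not** show: robustness to real
speckle, curved/unflattened anatomy, pathology (fluid pockets), vendor
intensity profiles, or annotation noise.

## Training recipe

Adam (weight decay 1e-5) with cosine-annealed learning rate, batch size
8, random crops, horizontal/vertical flips and brightness/contrast jitter
each with probability 0.5, five-fold cross-validation selecting the fold
model with the best validation mean Dice — these are the package
defaults. TSDF targets are computed once per full image and cached;
augmentation crops the cached stack, because the normalization is defined
over the full image and would otherwise drift under cropping. Validation
runs uncropped at full size.

Desk-scale experiments (tests and the acceptance script) run on
128×256-pixel scenes with K = 5 and a small-width model
([8, 16, 32, 32, 32]): 64 training images, 8 epochs with the cosine
schedule fully annealed 1e-3 → 1e-5, batch 4, jitter amplitude 0.05,
**full-height 128×128 crops**. Three of these numbers deserve comment:

* *Full-height crops.* The reference recipe's 256×256 crops of 256×512
  B-scans are full-height too. Small square crops whose content depends
  on vertical position make BatchNorm batch statistics fluctuate with
  crop location, which destroys the absolute-intensity cue the task
  rests on; we observed training stall exactly this way.
* *Jitter 0.05.* The default ±20 % photometric jitter is comparable to
  the between-class intensity gaps of the synthetic scenes, i.e. it
  relabels classes rather than perturbing them; at desk scale the
  augmentation must stay below that gap.
* *Full LR anneal.* Mean Dice converges within ~5 epochs, but
  boundary-pixel jitter — and with it the column-topology violation
  rate — keeps dropping through the low-LR tail, so the schedule is run
  to its end rather than early-stopped.

`train()` optionally stops early once a validation mean-Dice target is
reached (off by default); the experiment scripts use it to bound
runtimes.

## Pruning

Kernel importance = channel-attention α summed over all batches of a
scoring pass, run in inference mode with augmentation off and fixed data
order (pure summation, hence batch-order invariant). Each convolution is
its own depth group; the bottom `floor(r · n_current)` kernels per group
are removed (ascending score, ties drop the lower index first), never
below `min_kept` = 4. Each iteration prunes r% of the *current* kernels.

Surgery rebuilds the model at the reduced widths and copies every
surviving parameter: conv kernels and BN parameters by output-channel
rows, attention-MLP columns/rows (the MLP's hidden width stays at its
construction value so weights transfer), and every consumer's
input-channel slice, following the named channel-group graph through
residual adds, concatenations, skip connections and attention gates. The
correctness oracle: zeroing a to-be-pruned kernel's conv weights/bias and
BN affine in the original network makes its channel identically zero
downstream, so the masked original and the surgically pruned model must
produce identical outputs (to float tolerance) — asserted for arbitrary
plans in the tests.

The schedule scores → plans → prunes → fine-tunes, five iterations by
default, then keeps the checkpoint with the best validation mean Dice.
Unpruned parameters are always initialized from the unpruned network's
trained weights.

## Numerical conventions

* Coordinates are row-major, origin top-left, 0-based.
* Softmax is computed with a detached max-shift; sigmoid saturates
  cleanly at ±∞; x log x → 0 at x = 0 in the entropy weight.
* Masks are uint8 PNG (class index per pixel); images 8/16-bit grayscale
  PNG normalized to [0, 1]; TSDF stacks float32 multi-page TIFF.
* Inputs not divisible by 16 are reflect-padded and outputs cropped.
* Determinism: a single seed derives independent streams for curves,
  noise, initialization, shuffling and augmentation; two runs with the
  same seed produce identical epoch-1 losses.

## Known limitations

* CPU-only and desk-scale; the full-width model trains too slowly on one
  CPU for realistic epochs/datasets.
* Dice/IoU at the level of the reference clinical results require the
  clinical datasets and GPU training; nothing here claims them.
* The entropy weight is only defined for K ≥ 2.
* BatchNorm statistics are per-branch and can drift under very small
  batches; the experiments use batch ≥ 4.
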