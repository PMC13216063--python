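# Methods

## Model

The network couples a task-solving (TS) perceptron with a
concept-abstraction (CA) module. For TS layers l = 1…L (input layer
l = 0, two-unit Yes/No head at l = L):

* CA pre-activation: a_l = W_l^CA · c_{l−1} + b_l
* gating signal: g_l = σ(a_l), applied as z_{l−1} = x_{l−1} ⊙ g_l
* CA chain input: c_l = ReLU(BatchNorm(a_l))
* TS layer: o_l = W_l^TS · z_{l−1} + b_l, then x_l = ReLU(BatchNorm(o_l))
  for hidden layers; the head emits raw scores (No at index 0, Yes at
  index 1, ties resolved to No) consumed by a softmax cross-entropy.

Where the gating enters relative to the CA normalization is not fully
pinned down by the reference description; we place the sigmoid on the
raw pre-activation (so gates are guaranteed to lie in (0, 1)) and give
the CA chain the same normalize-then-rectify treatment as the TS chain.
This choice is isolated in `CatsNet.forward_batch` and easy to vary for
sensitivity analyses.

Reference layer sizes are TS [2048-100-100-2] and CA [d_c-2048-100-100]
with concept dimension d_c = 20 (supported range includes 10 and 100);
all sizes are constructor arguments and the synthetic studies use
TS [64-32-32-2]. Batch normalization uses batch statistics during
network training (batch size ≥ 2 enforced) and running statistics in
evaluation; weights initialize He-style from a seeded generator, so
every instance is reproducible from its seed.

Everything — forward pass, backward pass through both chains (including
the gradient with respect to the concept input, which the
concept-learning phase and concept expansion consume), Adam — is plain
numpy. Gradients are verified against central finite differences in the
test suite in both normalization modes.

## Training

The triplet builder pairs every sample with its own category's concept
(label Yes) or, for a fraction (default 0.5) of samples chosen exactly,
a uniformly drawn different category's concept (label No). Negatives
are re-drawn each epoch by default (a frozen assignment is available).

Alternating training runs, per epoch, one network phase (concepts
fixed; Adam, lr 1e−3) and one concept phase (weights fixed; Adam,
lr 1e−2, matching the stated concept-expansion learning rate — the main
optimizer and rates are otherwise not pinned down by the reference, and
Adam is the only optimizer it names). Uniform noise U(−0.1, 0.1) is
injected into every concept element in both phases and never at
evaluation. Default epoch count is 5; an optional patience-based stop
(no accuracy gain > 1e−3 for 2 epochs) is available. The concept phase
runs the network in evaluation mode so that all network state —
including normalization buffers — is bytewise untouched by that phase;
this is asserted by checksum in the tests. Joint mode updates both
parameter groups in a single loop with batch statistics.

Initial concept vectors are i.i.d. standard normal (uniform[−1, 1]
selectable); the reference procedure only says random points.

Evaluation is balanced per category: every held-out sample of the
category (expected Yes) against an equal number of other-category
samples under the same concept (expected No), noise-free.

## Synthetic study conditions

The feature generator emulates backbone embeddings as Gaussian class
clusters whose means accumulate displacements along a binary hierarchy
(siblings share all but the deepest displacement, so they sit closer
than cousins). It returns the analytic class-mean distance RDM as
ground truth. What it does not emulate: heavy-tailed activation
statistics, feature correlations, class imbalance or label noise of
real backbone embeddings — so passing tests demonstrate the mechanics
and statistics of the method, not performance on natural images.

Two worlds are used throughout:

* classification world — 8 classes, 64-d features, level scales
  (4, 2, 1), within-class sd 0.5, 100 training and 50 evaluation
  samples per class. Five alternating epochs reach ≥ 0.95 held-out
  macro accuracy; joint training lands within 0.03.
* communication world — 20 classes, 64-d features, five levels with
  scales (3.0, 1.5, 0.8, 0.4, 0.2), within-class sd 0.5, 50 train / 30
  eval per class (`desk_scale_world`). The geometrically shrinking
  scales give every class a close sibling, the superclass-like
  structure that concept transfer relies on: a never-trained category
  is recognized through its trained semantic neighbors. Concept
  dimension is 10 here (20 classes constrain a 10-d space more tightly
  than a 20-d one, which helps the translation generalize from 19
  anchor categories).

The RDM-ensemble generator draws subject and model-instance RDMs as a
shared signal RDM plus independent symmetric upper-triangle noise
(clipped to ≥ 0, zero diagonal) — exactly the generative model the
noise-ceiling estimator assumes, which is what makes the Monte-Carlo
oracle comparison meaningful.

## Concept-space statistics

Functional entropy uses natural logarithms with 0·log 0 := 0 (the log
base only rescales comparisons). All-zero Yes counts leave the
distribution undefined and raise; the distribution sampler reports how
many sampled points it dropped for that reason. The trained concept
space is sampled through a Gaussian fit (mean + covariance) to the
learned vectors; the *baseline* distribution is produced by feeding
random concept vectors through an architecture-matched network with
random parameters. An untrained network answers indiscriminately, so
its entropies concentrate near log K, whereas a trained space is
category-specific — this parameter-space baseline is the contrast the
package tests. Samplers over concept space (standard normal and
uniform) are provided for both roles.

RDMs vectorize as the row-major upper triangle excluding the diagonal,
everywhere. Hierarchical clustering is cosine distance with unweighted
average (UPGMA) linkage; items are sorted lexicographically before
linkage so distance ties resolve deterministically. The critical
Pearson threshold is r* = t*/√(t*² + df); note that 0.107 — the
conventionally quoted two-tailed 5% value in this literature — is the
df = 332 value (n = 334 items), while df = 330 gives 0.1077.

## Attention maps

The class activation map weights each convolutional feature map A^k by
α_k = g_{1,k} · (1/Z) Σ_ij ∂y_Yes/∂A^k_ij — the Grad-CAM neuron
importance additionally scaled by the first-layer gate — and applies a
ReLU to the weighted sum. The map targets the pre-softmax Yes score.
Backbones enter through an adapter contract (`feature_maps(image)`);
maps reach the network via global average pooling, so ∂y/∂A^k spreads
uniformly over each map's Z pixels. Display upscaling is bilinear. A
seeded two-layer convolutional stub ships for tests and demos; no
pretrained backbone is bundled.

## Communication protocol

Phase 1 trains a teacher on all categories and a student with one
category (D1) held out. Phase 2 expands the teacher's concept set: for
each shared category, extra concept vectors are optimized from fresh
standard-normal inits with the network frozen, minimizing
L = L_CE(x_new, Yes|C) + α·L_CE(x_old, No|C) + β·L_rep(C, C_old, τ),
L_rep = Σ_i exp(−|C_i − C|²/τ), with α = 0.5, β = 0.001, τ = 0.01,
lr = 0.01, 2 new-category shots and 1 shot per old category. Old-class
shots are paired with the candidate (new) concept under label No — the
reading of the combined loss in which the new concept must reject old
images. At reference scale each category carries 97 vectors (1 learned
+ 96 expanded); the reduced-scale protocol uses 1 + 8. Candidates are
optimized jointly in one stacked batch (their losses are independent
and additive), 150 Adam steps each.

The translation module regresses every teacher vector of a category
onto the category's single student concept: a ReLU MLP under MSE with
inverted dropout active only while fitting. Reference configuration:
10 hidden layers × 500 units, dropout 0.3, Adam at 1e−4 halved every 10
epochs, 200 epochs. The reduced-scale profile (`desk_translation_config`)
uses 3 × 64 with lr 3e−3 halved every 50 epochs: the reference schedule
presumes hundreds of minibatches per epoch and underfits badly at the
reduced scale's handful of batches.

Phase 3 maps the teacher's D1 concept through the translation and
scores the student on a balanced D1-vs-others probe using only that
vector. The held-out category never enters student training or
translation fitting (asserted; violations raise). Controls: a
scrambled translation (output dimensions permuted) should fall to
chance, and per-round teacher/student concept RDMs over shared classes
quantify cross-instance structural similarity. Per-round networks train
15 epochs in the reduced-scale protocol — the small synthetic dataset
needs more than the reference 5 epochs to reach its accuracy plateau,
and transfer depends on concepts having converged onto the data's
similarity structure. Over 20 rounds the protocol yields mean transfer
accuracy well above chance while the scrambled control stays at chance;
the exact values are computed by `scripts/acceptance.py`.

## RSA statistics

Spearman correlations operate on tie-averaged ranks of upper-triangle
vectors. The partial correlation is the first-order formula on ranked
vectors; collinear covariates raise rather than returning NaN. The
Mantel test permutes item labels jointly on rows and columns of one
RDM; because a joint permutation only permutes the upper-triangle
multiset, both matrices are rank-transformed once and each null
statistic is a plain normalized dot product, with the add-one rule
p = (1 + #{null ≥ observed})/(1 + n_perm). Default n_perm = 10,000
(tests and calibration use fewer, as every caller can).

Split-half group reliability correlates half-sample mean RDMs across
random 50/50 subject splits (odd subject assigned at random per split),
Fisher-z averages across splits (default 1,000) and applies the
Spearman–Brown correction 2r/(1+r). The subject reliability formula
rel_s ≥ r²(X_s, X̄_{−s})/rel_group is a lower bound; the estimator
plugs it in as a point value because the ceiling formula consumes a
number, clipping every reliability into [0, 1 − 1e−7] and negative
intermediate correlations at 0. Model-instance reliability is the
back-transformed Fisher-z mean of leave-one-out instance correlations.
The ceiling NC_z = (1/S) Σ_s atanh(√(rel_s · rel_model)) lives in the
same z-domain as the package's group-level effect sizes. Fisher-z is
applied to Spearman coefficients throughout, mirroring how the pipeline
aggregates them (the transform is variance-stabilizing for Pearson r;
for Spearman it is the field's convention rather than exact).

Group-level tests are standard one-sample/paired t statistics with
Cohen's d and 95% CI; zero-variance inputs return an explicit
degenerate result instead of NaN.

## Numerical choices and limitations

* Seeds thread through `numpy.random.default_rng` everywhere; identical
  seeds give bitwise-identical runs (asserted for training histories
  and checkpoint round-trips).
* The sigmoid is computed in its numerically stable split form;
  cross-entropy shifts scores before exponentiation.
* Checkpoints are `.npz` containers of named arrays with a SHA-256
  content checksum; text formats write ≥ 9 significant digits.
* k-means on model RDMs uses multiple restarts under a fixed seed; ties
  in the dendrogram are resolved by lexicographic item order.
* Known limitations: no convolutional backbone is included (features
  are inputs; the conv stub exists for gradient tests only); the
  synthetic worlds are Gaussian and isotropic within class; transfer
  statistics at the reduced scale are noisier than at reference scale —
  individual rounds range from chance to near-perfect, and only the
  20-round aggregate is a stable quantity.
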