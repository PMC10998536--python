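# Methods

## Problem and model

`fgrnet` infers *signed* gene regulatory networks from bulk expression
profiles: for an ordered gene pair (R, T) it predicts whether R activates
T, represses T, or does not regulate it (a binary regulation /
non-regulation mode is also provided).  The inference is cast as
supervised pair classification: a partial prior network of curated signed
edges supplies positive labels, sampled regulator-anchored non-edges
supply the non-regulation class, and the trained classifier is then
applied to unobserved pairs.

Three feature families describe a pair:

1. **Correlation embedding (Cnet).**  Each gene's normalized expression
   profile passes through three residual 1-D convolution blocks.  Each
   block runs two convolution units on the main branch and a projection
   convolution unit on the shortcut, where a unit is
   conv → ReLU → BatchNorm → MaxPool (the activation deliberately
   precedes batch normalization, and the shortcut is a projection, not an
   identity skip); block output is the sum of the two branches.  The
   block-3 feature sequences of R and T are concatenated, flattened, and
   mapped through dense → dropout → dense to the pair's correlation
   embedding `F_corr`.
2. **Expression features (expResNet).**  The same residual trunk followed
   by global average pooling and a dense layer yields a per-gene feature
   vector whose width is independent of the number of biological samples.
   This family exists for ablation; the default model does not use it.
3. **Bidirectional node embeddings (BLR).**  Every gene owns a
   source-role row S[g] and a target-role row T[g] in two trainable
   tables.  The tables are fit adversarially on the prior digraph
   (signs ignored): a discriminator scores a directed edge (u, v) as
   D(S[u], T[v]); two conditional generators produce fake source /
   target neighbor vectors for each node; the discriminator opposes the
   real term `-Σ D(S[u], T[v])` against four fake terms
   `(û_s, T[u]), (S[u], û_t), (v̂_s, T[v]), (S[v], v̂_t)` per edge batch,
   and the generators maximize the discriminator's score on their fakes.
   Direction is encoded because S and T rows enter the discriminator
   asymmetrically.

   The *reported* objectives are the plain score sums exposed as
   `generator_loss` / `discriminator_loss`.  As training signals those
   sums are degenerate: the fake terms outnumber the real term four to
   one, so a discriminator that calls everything fake reaches loss
   `3·m·c`, minimized by a constant output c → 0 where sigmoid
   saturation kills all gradients — we observed exactly this collapse on
   benchmark-sized graphs (a few hundred nodes), while toy graphs escape
   it only because training is short relative to capacity.  Training
   therefore defaults to the standard logarithmic GAN objective
   (`-Σ log D(real) + Σ -log(1 - D(fake))`, non-saturating generator),
   whose optimum is the same intended separation but which penalizes the
   constant collapse unboundedly.  `loss_form="literal"` restores the
   sum-form training signal for comparison.

The final pair feature is `allFe = [F_corr | S[R] | T[R] | S[T] | T[T]]`,
classified by conv → ReLU → BatchNorm → MaxPool → dense → dense → softmax.

## Training procedure

Embedding tables are pre-trained and frozen; the residual trunk, Cnet and
head then train jointly with Adam under class-weighted cross-entropy
(inverse-frequency "balanced" weights), early stopping on a stratified
10 % validation split, and a cosine learning-rate schedule annealing to
lr/10.  During repeated stratified 5-fold cross-validation the embedding
is retrained per fold on training-fold positive edges only, so no test
edge leaks into the embedding (`embed_on_full_prior=True` restores the
leaky single-fit variant for comparison).  The fold unit is the gene
pair; the same gene may appear on both sides of a split, which mirrors
how association-prediction benchmarks are usually scored and is a known
optimistic bias shared by the evaluated setup.

## Design choices in ambiguous places

* **Cnet nonlinearity.**  The pair head is written as two stacked dense
  layers; two purely linear layers collapse into one, so a ReLU is
  placed after the first dense layer.
* **Residual-block pooling.**  Each block's main branch contains two
  convolution units and the shortcut one; pooling with the nominal pool
  size in every unit would shrink the main branch twice as fast as the
  shortcut.  The net length reduction per block is therefore applied
  once: the first main-branch unit uses a unit pool.  Pooling is
  ceil-mode, so profiles as short as 4 samples survive three blocks.
* **Generator conditioning.**  An unconditioned generator cannot produce
  node-specific neighbors, so each generator concatenates a learned
  per-node condition vector with its Gaussian noise input.
* **Conflicting prior records.**  A (regulator, target) pair curated with
  both signs is dropped entirely: a 3-class label cannot represent dual
  regulation, and silently preferring one sign would bias the classes.
* **Constant genes** min–max-normalize to the all-zero profile
  (information-free, avoids division by zero).
* **Negative sampling** draws non-regulation pairs uniformly from
  regulator-anchored non-edges at a configurable ratio (default 1.0 ×
  positives); the first element is restricted to known regulators to
  match the regulator → target framing of the task.
* **Gene identifiers** match case-insensitively with whitespace
  stripped, because symbol casing differs across curation databases.

## Synthetic benchmark

The simulator generates the two properties the method leans on.
Structure: a sparse digraph whose edges originate from a small regulator
subset with preferential-attachment (heavy-tailed) out-degrees;
regulators are exogenous, so targets are non-regulator genes and
generation is single-pass.  Expression: linear-Gaussian — each regulator
has standard-normal activity per sample, each target is the signed
weighted (w ~ U(0.5, 1.5)) sum of its regulators' activities plus
N(0, noise_sd) noise, and unregulated genes are pure noise.  For a
single-regulator target this gives the closed form
|Pearson r| = w / √(w² + σ²), used as a test oracle; min–max
normalization is a positive affine map per gene and leaves correlations
unchanged.

The default conditions are 200 genes, 20 regulators, 400 signed edges
(activation fraction 0.5), 100 samples and noise_sd 0.3, giving ≈90 % of
nodes zero out-degree — the sparsity regime of curated prokaryote
networks — and pair correlations diluted by multi-regulator targets.
What the simulator does *not* emulate: regulator-on-regulator cascades
and feedback, nonlinear (saturating) regulation, heteroscedastic
measurement noise, batch effects, and time-series autocorrelation.
Passing the synthetic recovery tests therefore shows the pipeline can
learn signed, directed associations from correlated profiles at realistic
sparsity — not that it matches curated-network accuracy on real
compendia.

## Model configurations

`presets.default_*` follow common CNN practice for full-size runs:
extractor channels (32, 64, 128), kernel 3, pool 2, feature width 64,
Cnet width 64 → 64, dropout 0.5, head channels 64, embedding d = 64,
noise and condition width 32, Adam 1e-3 (classifier) / 2e-4 (GAN).

`presets.desk_*` is the configuration used by the bundled evaluation
scripts and heavy tests, sized for minutes-scale runs on one CPU core:
extractor channels (4, 6, 8) with kernel 3 and **pool 1**, Cnet
128 → 32, head channels 16, embedding d = 16, GAN 20 epochs, batch 32,
up to 100 classifier epochs with patience 15, early stopping monitored
on validation macro AUC (the headline metric) rather than loss.  Pool 1 is
a deliberate choice, not only a size reduction: the pair head compares
the two genes' feature sequences position by position, and on ~100-sample
profiles max-pooling discards the per-sample alignment that carries the
correlation signal (unpooled extraction scores markedly higher on the
synthetic benchmark).  With pooling disabled the global-average-pooling
contract still makes the expResNet feature width length-independent.

## Numerical details

* All tensors are float64; batch normalization uses eps 1e-5 and running
  stats with momentum 0.9 (batch statistics in training, running
  statistics at inference; a size-1 batch degenerates to the beta offset
  rather than NaN).
* Cross-entropy clips predicted probabilities at 1e-12 with a warning.
* Max-pooling pads with -inf (ceil mode); convolution padding is "same"
  with odd kernels only.
* One seed drives each run; every stochastic component (simulation,
  negative sampling, fold splits, parameter init, noise draws, dropout)
  derives from it, so reruns from a config snapshot reproduce fold
  assignments and sample lists exactly.
* Multiclass AUC is macro one-vs-rest with tie mid-ranks; multiclass MCC
  is the covariance (Gorodkin) form; zero-division precision/recall
  conventions return 0 with a warning.

## Known limitations

* The correlation module can exploit position-specific (sample-specific)
  patterns of the training regulators; it generalizes across pairs, not
  across unseen sample layouts.
* Fold-level (pair-level) CV shares genes between train and test pairs.
* The GAN offers no convergence guarantee; defaults were chosen for
  stability (sigmoid-bounded scores) and the `wgan_strict` flag (linear
  critic + weight clipping) is experimental.
* Binary mode reuses the same negative-sampling scheme; curated gold
  negatives, where available, are not consumed directly.
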