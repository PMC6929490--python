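# Methods

## Problem setting

Eight membrane-protein types are predicted from two inputs per protein:
the residue sequence and its PSSM (position-specific scoring matrix),
the L×20 integer log-odds profile produced by iterative profile search
in which entry M[i, j] scores residue j at position i.  Both inputs are
brought to a fixed length T (default 1500) by keeping the N-terminal
prefix of longer proteins and zero-padding shorter ones at the
C-terminal end; T = 1500 covers ~98% of sequences in curated
membrane-protein sets, whose lengths range over roughly 50–5000.

## Sequence encoding

Residues map to integer tokens in alphabetical one-letter-code order
(A = 0 … Y = 19).  The mapping is arbitrary under one-hot expansion;
fixing it alphabetically makes runs reproducible.  Ambiguity codes
(B, Z, X, U, O, J) map by default to the pad token and hence contribute
all-zero rows, so real-world FASTA files pass through; a strict policy
that raises instead is available.  Pad rows are all-zero in both the
one-hot (T×20) and embedded (T×d) representations; no masking layer is
used downstream — the zero rows themselves carry the "no residue"
signal, matching the zero-padding of the PSSM channel.

## Sequence model

Conv1D(256 filters, kernel 15, stride 10, same padding, ReLU) shortens
T = 1500 inputs to 150 steps (out = ceil(T/stride)); two bidirectional
LSTM layers follow (128 units per direction → 256-wide outputs; the
first returns the full sequence, the second only its final states), and
a dense softmax yields the 8 class probabilities.  Batch normalisation
(momentum 0.99) is applied after the convolution and after each
recurrent layer, following the activation.  The LSTM uses the standard
gate algebra (logistic input/forget/output gates, tanh candidate,
C_t = f_t·C_{t−1} + i_t·C̃_t), orthogonal recurrent initialisation and
a unit forget-gate bias; the stated dropout of 0.5 is applied to the
recurrent layers' inputs with one mask shared across timesteps.
Training: categorical cross-entropy, Adam (lr 1e-3, β₁ 0.9, β₂ 0.999,
decay 0), default batch 64; the retained weights are those of the epoch
with the best validation OSR (including the batch-norm running
statistics, so a restored model reproduces its validation score
exactly).

## Evolutionary model

The PSSM (T×20, one channel) passes through Conv2D(256, 5×5, valid,
ReLU) → dropout 0.5 → AvgPool(2×2) → Conv2D(128, 5×5, valid, ReLU) →
dropout 0.5 → AvgPool(2×2), giving 372×2×128 at full scale.  Dropout
sits after each convolution's activation and before pooling.  The
PrimaryCaps stage is a 1×1 convolution producing 4 capsule channels of
16 dimensions (64 output channels over the full 128-channel input),
reshaped to 372·2·4 = 2976 capsules of dimension 16 and squashed.  Each
primary capsule i predicts each of the 8 type capsules j through its
own untied 16×16 matrix W_ij (initialised N(0, 0.1²); a tied-per-channel
option exists for memory-constrained runs).  Dynamic routing runs 3
iterations: logits b start at 0 (re-initialised on every forward pass),
couplings are softmax over output capsules (so the first round couples
uniformly at 1/8 and every round satisfies Σ_j c_ij = 1), s_j is the
coupling-weighted sum of predictions, V_j = squash(s_j), and
b_ij += û_j|i·V_j.

The squashing function is V = (‖s‖²/(1+‖s‖²))·s/‖s‖ — monotone in ‖s‖,
bounded by 1, zero at zero (implemented as s·‖s‖/(1+‖s‖²) with a 1e-12
smoothing inside the norm, so it is differentiable at the origin).  An
"as_printed" mode computing s/(1+‖s‖²) is kept for auditing; its norm
peaks at 0.5 and then decreases, which contradicts the intended
"compresses length into [0, 1]" behaviour, so it is not the default.

Class scores are the output capsules' Euclidean norms.  Training uses
the margin loss (m⁺ = 0.9, m⁻ = 0.1, λ = 0.5; per-sample sum over the
8 class terms, batch mean) under Adam at lr 1e-4.

## Amino-acid embedding

An AAindex1-style table (20 residues × P property indexes; the full
published database has 557 indexes) is screened: any index containing
a missing ('NA') cell for any residue is dropped (537 survive in the
full database).  "Any-NA" rather than "all-NA" is assumed.  Because raw
index scales differ by orders of magnitude, each retained index is
z-scored over the 20 residues before training — an autoencoder on raw
scales degenerates to fitting the large-magnitude indexes; constant
columns are dropped with a warning, and the affine parameters are kept
so the transform is invertible (round-trip tested to 1e-10).

The autoencoder is symmetric, P → 128 → 64 → d → 64 → 128 → P with
d = 10 by default; hidden layers use ReLU while the bottleneck and the
output are linear, so embeddings are unconstrained in sign and
reconstruction is unrestricted on the z-scored scale.  Loss is mean
squared reconstruction error; the training set is exactly the 20
residue rows (full batch, Adam lr 1e-3, fixed epoch budget — there is
no held-out residue to stop on).  Training is deterministic given the
seed.  Each residue's bottleneck activation is its embedding vector.
A uniform-[0, 1] random table of the same dimension serves as the
control representation, and the 20×20 identity reproduces one-hot.

## Fusion

Base outputs are concatenated sequence-half first into a 16-vector;
capsule-norm scores are renormalised to sum 1 beforehand so both halves
live on a probability scale (a raw-norm mode exists; renormalisation
preserves the argmax).  The meta-classifier is multinomial logistic
regression with a weak L2 penalty (inverse strength C = 10) fit by
lbfgs — deterministic, so sample order does not affect the
coefficients.  Meta-training uses base predictions on the held-out
validation split, never on data the bases trained on; an out-of-fold
K-fold mode is provided as an alternative.  Meta-inference is a single
16×k affine map plus softmax and costs well under 1% of base-model
inference.

## Metrics

Per-class one-vs-rest counts give Se = TP/(TP+FN), Sp = TN/(TN+FP),
ACC = (TP+TN)/N and MCC; OSR is total correct over total samples.  All
metrics are computed from exact integer counts; any ratio with a zero
denominator (a class never present or never predicted) is defined as 0,
the convention under which never-predicted minority classes report
MCC = 0.0.

## Synthetic data

The generator reproduces the statistical couplings the models exploit,
with these defaults:

* **class compositions** — composition_c = (1−s)·uniform + s·peak_c,
  peaks drawn from Dirichlet(0.3·1); the mixing weight s
  ("separability") makes pairwise total-variation distance between
  classes monotone in s, with s = 0 collapsing all classes to the
  uniform background.  The study conditions use s = 0.9 (separable)
  and s = 0 (chance control).
* **lengths** — log-normal (μ = 6.0, σ = 0.64 on the log scale)
  clipped to [50, 5000]; ~98% of draws fall below 1500.  Scaled-down
  experiments use μ = log 150, σ = 0.25 clipped to [50, 200].
* **PSSMs** — row i = round(2·log₂(p_i/background)) + optional integer
  Gaussian noise, clipped to [−12, 12], where p_i mixes a point mass on
  the true residue (weight α = 0.6) with the class composition.  Every
  row therefore carries class signal, as real profiles do through
  conservation patterns.
* **class imbalance** — an 8-class mode mirrors benchmark-style
  imbalance (largest:smallest ≈ 55:1); the training tests use balanced
  4-class configurations to keep runtimes small.
* **property tables** — 20×P fixtures with planted rank-3 (or chosen
  rank) structure and a controlled fraction of NA-carrying indexes, in
  AAindex1 flat-file format.

Not emulated: transmembrane topology, domain architecture, homology
between sequences, and profile pseudo-count machinery.  Passing tests
on this data shows the models extract class-conditional compositional
and profile signal end to end; it does not certify the published
accuracies on curated benchmarks, which require the original datasets
and long GPU training.

## Scaled-down study conditions

CPU-scale experiments (tests and the acceptance script) use 4 balanced
classes × 100 proteins, T = 200, and reduced widths: the sequence model
with 64 conv filters and 32 LSTM units per direction; the capsule model
with 32+32 conv filters, 2 capsule channels of dimension 8, and
8-dimensional output capsules (47×2 spatial → 188 primary capsules).
The capsule model's scaled configuration trains at lr 1e-3 (the
full-scale default 1e-4 is tuned to much larger data and model sizes);
dropout is reduced to 0.2 for the small models.  Training stops early
once validation OSR reaches the configured target, and never exceeds
30 epochs, with a stratified 20% validation hold-out.

## Numerical choices

* All tensors are float64; the capsule forward pass matches a
  straight-line loop implementation to 1e-8 and routing to 1e-10.
* Norms are smoothed as sqrt(Σx² + 1e-12) to keep gradients finite at
  zero capsules.
* Softmax and cross-entropy are computed with max-shifts; batch-norm
  uses ε = 1e-3 (inference falls back to running statistics).
* Split sizes use round(fraction·n); stratified splitting is the
  default, a single-sample class stays in training with a warning.
* Ties in argmax resolve to the lowest class index (NumPy convention).

## Known limitations

* No masking-aware recurrence: padding rows enter the LSTM as zero
  vectors; for extremely short sequences most timesteps are padding.
* The NumPy engine is single-threaded apart from BLAS matmuls;
  full-scale training (1500×20 inputs, 256-filter stacks, 2976×8
  untied routing transforms) is functional but intended for
  demonstration, not production-scale fitting.
* The meta-classifier consumes the validation split, so no unbiased
  validation OSR exists for the fused model — only test-set figures.
* PSI-BLAST parameters behind real PSSMs (iterations, database,
  E-value) are outside the package's contract; users comparing against
  published accuracies must generate profiles consistently themselves.
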