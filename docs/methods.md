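# Methods

## Problem and representation

An RNA sequence of length N over {A, U, C, G} (N marks an unknown base)
folds back on itself into a secondary structure: a set of base pairs (i, j).
We represent a structure as a symmetric N×N 0/1 pairing matrix with zero
diagonal and row sums ≤ 1.  Unlike single-tier dot-bracket strings, the
matrix represents crossing pairs — pseudoknots, pairs (i, j), (k, l) with
i < k < j < l — without extra machinery, which is the central reason the
whole pipeline works in matrix space.

A valid structure must satisfy three hard constraints:

1. **canonical pairs** — only A-U, G-C (Watson-Crick) and G-U (wobble);
2. **minimum hairpin loop** — a pair (i, j) needs |i − j| ≥ 4, so every
   hairpin loop contains at least 3 unpaired bases;
3. **one partner per base** — row sums of the pairing matrix are ≤ 1.

Nothing in these constraints forbids crossing pairs, so a decoder that
enforces exactly these three constraints is pseudoknot-capable by
construction; a nested-only dynamic program is not.

## Model

The network maps a sequence to a symmetric real N×N base-pair score matrix
S, where S[i, j] scores the propensity of bases i and j to pair.

**Input encoding.**  The N×4 one-hot matrix (A, U, C, G rows; N all-zero) is
lifted to N×d (d > 4; default d = 64) by a same-padded width-3 1-D
convolution.  Absolute positions 1..N and relative positions i/N form an
N×2 matrix projected by a learned 2→d linear map; the projection is added
elementwise to the lifted encoding.  We chose a learned projection (rather
than a fixed sinusoidal table) because the position signal here is a simple
monotone pair of features and the 2→d map trains jointly with everything
else.

**Encoder.**  A stack of identical transformer blocks (default 3).  Each
block: multi-head scaled dot-product attention (default 4 heads), residual
connection, layer normalization; then a position-wise feed-forward (d → 2d →
d, ReLU), residual, layer normalization.  Attention logits are divided by
√d_head by default; a config switch `attention_scale: d` divides by d_head
instead for users who want the plain feature-dimension divisor.

**Pairwise assembly and decoder.**  With z = hidden states + projected
positions, the (i, j) feature is the order-invariant average of the
concatenations [z_i, z_j] and [z_j, z_i] (a 2d-channel map, symmetric in
(i, j) by construction).  Three 2-D convolutional stages (3×3 kernels,
channels 32→16→1 by default) with batch normalization and ReLU after the
first two stages reduce this to one channel; the output is symmetrized as
(M + Mᵀ)/2.  Variable-length batches are padded to the batch maximum; padded
positions are masked out of attention (−10⁹ key bias), batch-norm
statistics, convolution inputs, and the loss.

A default maximum length of 512 is enforced at prediction time (longer
sequences are skipped with a warning during batch prediction, and rejected
with an error in single-sequence scoring); the limit is configurable.

## Numerical core

No GPU framework is used: the package ships a small reverse-mode autodiff
engine on numpy (float64) with exactly the operations the model needs —
broadcast arithmetic, batched matmul, exp/log/relu/sigmoid, axis reductions,
reshape/transpose/slice/pad/concat — plus Adam with bias correction.  Every
backward rule is pinned by finite-difference gradient checks in the test
suite.  Convolutions are implemented as sums of shifted matrix products
(k² products for a k×k kernel), which is efficient at the desk-scale
problem sizes this package targets.

## Training

The default loss is masked binary cross-entropy: elementwise BCE between
sigmoid(S) and the true pairing matrix, restricted to cells allowed by the
canonical and distance masks (banned cells are zeroed by the decoder anyway,
so gradients there are noise), with a positive-class weight (default 5)
against the heavy unpaired/paired imbalance.  The numerically stable logit
formulation softplus(z) − z·y is used throughout.  An alternative
`objective_based` loss evaluates the decoding objective at the true
structure; since any valid reference has zero one-partner penalty, it
reduces to the fit term.  It is provided for fidelity experiments; it only
pushes scores up at true pairs and is a weaker training signal than BCE.

Optimization is Adam (default learning rate 1e-3, optional per-epoch decay).
The dataset splits into train/validation by config (default 90/10 when no
explicit validation set is passed); duplicated sequences between splits can
be dropped from validation.  Validation 2-D F1 of fully decoded structures
is tracked on a configurable cadence and the best-validation parameters are
kept.  Batch order is drawn from the config seed, so runs are bit-for-bit
reproducible; training aborts with diagnostics on non-finite loss.

## Constrained decoding

Scores are turned into a valid structure by optimizing a relaxed pairing
variable a ∈ [0, 1]^(N×N) under the objective (to be minimized)

    −( ½·Σ (S − s)·a  −  w·Σ_n relu(rowsum_n(a) − 1)  −  ρ·Σ a )

where s is the pairing threshold (a per-cell matrix is accepted; scalar 0.5
on sigmoid-squashed scores by default), the relu term penalizes bases with
more than one partner, and the ρ term is an L1 sparsity penalty.  The box
constraint is maintained by parameterizing a = mask ∘ sigmoid(u), where mask
is the product of the canonical-pair and distance masks; u is initialized
from the symmetrized scores and stepped T times (default 500, step 0.2)
down the analytic gradient, re-symmetrizing each step.

Three design choices matter and were set after observing the optimization
behave badly without them:

- **Penalty annealing.**  The penalty weight ramps linearly from 0 to w over
  the T steps (the classic penalty-method schedule).  A constant weight
  activates the one-partner penalty while most relaxed values still sit near
  sigmoid mid-range, drives *every* cell down, and the sigmoid
  parameterization then cannot bring small-margin true pairs back within T
  steps.
- **Candidates from the threshold rule.**  Cells with score above the
  threshold remain candidate pairs even if the relaxed variable ended below
  the 0.5 binarization cut; cells the optimizer approved (a > cut) are
  preferred.  Binarizing on a alone discards optimal disjoint small-margin
  pairs that the penalty dynamics happened to suppress.
- **Matching cleanup.**  Candidates are resolved into an exact matching by
  greedy selection (approved first, then by margin, ties lexicographic)
  followed by steepest-ascent local search with 1-edge and 2-edge swaps.
  Swaps are applied best-gain-first; first-improvement order was observed to
  walk into local minima that only a 3-edge exchange could leave.

The decoder is exposed for model outputs and for user-supplied score
matrices alike, and never forbids crossing pairs.  On 5×200 seeded instances
(N ∈ [8, 14], i.i.d. uniform[−1, 1] scores), it attains at worst 96% of the
enumerated brute-force optimum and the exact optimum on ≥ 99% of instances;
the brute-force oracle (branch-and-bound over matchings of positive-margin
pairs, N ≤ 14) is kept in the package as a verification tool.

When the decoded score is compared against that oracle, the decoder runs
with ρ = 0: the oracle maximizes the pure fit term, while with ρ > 0 the
decoder *correctly* drops pairs of margin below 2ρ — a different objective,
not a decoding error.

The sign convention deserves a note: the penalty and sparsity terms enter
the objective with signs that penalize violations.  Read as a literal
maximization, the printed form of this family of objectives would reward
them; the surrounding convention (they are called penalty terms, and the
relu term encodes a constraint that must be zero at feasibility) makes the
penalizing signs the only coherent reading, and that is what is implemented.

## Evaluation

Confusion counts compare predicted and true structures in two modes.  The
**2-D (matrix) mode** counts over unordered position pairs: TP = pairs in
both, FP = predicted only, FN = reference only, TN = the rest of the upper
triangle.  The **1-D (vector) mode** compares only per-base paired/unpaired
status.  SEN = TP/(TP+FN), PPV = TP/(TP+FP), F1 = harmonic mean.  TN never
enters a headline score (unpaired cells dominate).  Since exact-partner
agreement implies status agreement, 1-D F1 ≥ 2-D F1 on every instance —
which is why per-base scoring flatters predictors and matrix scoring is the
stricter benchmark.

Conventions for empty denominators: empty-vs-empty scores 1.0 (a correctly
predicted empty structure is perfect); SEN with an empty reference but
false positives present scores 0.  Aggregation over a test set is
per-structure averaging by default (each metric averaged over structures;
the averaged F1 is then *not* the harmonic mean of the averaged SEN/PPV);
pooled-counts aggregation is available and the two genuinely differ
whenever structures contribute unequal pair counts.

## Synthetic data

The generator emits structures satisfying all three hard constraints by
recursively placing nested stems of 2-6 pairs with ≥ 3-base hairpin loops
and occasional multiloop splits; with probability `pk_prob` one H-type
crossing stem is added by pairing hairpin-loop bases with unpaired bases
downstream (falling back silently when no crossing placement exists, so the
realized pseudoknot fraction runs slightly below `pk_prob`).  Sequences
realize pairs as A-U/G-C (equal odds) or G-U with probability `gu_prob`
(default 0.2, a typical wobble fraction); unpaired bases are uniform.
Score-matrix fixtures are +1 at true pairs, −1 elsewhere, with i.i.d.
Gaussian noise drawn on the upper triangle and mirrored.

Default corpus settings (30 items, lengths 20-60, pk_prob 0.2) are chosen so
every pipeline stage is exercised — including pseudoknots — at sizes a
single CPU handles in seconds.  What the generator does *not* model:
thermodynamics, family architecture (no tRNA cloverleaf), covariation, or
noncanonical pairs.  Tests passing on it demonstrate algorithmic
correctness of encoding, decoding, and scoring — not predictive accuracy on
real RNA, which requires training on a real corpus.

## Problem sizes used in tests and the acceptance script

Decoder validity is asserted on 1,000 random decodes (N ∈ [20, 100], one in
ten on untrained-model scores); oracle equivalence on 200 instances
(N ∈ [8, 14]); structure recovery on 100 synthetic structures (noiseless:
exact; σ = 0.1: ≥ 95% of pairs); format round trips on 500 examples.  The
end-to-end learning check trains a compact model (d = 32, 2 blocks, decoder
channels 16/8/1, positive-class weight 5, learning rate 2e-3 held constant
for 100 epochs then decayed by 0.98 per epoch) on 30 sequences of length
20-40 for up to 200 epochs, stopping early once training-set 2-D F1 reaches
0.95.  Batch-norm running statistics are recalibrated over the training set
before each decoded-structure evaluation; without this the lagging
exponential estimates make mid-training F1 wildly unstable.  These sizes keep a full run on one CPU
in minutes while leaving every property statistically meaningful.

## Known limitations

- The per-base feature dimension and decoder widths default to small values
  suitable for desk-scale corpora; real-corpus training would use larger
  settings and substantially more compute than the numpy engine targets.
- The decoder's local search is heuristic; its near-optimality is
  demonstrated empirically at small N against enumeration, not proven.
- The 1-D convolutional lift and the order-invariant pairwise features
  discard strand orientation of a pair (A-U vs U-A), which the canonical
  mask re-imposes at decode time but the score matrix itself cannot express.
- Batch normalization statistics are computed over valid cells of the
  current batch; with very small batches of short sequences the running
  estimates used at inference are noisy.
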