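# crossfold

RNA secondary-structure prediction with pseudoknots: an attention-based
encoder and a pairwise convolutional decoder score every candidate base
pair of a sequence, and a hard-constraint optimization stage converts the
score matrix into a valid structure.

## Who this is for

Researchers who need a structure predictor (or just a constrained decoder
and evaluation toolkit) that treats pseudoknots as first-class citizens.
Classic minimum-free-energy folders built on nested dynamic programming
cannot emit crossing pairs; this package works entirely in pairing-matrix
space, where a pseudoknot is just another symmetric 0/1 matrix.

## The model in brief

For a sequence of length N, the network produces a symmetric score matrix
S ∈ ℝ^(N×N), S_ij scoring the propensity of bases i, j to pair:

    one-hot (N×4) → conv1d lift (N×d) + position embedding (N×d)
      → 3 transformer blocks (multi-head attention, residual + LayerNorm)
      → pairwise features (N×N×2d) → 3 conv stages + BatchNorm → S (N×N)

Decoding maximizes the fit ½·Σ (S − s)∘R over relaxed pairing matrices R
subject to the three hard constraints of RNA secondary structure —
canonical pairs only (A-U, G-C, G-U), hairpin loops ≥ 3 bases
(|i − j| ≥ 4), one partner per base (Σ_j R_ij ≤ 1, imposed through the
penalty w·relu(rowsum − 1) plus an L1 sparsity term ρ‖R‖) — by projected
gradient descent with a sigmoid box parameterization, followed by an exact
matching cleanup.  Predictions are scored by sensitivity, positive
predictive value, and F1 over exact base pairs (2-D mode) or per-base
paired status (1-D mode).

Everything runs on a small numpy autodiff engine shipped with the package;
there is no GPU dependency.  See `docs/methods.md` for the full treatment.

## Worked example

```python
import crossfold as cf

# a pseudoknotted synthetic instance
truth = cf.sample_structure(50, pk_prob=1.0, seed=7)
seq = cf.sample_sequence(truth, seed=8)
scores = cf.noisy_score_matrix(truth, noise_sigma=0.3, seed=9)

decoded = cf.constrained_decode(scores, seq, cf.DecodeConfig(s=0.0, squash=False))
rep = cf.scores(cf.count_confusion_2d(decoded, truth))
print(cf.to_dotbracket(truth))
print(cf.to_dotbracket(decoded))
print(f"SEN={rep.sen:.3f}  PPV={rep.ppv:.3f}  F1={rep.f1:.3f}")
print("pseudoknot detected:", cf.detect_pseudoknots(decoded)[0])
```

prints

```
(([[[[.))((((((.....................)))))).]]]]...
(([[[[.))((((((.....................)))))).]]]]...
SEN=1.000  PPV=1.000  F1=1.000
pseudoknot detected: True
```

The decoder recovered every true pair from the noisy scores; the `[`
bracket tier marks the crossing stem, and F1 = 1 means the predicted pair
set equals the truth exactly.  The scripts in `examples/` walk through the
other capabilities: dataset simulation, end-to-end training, and per-family
evaluation in both scoring modes.

A thin command line mirrors the library:

```bash
crossfold simulate --out data --n 30 --seed 0
crossfold train --data data --checkpoint model.npz --log-tsv log.tsv
crossfold predict --checkpoint model.npz --fasta data/sequences.fasta --out preds
crossfold evaluate --pred preds --truth data
```

## Scope

Sequence/structure I/O (FASTA, BPSEQ, CT, extended dot-bracket), synthetic
corpus generation, model training and prediction, constrained decoding of
arbitrary score matrices, and matrix-mode evaluation.  Out of scope:
thermodynamic ensembles, alignment/covariation input, tertiary structure,
and pretrained weights — the package ships the machinery, not a trained
model of real RNA.
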