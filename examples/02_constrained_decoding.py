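"""Decode a noisy base-pair score matrix into a valid secondary structure.

A score matrix (+1 at true pairs, -1 elsewhere, Gaussian noise on top) is
pushed through the hard-constraint decoder: canonical-pair and minimum-loop
masks zero out impossible cells, T gradient steps on the penalized pairing
objective suppress one-to-many conflicts, and a final matching cleanup
guarantees a valid structure.  The decoded pairs are compared to the truth.
"""

import crossfold as cf

truth = cf.sample_structure(50, pk_prob=1.0, seed=7)
seq = cf.sample_sequence(truth, seed=8)
scores = cf.noisy_score_matrix(truth, noise_sigma=0.3, seed=9)

decoded = cf.constrained_decode(scores, seq, cf.DecodeConfig(s=0.0, squash=False))

rep = cf.scores(cf.count_confusion_2d(decoded, truth))
print("sequence      ", seq.bases)
print("true structure", cf.to_dotbracket(truth))
print("decoded       ", cf.to_dotbracket(decoded))
print(f"SEN={rep.sen:.3f}  PPV={rep.ppv:.3f}  F1={rep.f1:.3f}")
print("valid under hard constraints:", cf.validate_structure(decoded, seq))
print("pseudoknot detected:", cf.detect_pseudoknots(decoded)[0])

# F1 = 1.000 means the decoder recovered every true pair exactly despite the
# noise; validity holds by construction for any input scores.
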