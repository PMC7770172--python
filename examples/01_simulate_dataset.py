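"""Generate a small synthetic RNA dataset and inspect its structures.

Builds 10 sequences (lengths 25-50) with nested stems and occasional H-type
pseudoknots, writes them as FASTA + BPSEQ, and prints each structure in
extended dot-bracket notation (extra bracket tiers mark crossing pairs).
"""

from pathlib import Path

import crossfold as cf

out = Path("scratch/example_dataset")
cfg = cf.SynthConfig(n_items=10, length_range=(25, 50), pk_prob=0.3, seed=42)
items = cf.make_dataset(cfg, out_dir=out)

print(f"wrote {len(items)} records to {out}/\n")
for seq, struct in items:
    pk, crossings = cf.detect_pseudoknots(struct)
    tag = f"  <- pseudoknot ({len(crossings)} crossing pair-pairs)" if pk else ""
    print(seq.id, f"n={len(seq)}", f"pairs={len(struct.pairs)}")
    print("  ", seq.bases)
    print("  ", cf.to_dotbracket(struct), tag)

# Each line pairs a sequence with its structure: matching brackets are paired
# bases, dots are unpaired; '[' tiers appear only where pairs cross '(' pairs.
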