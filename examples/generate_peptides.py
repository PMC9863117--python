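"""Generate random peptides from the primitive amino-acid alphabets.

Draws 100 20-mers from the codon-ratio alphabet GA(D/E)V (G:A:D:V:E =
2:2:1:2:1), writes them as FASTA, and checks the pooled residue
composition against the target ratios.
"""

from collections import Counter

from primpep import generate_sequences, get_builtin_set, write_fasta

aa_set = get_builtin_set("GA(D/E)V")
seqs = generate_sequences(aa_set, n=100, length=20, seed=42)
write_fasta(seqs, "gadev_peptides.fasta")

pooled = Counter("".join(s.residues for s in seqs))
total = sum(pooled.values())
print(f"{len(seqs)} peptides of length {len(seqs[0])} written to gadev_peptides.fasta")
print("residue  observed  target")
for res, target in aa_set.probabilities().items():
    print(f"   {res}      {pooled[res] / total:.3f}    {target:.3f}")
# Observed frequencies track the normalized set weights (2:2:1:2:1 -> 0.25,
# 0.25, 0.125, 0.25, 0.125); per-sequence composition varies binomially.
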