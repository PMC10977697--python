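"""Degenerate and doped codon arithmetic.

Computes the amino-acid distribution of the NNK codon, the equimolar
19-amino-acid trinucleotide mixture, and the amino-acid-level mutation
rate produced by 70:10:10:10 doping (soft randomization).
"""

from dcphage import (
    NNK,
    STANDARD_CODE,
    aa_mutation_rate,
    codon_profile,
    mean_mutation_rate,
    trinucleotide_profile,
)

nnk = codon_profile(NNK)
print(f"NNK: stop probability {float(nnk.stop_probability):.5f} (= 1/32),",
      f"{len(nnk.support)} amino acids covered, Ser at {float(nnk['S']):.5f} (= 3/32)")

tri = trinucleotide_profile({"C"})
print(f"trinucleotide(-Cys): {len(tri.support)} amino acids at 1/19 each, stop = 0")

# one-codon examples: Met (single codon) loses its identity at 1 - 0.7^3
print(f"doped ATG at 70%: mutation rate {aa_mutation_rate('ATG', 0.7):.3f}")
print(f"doped GGA at 70%: mutation rate {aa_mutation_rate('GGA', 0.7):.3f}  (GGN all Gly)")

mean = mean_mutation_rate(STANDARD_CODE.sense_codons, 0.7)
print(f"mean over all 61 sense codons: {mean:.4f}  (~50% per doped position)")
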