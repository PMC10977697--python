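"""Library design: randomization schemes, diversity and oligo specs.

Builds the EETI-II two-loop library (loop1 at lengths 6/8/10, loop5 at
native length), reports its theoretical sequence-space size, and writes
the NNK-walking oligo panel for the template.
"""

from dcphage import (
    LibraryDesign,
    LoopScheme,
    RandomizationScheme,
    design_nnk_walk,
    design_soft,
    get_scaffold,
    reverse_translate,
    theoretical_diversity,
)

eeti = get_scaffold("EETI-II")
design = LibraryDesign(
    eeti,
    RandomizationScheme(
        {
            "loop1": LoopScheme("hard_trinucleotide"),  # lengths 6/8/10
            "loop5": LoopScheme("hard_trinucleotide"),  # native length 5
        }
    ),
    name="EETI-II two-loop library",
)
for cls in design.length_classes():
    print("length class:", dict(cls.loop_lengths), "-> peptide length", cls.total)
print(f"theoretical diversity: {theoretical_diversity(design):.3e}",
      "(= 19^11 + 19^13 + 19^15 over the three loop1 lengths)")

parent_nt = reverse_translate(eeti.template)
oligos = design_nnk_walk(eeti, parent_nt)
print(f"\nNNK walk: {len(oligos)} oligos (28 residues minus 6 cysteines)")
print("first oligo:", oligos[0].name, oligos[0].sequence)

soft = design_soft(design, parent_nt, ["loop1", "loop5"])
print(f"\nsoft oligo dopes {len(soft.doped)} codons:", sorted(soft.doped))
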