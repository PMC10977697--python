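"""Scaffold registry: templates, loops, and clone validation.

Lists the seven built-in disulfide-constrained peptide scaffolds, pulls
the loops out of a selected clone, and shows how framework validation
distinguishes intact clones from broken ones.
"""

from dcphage import builtin_scaffolds, extract_loops, get_scaffold, validate_framework

for sc in builtin_scaffolds():
    print(f"{sc.name:16s} {sc.template}  cys={sc.cys_positions}")

eeti = get_scaffold("EETI-II")

# a selected anti-Notch2 clone with an 8-residue loop1 (native length is 6)
clone = "GCEQSTWWAPCKQDSDCLAGCVCYQRWHCG"
assignment = extract_loops(eeti, clone)
print("\nclone loops:", assignment.loops)
print("reassembly exact:", assignment.reassemble() == clone)

broken = eeti.template[:8] + "S" + eeti.template[9:]  # Cys9 -> Ser
verdict = validate_framework(broken, eeti)
print("\nbroken clone valid:", bool(verdict), "| reason:", verdict.reason)
# The loop contents are free to vary; the cysteine framework is not.
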