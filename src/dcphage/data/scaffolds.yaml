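# Built-in disulfide-constrained peptide (DCP) scaffolds.
#
# Positions are 1-based inclusive on the mature displayed peptide.
# Loops are the variable-content segments between framework cysteines
# (a few scaffolds keep an anchor residue fixed just inside a loop, e.g.
# AVR9 Val19 and Circulin-A Tyr19; those anchors are part of the fixed
# framework, not the loop).  allowed_loop_lengths always contains the
# native length; extra lengths reflect the loop-length diversity built
# into the published libraries and observed in selected clones.
scaffolds:
  - name: EETI-II
    aliases: [EETI, EET]
    template: GCPRILMRCKQDSDCLAGCVCGPNGFCG
    display: p8
    loops:
      loop1: [3, 8]
      loop2: [10, 14]
      loop3: [16, 18]
      loop4: [20, 20]
      loop5: [22, 26]
    allowed_loop_lengths:
      loop1: [6, 8, 10]
      loop2: [5]
      loop3: [3]
      loop4: [1]
      loop5: [5]
    notes: >-
      Squash trypsin inhibitor cystine-knot peptide; loop1 supports
      length variants 6/8/10 and loop5 is randomized at native length.

  - name: AVR9
    aliases: [AVR]
    template: AFDCLGQCGRCDFHKLQCVHGVGLDYCNSSCTR
    display: p8
    loops:
      loop1: [5, 7]
      loop2: [9, 10]
      loop3: [12, 17]
      loop4: [20, 26]
      loop5: [28, 30]
    allowed_loop_lengths:
      loop1: [3]
      loop2: [2]
      loop3: [6]
      loop4: [6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16]
      loop5: [3]
    notes: >-
      Ring-opened (Arg13-Ala14 of the native cyclic form) fungal
      cystine-knot peptide; the synthetically fused terminal region
      (loop4, after the fixed Val19 anchor) is randomized at lengths
      6-16.

  - name: Circulin-A
    aliases: [CirA, Circulin]
    template: WIPCISAALGCSCKNKVCYRNGIPCGESC
    display: p8
    loops:
      loop1: [5, 10]
      loop2: [12, 12]
      loop3: [14, 17]
      loop4: [20, 24]
      loop5: [26, 28]
    allowed_loop_lengths:
      loop1: [6]
      loop2: [1]
      loop3: [4]
      loop4: [4, 5, 6, 7, 8, 9, 10, 11, 12]
      loop5: [3]
    notes: >-
      Ring-opened cyclotide; loop4 (after the fixed Tyr19 anchor) is the
      randomized protruding loop.

  - name: Conotoxin-MVIIA
    aliases: [CnTx, Conontoxin-MVIIA, Conotoxin]
    template: ECKGKGAKCSRLMYDCCTGSCRSGKC
    display: p8
    loops:
      loop1: [3, 8]
      loop2: [11, 15]
      loop3: [18, 20]
      loop4: [22, 25]
    allowed_loop_lengths:
      loop1: [6]
      loop2: [4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
      loop3: [3]
      loop4: [4]
    notes: >-
      Cone-snail cystine-knot toxin (Ca_V 2.2 blocker); loop2 (after the
      fixed Ser10 anchor) is randomized with loop-length diversity.

  - name: Huwentoxin
    aliases: [HwTx, Huwen-toxin]
    template: ACKGVFDACTPGKNECCPNRVCSDKHKWCKWKL
    display: p8
    loops:
      nterm: [3, 8]
      loop1: [11, 15]
      loop2: [18, 21]
      loop3: [23, 28]
      loop4: [30, 33]
    allowed_loop_lengths:
      nterm: [6]
      loop1: [4, 5, 6, 7, 8, 9, 10, 11, 12]
      loop2: [4]
      loop3: [6]
      loop4: [4]
    notes: >-
      Spider cystine-knot toxin; the long protruding loop after the
      fixed Thr10 anchor (labelled loop1 here) carries the
      randomization.

  - name: Charybdotoxin
    aliases: [ChTx, Charybdo-toxin, ChTx template]
    template: VSCTTSKECWSVCQRLHNTSKGGCQGSFCTCGP
    display: p8
    loops:
      loop1: [4, 8]
      loop2: [10, 12]
      loop3: [14, 23]
      loop4: [25, 28]
      loop5: [30, 30]
      cterm: [32, 33]
    allowed_loop_lengths:
      loop1: [5]
      loop2: [3]
      loop3: [8, 9, 10, 11, 12]
      loop4: [4]
      loop5: [1]
      cterm: [2]
    notes: >-
      Scorpion potassium-channel blocker; libraries randomize the
      beta-turn of loop4, an extended beta-sheet patch (loop3 tail,
      loop4, loop5, cterm) or the helix surface.

  - name: CBD
    aliases: [CBD-wt]
    template: GPTQSHYGQCGGIGYSGPTVCASGTTCQVLNPYYSQCLPGAS
    display: p8
    loops:
      nterm: [6, 9]
      loop1: [11, 20]
      loop2: [22, 26]
      loop3: [28, 36]
    allowed_loop_lengths:
      nterm: [4]
      loop1: [10]
      loop2: [5]
      loop3: [9]
    notes: >-
      Cellulose-binding domain of T. reesei cellobiohydrolase I; two
      disulfides only. Surface randomization targets the flat binding
      face (nterm patch, loop1 and loop3).
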