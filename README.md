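# dcphage

Library design and NGS enrichment analysis for phage-displayed
**disulfide-constrained peptide (DCP)** scaffolds.

Small peptides whose fold is pinned by a conserved cysteine framework —
cystine-knot peptides, ring-opened cyclotides, the two-disulfide
cellulose-binding domain — make unusually stable scaffolds for peptide
therapeutics. Their surface loops tolerate randomization, so phage
display libraries built on them can be panned against protein targets
to evolve new binders. `dcphage` implements the computational side of
such a discovery platform:

* **Scaffold registry** — seven built-in DCP scaffolds (EETI-II, AVR9,
  Circulin-A, Conotoxin-MVIIA, Huwentoxin, Charybdotoxin, CBD) with
  their cysteine frameworks and loop maps; validation of clone
  sequences against a framework (strict, or cysteine-framework-only for
  affinity-matured clones) and loop extraction.
* **Codon engine** — exact arithmetic (rational internally) on
  degenerate and doped codons: NNK profiles, equimolar 19-amino-acid
  trinucleotide mixtures, and 70:10:10:10 wild-type-biased doping with
  its amino-acid-level mutation rate.
* **Library design** — per-position amino-acid distributions per
  loop-length class, theoretical diversity counts, and mutagenic oligo
  specifications: hard (NNK / trinucleotide), soft (doped), and
  position-by-position NNK-walking panels with phagemid-complementary
  flanks.
* **Selection simulator** — naive library sampling from the design's
  positional profiles, multiplicative-fitness reweighting with
  multinomial resampling per panning round, and FASTQ emission with
  per-base substitution errors, so the whole analysis pipeline runs and
  is validated with no external data.
* **Enrichment analysis** — read filtering/translation, per-position
  frequency matrices, the enrichment-score matrix with blue-white-red
  heatmaps, conserved-position calls, sequence logos, and per-round
  clone ranking.
* **Hit calling** — spot-ELISA signal-to-noise, positivity calls,
  unique-clone tabulation per scaffold × target with hit rates, and SPR
  confirmation rates.

## The enrichment score

For amino acid *a* at position *i*, let *F0* be its frequency in the
pool before sorting and *F1* after sorting:

```
ES = (F1 − F0) / (1 − F0)   if F1 > F0        (enrichment)
ES = (F1 − F0) / F0         if F1 < F0        (de-enrichment)
ES = 0                      if F1 = F0        (including 0/0)
```

ES is bounded in [−1, 1]: +1 means the residue took over the sorted
pool, −1 that it vanished. A position whose every observed non-parental
residue scores ES ≤ −τ (default τ = 0.8) is called *conserved* — those
residues are required for binding or folding.

## Worked example

`examples/04_simulated_panning_enrichment.py` simulates a four-round
campaign on the EETI-II loop5 library with engineered residue
preferences (W/R/D/F/K at positions 22–26), runs the sequencing and
translation pipeline, and reads the preferences back from the ES matrix:

```
engineered -> recovered residue per position:
  position 22: engineered W, argmax-ES W, ES 0.463
  position 23: engineered R, argmax-ES R, ES 0.486
  position 24: engineered D, argmax-ES D, ES 0.772
  position 25: engineered F, argmax-ES F, ES 0.793
  position 26: engineered K, argmax-ES K, ES 0.815
```

Every engineered residue is the argmax-ES residue at its position; the
positive ES values say those residues expanded in the sorted pool while
all 18 alternatives were depleted. The same script ranks clones by
final-round abundance and writes the ES heatmap and a sequence logo.
The other examples cover scaffold validation (`01`), codon arithmetic
(`02`, e.g. the doped-ATG mutation rate 0.657 and the ~0.55 mean over
all 61 sense codons), library design and diversity (`03`, e.g. the
two-loop EETI-II library at 19¹¹ + 19¹³ + 19¹⁵ sequences), and hit
tabulation (`05`, reproducing the published campaign statistics:
242 EETI-II clones across 14/16 targets, 172 CBD clones across 11/16,
15/16 targets hit overall).

A thin CLI wraps the same functions:

```
dcphage design nnk-walk --scaffold EETI-II --out walk/
dcphage simulate --scaffold EETI-II --loop loop5 --seed 1 --out sim/
dcphage analyze --scaffold EETI-II --loop loop5 \
    --unsorted sim/round_0.fastq --sorted sim/round_4.fastq --out analysis/
dcphage hits --builtin-counts --out hits/
```

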