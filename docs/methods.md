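# Methods

## Scaffolds and loop geometry

Each scaffold is a mature displayed peptide template with a fixed
cysteine framework (six cysteines / three disulfides for the
cystine-knot scaffolds, four cysteines for CBD). Positions are 1-based
on the mature peptide. Loops are the variable-content segments between
framework cysteines; a few scaffolds keep an anchor residue fixed just
inside an inter-cysteine segment (AVR9 Val19, Circulin-A Tyr19,
Conotoxin-MVIIA Ser10, Huwentoxin Thr10), which the registry assigns to
the framework rather than the loop. Published sources do not print loop
boundary indices, so the registry derives them from the templates'
cysteine positions together with the loop contents observed in selected
clones; the same applies to allowed loop-length sets beyond the
explicitly stated ones (EETI-II loop1 at 6/8/10 residues, the AVR9
randomized segment at 6–16): the remaining sets bracket the loop
lengths observed in selected clones and are package choices.

Validation has two modes. `strict` matches the full framework — every
cysteine in the template's inter-cysteine topology, fixed segments
identical to the template, loop lengths within the allowed set (loops
may not contain cysteine, since an extra cysteine breaks the disulfide
pairing). `cys_only` checks only the cysteine framework: same cysteine
count, with template-adjacent cysteine pairs (the knot's CC motifs)
preserved. `cys_only` is the "intact sequence containing all
cysteines" criterion used for hit triage and is the right mode for
affinity-matured clones whose formerly fixed segments were deliberately
mutated; several published selected clones carry such framework
mutations (a C-terminal substitution, a fixed-segment point mutation, a
one-residue C-terminal overhang) and validate only in this mode.

## Codon arithmetic

A degenerate codon is three independent base mixtures; its induced
amino-acid distribution is the exact sum of per-codon products over the
64 codons of the standard genetic code (phage display in E. coli; no
alternative codes). Probabilities are exact `Fraction`s internally —
decimal floats such as 0.7 are read as 7/10 — and reported as floats.
The three mixture families are:

* **NNK** (uniform N, N, {G,T}): 32 equiprobable codons, all 20 amino
  acids, one stop (TAG) at 1/32.
* **Trinucleotide**: codon-level synthesis gives an equimolar
  amino-acid mixture directly; the default excludes cysteine (19 amino
  acids at 1/19, stop probability 0).
* **Doping** at wild-type fraction f (default 7/10): each position
  carries the parental base at f and every other base at (1−f)/3 — the
  70:10:10:10 soft-randomization mixture.

The amino-acid mutation rate of a doped codon is 1 − P(encoded amino
acid = parental amino acid). The default is unconditional (stop
outcomes count as mutations) because stop-containing clones cannot
display and are purged by selection; `condition_on_sense=True`
renormalizes over sense outcomes first. At f = 0.7 the unconditional
rate averaged over all 61 sense codons is 33303/61000 ≈ 0.546, i.e.
roughly a 50% amino-acid-level mutation rate per doped position;
single-codon amino acids (Met, Trp) sit at 1 − 0.7³ = 0.657 and
four-fold degenerate sites lower (Gly GGA at 0.51). Because the
parental codons actually present on a phagemid are generally unknown,
both the 61-codon average and per-sequence averages are exposed.

## Library designs and oligos

A design assigns each loop a mode: `fixed`, `hard_trinucleotide`,
`hard_nnk`, or `soft` (doped parental codons; requires a parental
nucleotide sequence and keeps the native loop length). Hard loops may
carry a set of allowed lengths; a design's length classes are the
cartesian product of loop-length choices. Per-position amino-acid
profiles are point masses at framework positions and the codon-induced
distribution at randomized positions. Theoretical diversity is the sum
over length classes of the product of per-position support sizes (stop
excluded); it deliberately measures sequence space, not transformant
counts, so it will not match physical library-size figures.

Parent clones known only at the protein level are reverse-translated
with a fixed one-codon-per-amino-acid table of high-usage E. coli
codons, making doped designs deterministic. NNK-walking produces one
oligo per requested residue position (default: all non-cysteine
positions — 22 for EETI-II), each the parental sequence with NNK at
that codon and 15-nucleotide parental flanks; flanks truncate at the
coding-region boundary unless vector context is supplied. Oligos are
stored sense-strand; doped positions cannot be written in IUPAC code
and are serialized as explicit per-base fractions alongside the
sequence.

## Selection simulator

The simulator exists to validate the enrichment pipeline end to end and
to support parameter recovery, not to model panning biophysics. A
campaign is:

1. **Naive library** (round 0): N independent draws from the design's
   positional profiles, the loop-length class uniform over the allowed
   classes. Stop codons never enter the pool — each position is drawn
   from its profile conditioned on non-stop outcomes, which equals
   rejecting and redrawing stop-containing sequences because positions
   are independent.
2. **Selection rounds**: with clone frequency F(s) and fitness weight
   w(s), the post-selection distribution is F′(s) = F(s)w(s) / Σ
   F(t)w(t), observed as a multinomial sample of the sequencing depth D.
   This multiplicative-reweighting + resampling update is the simplest
   model producing the monotone round-over-round enrichment seen in
   real campaigns; there are no PCR-bias or phage-growth terms, and
   bead/plate/washing-stringency differences appear only as
   fitness-scale knobs.
3. **Sequencing**: clones are reverse-translated, replicated per count,
   and subjected to i.i.d. per-base substitutions at rate ε
   (substitutions only — no indels, so frame and length class are
   preserved; length/indel robustness is the translation filter's job).
   Quality strings are uniform and unused by default.

Weights are w(s) = exp(Σᵢ e[i, sᵢ]) with additive per-position
energies (default 0 everywhere: neutral), optionally times a
per-sequence multiplier — needed for clone-specific scenarios such as
"one clone 100× fitter than any other", which additive energies cannot
express — and gated to zero for framework-invalid sequences when the
fold gate is on. Defaults (4 rounds, N = D = 10⁵, ε = 0) mirror a
four-round panning campaign at typical amplicon sequencing depth; all
simulator constants are calibration choices, not measured quantities.

What the simulator does *not* emulate: PCR jackpots and chimeras,
clone-dependent phage growth, avidity differences between p8 and p3
display, indels, and quality-score structure. Passing the recovery
tests therefore shows the analysis is correct under multinomial
sampling noise, not that it is robust to every real-data artifact.

## Enrichment analysis

Reads (nucleotide or amino acid, never mixed) are translated in frame 0
— simulator and assay amplicons are in-frame by construction, so no
frame search is done — and rejected with per-record reasons for
internal stops, lengths outside the design's length classes, ambiguous
bases, and cysteine-framework failures. Counts aggregate per unique
amino-acid sequence per round. Frequencies are computed per length
class only (pools of different loop lengths occupy different position
registers; no alignment is performed because library positions are
structurally fixed, and cross-class comparison is refused rather than
padded). Frequency weighting is read-count-based by default with a
unique-clone option; no pseudocount is used anywhere — the ES formula
handles zeros natively, with F1 = F0 (including 0/0) defined as ES = 0,
the continuous completion of both branches.

The ES matrix is the elementwise piecewise score of sorted vs unsorted
frequency matrices; the CSV export is the bit-exact source of truth and
the heatmap uses a diverging blue-white-red scale anchored at −1/0/+1
with positions on x and amino acids on y.

`conserved_positions` flags positions where every *observed*
non-parental residue has ES ≤ −τ (default τ = 0.8). Residues with ES
exactly 0 are treated as unobserved (the 0/0 case): residues absent
from both pools — cysteine under a 19-amino-acid mixture, anything at a
non-randomized position — carry no evidence and must not veto a call.

Sequence logos come in frequency mode (columns are the frequency
matrix) and information mode (heights F·(log₂20 − H) with H the
column's Shannon entropy in bits, no small-sample correction); the
logo matrix is computed by the package and rendered with matplotlib
glyph scaling.

### Which sorted round to compare

Clone *ranking* reads best from the final round, where selection has
concentrated the pool. Per-position *marginal* preferences read best
from an intermediate round (round 2 of a four-round campaign in the
recovery experiments): without recombination, a pool of 10⁵ clones over
a 19⁵ loop space almost never contains the jointly optimal sequence, so
late rounds fix on whole partial-match clones and blur per-position
marginals, while early-to-mid rounds still reflect the independent
per-position reweighting. Conservation is read from an NNK-walking-style
pool (single-position variants of a parent): that is the experiment the
readout belongs to, and jointly gating several positions of a fully
random pool would simply leave no survivors.

## Hit calling and tabulation

Spot-ELISA signal-to-noise is the target-well signal over the BSA
background signal (a zero background is surfaced as an error, not
treated as infinite S/N). A clone is positive when its sequence passes
cysteine-framework validation, its ELISA signal is ≥ 0.3 absorbance
units and its S/N exceeds 2. The signal threshold is inclusive because
the published selected-hit tables include a clone at exactly 0.3; the
comparison is configurable. Unique clones are exact sequence matches
within a scaffold × target cell (no near-duplicate clustering);
per-scaffold hit rate is targets-with-≥1-clone over targets screened,
and overall success is targets hit by any scaffold over all targets.
SPR confirmation counts numeric and bounded ("> 20 µM") dissociation
constants as confirmed; bounds are excluded from numeric Kd statistics.
The packaged tables keep their published values verbatim, including one
clone whose ELISA signal differs between the primary-hit and
affinity-maturation tables (0.3 vs 0.4); each table is used as its own
source of truth.

## Numerical and testing choices

Codon arithmetic is exact (rationals); profile sums are checked at
1e-9, mixture sums at 1e-12. Simulator experiments in the test suite
are seeded and deterministic; sampling-accuracy checks use chi-square
goodness-of-fit or 4-standard-error bounds when the check is a maximum
over many cells (a per-cell 3-SE band is crossed by chance even by a
perfect sampler). Test problem sizes: unit tests run at 10²–10⁴ clones;
the end-to-end recovery experiments use N = D = 10⁵ over four rounds
and four seeds, the scale at which multinomial noise is representative
while the suite stays fast. Clone ranking breaks ties
lexicographically by sequence so output is stable across runs.

## Known limitations

* Loop intervals and length sets beyond those explicitly published are
  inferred from clone evidence (see above) and may not match the
  original library exactly where no clone constrains them.
* The simulator's fitness model is phenomenological; recovered
  "energies" have no biophysical units.
* Diversity figures are sequence-space counts, not transformant counts.
* SPR kinetics fitting, enzyme-inhibition assays and synthesis/folding
  chemistry are out of scope; Kd values appear only as fixture
  metadata.
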