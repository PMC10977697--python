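"""Library designs: randomization schemes, diversity arithmetic, oligo specs.

A library design pairs a scaffold with a per-loop randomization scheme:

* ``fixed`` — the loop keeps its template residues;
* ``hard_trinucleotide`` — equimolar codon-level mixture (by default the
  19 amino acids excluding Cys);
* ``hard_nnk`` — NNK degenerate codon at every loop position;
* ``soft`` — 70:10:10:10 doping of the parental codons (~50% amino-acid
  mutation rate per position).

From a design the module derives per-position amino-acid distributions
per loop-length class, theoretical sequence-space sizes, and degenerate
oligo specifications for Kunkel-style mutagenesis, including
position-by-position NNK-walking panels.

Where only a protein sequence of the parent clone is known, reverse
translation uses a fixed one-codon-per-amino-acid table of high-usage
E. coli codons so that doped designs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

from .codons import (
    NNK,
    STANDARD_CODE,
    STOP,
    AAProfile,
    DegenerateCodon,
    GeneticCode,
    codon_profile,
    doped_codon,
    trinucleotide_profile,
)
from .scaffolds import Scaffold, validate_framework

#: One high-usage E. coli codon per amino acid, used for deterministic
#: reverse translation of protein-only parent clones.
ECOLI_CODONS: dict[str, str] = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

Mode = Literal["fixed", "hard_trinucleotide", "hard_nnk", "soft"]


def reverse_translate(aa_seq: str) -> str:
    """Deterministic nucleotide backbone for a protein sequence."""
    try:
        return "".join(ECOLI_CODONS[a] for a in aa_seq)
    except KeyError as e:
        raise ValueError(f"cannot reverse-translate residue {e.args[0]!r}") from None


def translate(nt_seq: str, code: GeneticCode = STANDARD_CODE) -> str:
    if len(nt_seq) % 3:
        raise ValueError("nucleotide length is not a multiple of 3")
    return "".join(code[nt_seq[i : i + 3].upper()] for i in range(0, len(nt_seq), 3))


@dataclass(frozen=True)
class LoopScheme:
    """Randomization of one loop."""

    mode: Mode
    lengths: Optional[frozenset[int]] = None  # None -> scaffold's allowed set
    excluded: frozenset[str] = frozenset({"C"})
    wt_fraction: Fraction = Fraction(7, 10)

    def __post_init__(self) -> None:
        if self.lengths is not None:
            object.__setattr__(self, "lengths", frozenset(self.lengths))


@dataclass(frozen=True)
class RandomizationScheme:
    loops: dict[str, LoopScheme]


class LengthClass(NamedTuple):
    """One combination of realized loop lengths."""

    loop_lengths: tuple[tuple[str, int], ...]
    total: int


@dataclass(frozen=True)
class LibraryDesign:
    """Scaffold + randomization scheme + display format."""

    scaffold: Scaffold
    scheme: RandomizationScheme
    name: str = ""
    display: str = "p8"

    def __post_init__(self) -> None:
        unknown = set(self.scheme.loops) - set(self.scaffold.loops)
        if unknown:
            raise ValueError(f"scheme loops {sorted(unknown)} not on scaffold {self.scaffold.name}")

    def loop_scheme(self, loop: str) -> LoopScheme:
        return self.scheme.loops.get(loop, LoopScheme("fixed"))

    def loop_lengths(self, loop: str) -> frozenset[int]:
        sch = self.loop_scheme(loop)
        if sch.lengths is not None:
            return sch.lengths
        if sch.mode in ("fixed", "soft"):
            # doping mutates residues in place; the loop keeps its native length
            return frozenset({self.scaffold.native_loop_length(loop)})
        return self.scaffold.allowed_loop_lengths[loop]

    def loop_length_sets(self) -> dict[str, frozenset[int]]:
        return {loop: self.loop_lengths(loop) for loop in self.scaffold.loops}

    def length_classes(self) -> list[LengthClass]:
        """All loop-length combinations, with resulting total peptide length."""
        loops = [s.name for s in self.scaffold.segments() if s.kind == "loop"]
        fixed_len = self.scaffold.length - sum(
            self.scaffold.native_loop_length(l) for l in loops
        )
        combos = []
        for lens in product(*(sorted(self.loop_lengths(l)) for l in loops)):
            combos.append(
                LengthClass(tuple(zip(loops, lens)), fixed_len + sum(lens))
            )
        return combos

    def allowed_total_lengths(self) -> frozenset[int]:
        return frozenset(c.total for c in self.length_classes())


def fixed_design(scaffold: Scaffold, name: str = "") -> LibraryDesign:
    """A design with every loop fixed at the template sequence."""
    return LibraryDesign(scaffold, RandomizationScheme({}), name=name or f"{scaffold.name}-fixed")


def _loop_position_profile(
    scheme: LoopScheme, parent_codon: Optional[str], code: GeneticCode
) -> AAProfile:
    if scheme.mode == "hard_trinucleotide":
        return trinucleotide_profile(scheme.excluded)
    if scheme.mode == "hard_nnk":
        return codon_profile(NNK, code)
    if scheme.mode == "soft":
        if parent_codon is None:
            raise ValueError("soft randomization requires a parental nucleotide sequence")
        return codon_profile(doped_codon(parent_codon, scheme.wt_fraction, code), code)
    raise AssertionError(scheme.mode)


def positional_profiles(
    design: LibraryDesign,
    parent_nt: Optional[str] = None,
    code: GeneticCode = STANDARD_CODE,
) -> dict[LengthClass, list[AAProfile]]:
    """Per-position amino-acid distribution for each loop-length class.

    Fixed framework positions get a point mass on the template residue;
    randomized positions get the profile their codon chemistry induces.
    Soft loops require ``parent_nt`` (the parental coding sequence, at
    native length) and are only defined at the parental loop length.
    """
    parent_aa = translate(parent_nt, code) if parent_nt else None
    if parent_aa is not None and len(parent_aa) != design.scaffold.length:
        raise ValueError(
            "parent nucleotide sequence must encode the scaffold-length peptide"
        )
    out: dict[LengthClass, list[AAProfile]] = {}
    for cls in design.length_classes():
        lens = dict(cls.loop_lengths)
        profiles: list[AAProfile] = []
        for seg in design.scaffold.segments():
            if seg.kind == "cys":
                profiles.append(AAProfile.point_mass("C"))
            elif seg.kind == "fixed":
                for i in range(seg.start, seg.end + 1):
                    profiles.append(AAProfile.point_mass(design.scaffold.template[i - 1]))
            else:
                scheme = design.loop_scheme(seg.name)
                native = seg.end - seg.start + 1
                n = lens[seg.name]
                if scheme.mode == "fixed":
                    for i in range(seg.start, seg.end + 1):
                        profiles.append(AAProfile.point_mass(design.scaffold.template[i - 1]))
                elif scheme.mode == "soft":
                    if n != native:
                        raise ValueError(
                            f"soft loop {seg.name} only defined at native length {native}"
                        )
                    for i in range(seg.start, seg.end + 1):
                        codon = parent_nt[(i - 1) * 3 : i * 3] if parent_nt else None
                        profiles.append(_loop_position_profile(scheme, codon, code))
                else:
                    prof = _loop_position_profile(scheme, None, code)
                    profiles.extend([prof] * n)
        assert len(profiles) == cls.total
        out[cls] = profiles
    return out


def theoretical_diversity(design: LibraryDesign) -> int:
    """Number of distinct peptide sequences the design can encode.

    Sum over loop-length combinations of the product of per-position
    amino-acid support sizes (stop excluded).  Only meaningful for
    hard/fixed schemes: soft randomization reaches every sequence with
    non-zero probability, so its support size is reported the same way
    but is not a practical diversity figure.
    """
    total = 0
    for cls in design.length_classes():
        n = 1
        lens = dict(cls.loop_lengths)
        for seg in design.scaffold.segments():
            if seg.kind != "loop":
                continue
            scheme = design.loop_scheme(seg.name)
            if scheme.mode == "fixed":
                continue
            if scheme.mode == "hard_trinucleotide":
                support = len(trinucleotide_profile(scheme.excluded).support)
            elif scheme.mode == "hard_nnk":
                support = len(codon_profile(NNK).support)
            else:  # soft reaches all 20 per position
                support = 20
            n *= support ** lens[seg.name]
        total += n
    return total


@dataclass(frozen=True)
class OligoSpec:
    """A mutagenic oligo: coding span (IUPAC letters) plus flanks.

    Doped (biased-mixture) codons cannot be written in IUPAC, so their
    positions carry the parental codon in ``sequence`` and the explicit
    doping in ``doped`` (codon index -> (parental codon, wt fraction)).
    Trinucleotide codons appear as ``NNN`` in the sequence with the
    exact amino-acid mixture recorded in ``annotations``.
    """

    name: str
    sequence: str                      # flank5 + coding span + flank3
    flank5: int
    flank3: int
    target_codons: tuple[int, ...]     # 1-based codon (residue) positions
    doped: dict[int, tuple[str, Fraction]] = field(default_factory=dict)
    annotations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        coding = self.coding_span
        if len(coding) % 3:
            raise ValueError("coding span length is not a multiple of 3")
        flanks = self.sequence[: self.flank5] + self.sequence[len(self.sequence) - self.flank3 :]
        if any(b not in "ACGT" for b in flanks):
            raise ValueError("flanks must not contain degenerate bases")

    @property
    def coding_span(self) -> str:
        return self.sequence[self.flank5 : len(self.sequence) - self.flank3 or None]


def design_nnk_walk(
    scaffold: Scaffold,
    parent_nt: str,
    positions: Optional[Iterable[int]] = None,
    flank: int = 15,
    context5: str = "",
    context3: str = "",
) -> list[OligoSpec]:
    """One NNK oligo per requested residue position of a parent clone.

    The default position set is every non-cysteine residue.  Each oligo
    carries the NNK codon for its position with ``flank``-nucleotide
    parental (phagemid-complementary) flanks on both sides; vector
    context beyond the coding region may be supplied for positions near
    the termini, otherwise edge flanks are truncated.
    """
    parent_aa = translate(parent_nt)
    verdict = validate_framework(parent_aa, scaffold)
    if not verdict:
        raise ValueError(f"parent does not validate on {scaffold.name}: {verdict.reason}")
    cys = {i + 1 for i, a in enumerate(parent_aa) if a == "C"}
    if positions is None:
        positions = [i for i in range(1, len(parent_aa) + 1) if i not in cys]
    else:
        positions = sorted(set(positions))
        bad = [i for i in positions if not 1 <= i <= len(parent_aa)]
        if bad:
            raise ValueError(f"positions {bad} outside parent (length {len(parent_aa)})")
    full = context5 + parent_nt + context3
    off = len(context5)
    oligos = []
    for pos in positions:
        lo = off + (pos - 1) * 3
        hi = lo + 3
        f5 = min(flank, lo)
        f3 = min(flank, len(full) - hi)
        seq = full[lo - f5 : lo] + "NNK" + full[hi : hi + f3]
        oligos.append(
            OligoSpec(
                name=f"nnkwalk_{scaffold.name}_{pos:02d}",
                sequence=seq,
                flank5=f5,
                flank3=f3,
                target_codons=(pos,),
                annotations={pos: "NNK"},
            )
        )
    return oligos


def _mutagenic_oligo(
    design: LibraryDesign,
    parent_nt: str,
    loops: Iterable[str],
    codon_for_position,
    name: str,
) -> OligoSpec:
    scaffold = design.scaffold
    parent_aa = translate(parent_nt)
    if len(parent_aa) != scaffold.length:
        raise ValueError("parent must be a native-length clone of the scaffold")
    loops = set(loops)
    unknown = loops - set(scaffold.loops)
    if unknown:
        raise ValueError(f"unknown loops {sorted(unknown)}")
    targets: list[int] = []
    for loop in loops:
        s, e = scaffold.loops[loop]
        targets.extend(range(s, e + 1))
    targets.sort()
    seq_parts: list[str] = []
    doped: dict[int, tuple[str, Fraction]] = {}
    annotations: dict[int, str] = {}
    for pos in range(1, scaffold.length + 1):
        codon = parent_nt[(pos - 1) * 3 : pos * 3]
        if pos in targets:
            letters, note, dope = codon_for_position(pos, codon)
            seq_parts.append(letters)
            annotations[pos] = note
            if dope is not None:
                doped[pos] = dope
        else:
            seq_parts.append(codon)
    return OligoSpec(
        name=name,
        sequence="".join(seq_parts),
        flank5=0,
        flank3=0,
        target_codons=tuple(targets),
        doped=doped,
        annotations=annotations,
    )


def design_soft(
    design: LibraryDesign,
    parent_nt: str,
    loops: Iterable[str],
    wt_fraction=Fraction(7, 10),
) -> OligoSpec:
    """Soft-randomization oligo: doped codons across the targeted loops."""
    from .codons import _as_fraction

    f = _as_fraction(wt_fraction)

    def codon_for(pos: int, codon: str):
        doped_codon(codon, f)  # validates sense parent
        return codon, f"doped({codon},{f})", (codon, f)

    return _mutagenic_oligo(
        design, parent_nt, loops, codon_for, name=f"soft_{design.scaffold.name}"
    )


def design_hard(
    design: LibraryDesign,
    loops: Iterable[str],
    codon_mode: Literal["NNK", "trinucleotide"] = "NNK",
    parent_nt: Optional[str] = None,
) -> OligoSpec:
    """Hard-randomization oligo: NNK or trinucleotide codons on the targeted loops.

    The non-targeted backbone comes from ``parent_nt`` when given, else
    from the deterministic reverse translation of the scaffold template.
    """
    if parent_nt is None:
        parent_nt = reverse_translate(design.scaffold.template)

    def codon_for(pos: int, codon: str):
        if codon_mode == "NNK":
            return "NNK", "NNK", None
        if codon_mode == "trinucleotide":
            return "NNN", "trinucleotide(19aa,-Cys)", None
        raise ValueError(f"unknown codon mode {codon_mode!r}")

    return _mutagenic_oligo(
        design, parent_nt, loops, codon_for,
        name=f"hard_{codon_mode}_{design.scaffold.name}",
    )
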