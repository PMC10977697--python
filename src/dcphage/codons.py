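"""Exact arithmetic on degenerate and doped codons.

A degenerate codon is a triple of nucleotide mixtures; multiplying the
per-position base probabilities over the 64 codons of the standard
genetic code induces a distribution over amino acids (plus stop).  This
is the primitive behind NNK randomization, trinucleotide (codon-level)
mixtures, and 70:10:10:10 wild-type-biased doping, and it lets the
amino-acid-level mutation rate of a doped codon be computed exactly.

Probabilities are kept as exact ``fractions.Fraction`` internally
(floats such as 0.7 are interpreted via their decimal literal, so the
70:10:10:10 mixture is exactly 7/10, 1/10, 1/10, 1/10); results are
reported as floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from itertools import product
from numbers import Rational
from typing import Iterable, Mapping, Union

from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"

#: IUPAC degenerate nucleotide codes.
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_REVERSE = {frozenset(v): k for k, v in IUPAC_BASES.items()}

Number = Union[int, float, Fraction]


def _as_fraction(x: Number) -> Fraction:
    """Exact rational for a probability given as int, Fraction, or decimal float."""
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid (or ``*``) mapping; only the standard code is shipped."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        sense = sum(1 for aa in self.table.values() if aa != STOP)
        stops = sum(1 for aa in self.table.values() if aa == STOP)
        if len(self.table) != 64 or sense != 61 or stops != 3:
            raise ValueError("genetic code must map 64 codons with 61 sense and 3 stops")

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa != STOP)

    @classmethod
    @lru_cache(maxsize=1)
    def standard(cls) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        table = {
            "".join(c): bio.forward_table.get("".join(c), STOP)
            for c in product(BASES, repeat=3)
        }
        return cls(table)


STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class NucleotideMixture:
    """Probabilities over A/C/G/T at one codon position; must sum to 1."""

    probs: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        clean = {b: _as_fraction(p) for b, p in self.probs.items() if _as_fraction(p) != 0}
        if set(clean) - set(BASES):
            raise ValueError(f"unknown bases {set(clean) - set(BASES)!r}")
        if any(p < 0 for p in clean.values()):
            raise ValueError("negative base probability")
        total = sum(clean.values())
        if abs(float(total) - 1.0) > 1e-12:
            raise ValueError(f"base probabilities sum to {float(total)}, not 1")
        object.__setattr__(self, "probs", clean)

    def __getitem__(self, base: str) -> Fraction:
        return self.probs.get(base, Fraction(0))

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.probs)

    def is_uniform(self) -> bool:
        vals = set(self.probs.values())
        return len(vals) == 1

    @classmethod
    def fixed(cls, base: str) -> "NucleotideMixture":
        return cls({base: Fraction(1)})

    @classmethod
    def uniform(cls, bases: Iterable[str]) -> "NucleotideMixture":
        bases = list(bases)
        return cls({b: Fraction(1, len(bases)) for b in bases})

    @classmethod
    def from_iupac(cls, code: str) -> "NucleotideMixture":
        try:
            return cls.uniform(IUPAC_BASES[code.upper()])
        except KeyError:
            raise ValueError(f"unknown IUPAC base code {code!r}") from None

    def to_iupac(self) -> str:
        """IUPAC letter for a uniform mixture; raises for biased (doped) mixtures."""
        if not self.is_uniform():
            raise ValueError(
                "mixture is not uniform over its support; no IUPAC code "
                "(serialize doped mixtures as explicit base fractions)"
            )
        return _IUPAC_REVERSE[self.support]


@dataclass(frozen=True)
class DegenerateCodon:
    """Three independent nucleotide mixtures plus a human-readable label."""

    positions: tuple[NucleotideMixture, NucleotideMixture, NucleotideMixture]
    label: str = ""

    def probability(self, codon: str) -> Fraction:
        return self.positions[0][codon[0]] * self.positions[1][codon[1]] * self.positions[2][codon[2]]

    @classmethod
    def from_iupac(cls, code: str) -> "DegenerateCodon":
        if len(code) != 3:
            raise ValueError("degenerate codon needs exactly 3 IUPAC letters")
        return cls(tuple(NucleotideMixture.from_iupac(c) for c in code), label=code.upper())

    def to_iupac(self) -> str:
        return "".join(m.to_iupac() for m in self.positions)


#: The NNK codon: any base at positions 1-2, G/T at position 3.
#: 32 equiprobable codons covering all 20 amino acids with one stop (TAG).
NNK = DegenerateCodon.from_iupac("NNK")


@dataclass(frozen=True)
class AAProfile:
    """Probability distribution over the 20 amino acids plus stop."""

    probs: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        clean = {a: _as_fraction(p) for a, p in self.probs.items() if _as_fraction(p) != 0}
        if any(p < 0 for p in clean.values()):
            raise ValueError("negative amino-acid probability")
        if abs(float(sum(clean.values())) - 1.0) > 1e-9:
            raise ValueError("amino-acid probabilities must sum to 1")
        object.__setattr__(self, "probs", clean)

    def __getitem__(self, aa: str) -> Fraction:
        return self.probs.get(aa, Fraction(0))

    @property
    def stop_probability(self) -> Fraction:
        return self[STOP]

    @property
    def support(self) -> frozenset[str]:
        """Amino acids (stop excluded) with non-zero probability."""
        return frozenset(a for a in self.probs if a != STOP)

    def as_floats(self) -> dict[str, float]:
        return {a: float(p) for a, p in sorted(self.probs.items())}

    def condition_on_sense(self) -> "AAProfile":
        """Renormalize over non-stop outcomes (displayed clones only)."""
        sense = {a: p for a, p in self.probs.items() if a != STOP}
        total = sum(sense.values())
        if total == 0:
            raise ValueError("profile has no sense outcomes")
        return AAProfile({a: p / total for a, p in sense.items()})

    @classmethod
    def point_mass(cls, aa: str) -> "AAProfile":
        return cls({aa: Fraction(1)})


def codon_profile(codon: DegenerateCodon, code: GeneticCode = STANDARD_CODE) -> AAProfile:
    """Amino-acid distribution induced by a degenerate codon.

    profile[aa] = sum over the codons translating to aa of the product of
    the three per-position base probabilities.
    """
    probs: dict[str, Fraction] = {}
    for b1 in codon.positions[0].support:
        for b2 in codon.positions[1].support:
            for b3 in codon.positions[2].support:
                c = b1 + b2 + b3
                p = codon.probability(c)
                aa = code[c]
                probs[aa] = probs.get(aa, Fraction(0)) + p
    return AAProfile(probs)


def trinucleotide_profile(excluded: Iterable[str] = ("C",)) -> AAProfile:
    """Equimolar codon-level (trinucleotide) mixture over non-excluded amino acids.

    Trinucleotide synthesis adds whole codons, so the distribution is
    uniform at the amino-acid level with zero stop probability; the
    published libraries use the 19-amino-acid mixture excluding Cys.
    """
    excluded = set(excluded)
    aas = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a not in excluded]
    if not aas:
        raise ValueError("cannot exclude all 20 amino acids")
    return AAProfile({a: Fraction(1, len(aas)) for a in aas})


def doped_codon(
    wt_codon: str,
    wt_fraction: Number = Fraction(7, 10),
    code: GeneticCode = STANDARD_CODE,
) -> DegenerateCodon:
    """Wild-type-biased (soft randomization) codon.

    Each position carries the parental base at ``wt_fraction`` and every
    other base at ``(1 - wt_fraction)/3`` — the 70:10:10:10 doping
    mixture at the default.
    """
    wt_codon = wt_codon.upper()
    if code[wt_codon] == STOP:
        raise ValueError(f"{wt_codon} is a stop codon; doping requires a sense parent")
    f = _as_fraction(wt_fraction)
    if not 0 < f <= 1:
        raise ValueError("wt_fraction must be in (0, 1]")
    off = (1 - f) / 3
    mixes = tuple(
        NucleotideMixture({b: (f if b == wb else off) for b in BASES})
        for wb in wt_codon
    )
    return DegenerateCodon(mixes, label=f"doped({wt_codon},{f})")


def aa_mutation_rate(
    wt_codon: str,
    wt_fraction: Number = Fraction(7, 10),
    condition_on_sense: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Probability that a doped codon encodes a different amino acid than its parent.

    Unconditional by default (stop outcomes count as mutations, since
    stop-containing clones cannot display and are purged by selection);
    with ``condition_on_sense`` the profile is first renormalized over
    non-stop outcomes.
    """
    profile = codon_profile(doped_codon(wt_codon, wt_fraction, code), code)
    if condition_on_sense:
        profile = profile.condition_on_sense()
    return float(1 - profile[code[wt_codon.upper()]])


def mean_mutation_rate(
    codons: Iterable[str],
    wt_fraction: Number = Fraction(7, 10),
    condition_on_sense: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Unweighted mean of :func:`aa_mutation_rate` over a list of sense codons."""
    codons = list(codons)
    if not codons:
        raise ValueError("empty codon list")
    return sum(
        aa_mutation_rate(c, wt_fraction, condition_on_sense, code) for c in codons
    ) / len(codons)
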