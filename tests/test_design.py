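"""Library designs: positional profiles, diversity arithmetic, oligo specs."""

from fractions import Fraction
from itertools import product

import pytest

from dcphage import (
    LibraryDesign,
    LoopScheme,
    RandomizationScheme,
    design_hard,
    design_nnk_walk,
    design_soft,
    fixed_design,
    positional_profiles,
    reverse_translate,
    theoretical_diversity,
    translate,
)
from dcphage.scaffolds import Scaffold


def test_reverse_translate_roundtrip(eeti):
    nt = reverse_translate(eeti.template)
    assert len(nt) == 3 * eeti.length
    assert translate(nt) == eeti.template


def test_positional_profiles_loop5_uniform_19(loop5_design):
    profiles = positional_profiles(loop5_design)
    (cls,) = profiles
    assert cls.total == 28
    for pos in range(22, 27):
        prof = profiles[cls][pos - 1]
        assert len(prof.support) == 19
        assert prof["G"] == Fraction(1, 19)
        assert prof["C"] == 0
    # framework positions are point masses on the template residue
    assert profiles[cls][0].support == {"G"}
    assert profiles[cls][1].support == {"C"}


def test_positional_profiles_all_fixed(eeti):
    profiles = positional_profiles(fixed_design(eeti))
    (cls,) = profiles
    assert all(len(p.support) == 1 for p in profiles[cls])
    assert "".join(next(iter(p.support)) for p in profiles[cls]) == eeti.template


def test_positional_profiles_soft_needs_parent(eeti):
    design = LibraryDesign(eeti, RandomizationScheme({"loop1": LoopScheme("soft")}))
    with pytest.raises(ValueError):
        positional_profiles(design)
    parent_nt = reverse_translate(eeti.template)
    profiles = positional_profiles(design, parent_nt=parent_nt)
    (cls,) = profiles
    # doped parental codon retains its residue at 0.7^k for a codon with
    # k non-degenerate positions; Pro (CCG -> CCN silent) retains 0.49
    prof = profiles[cls][2]  # position 3 = Pro
    assert float(prof["P"]) == pytest.approx(0.49, abs=1e-12)


def test_hard_profiles_independent_of_parent(loop5_design, eeti):
    a = positional_profiles(loop5_design)
    b = positional_profiles(loop5_design, parent_nt=reverse_translate(eeti.template))
    assert a == b


def test_theoretical_diversity_closed_forms(loop5_design, loop1_loop5_design, eeti):
    assert theoretical_diversity(loop5_design) == 19**5
    # loop1 length classes 6/8/10 x loop5 native 5
    assert theoretical_diversity(loop1_loop5_design) == 19**11 + 19**13 + 19**15
    assert theoretical_diversity(fixed_design(eeti)) == 1
    single_loop6 = LibraryDesign(
        eeti,
        RandomizationScheme({"loop1": LoopScheme("hard_trinucleotide", lengths=frozenset({6}))}),
    )
    assert theoretical_diversity(single_loop6) == 19**6 == 47_045_881


def test_theoretical_diversity_matches_brute_force_enumeration():
    """Oracle equivalence on a tiny design: enumerate every sequence."""
    toy = Scaffold(
        name="toy",
        template="GAAAG",
        loops={"x": (2, 4)},
        allowed_loop_lengths={"x": frozenset({1, 2, 3})},
    )
    keep = set("ADEF")
    excluded = frozenset(set("ACDEFGHIKLMNPQRSTVWY") - keep)
    design = LibraryDesign(toy, RandomizationScheme({"x": LoopScheme("hard_trinucleotide", excluded=excluded)}))
    enumerated = {
        "G" + "".join(body) + "G"
        for n in (1, 2, 3)
        for body in product(sorted(keep), repeat=n)
    }
    assert theoretical_diversity(design) == len(enumerated) == 4 + 16 + 64


def test_nnk_walk_default_covers_non_cys_positions(eeti):
    parent_nt = reverse_translate(eeti.template)
    oligos = design_nnk_walk(eeti, parent_nt)
    assert len(oligos) == 22  # 28 residues minus 6 framework cysteines
    positions = {o.target_codons[0] for o in oligos}
    assert positions.isdisjoint(set(eeti.cys_positions))


def test_nnk_walk_single_position_flanks(eeti):
    parent_nt = reverse_translate(eeti.template)
    (oligo,) = design_nnk_walk(eeti, parent_nt, positions=[7], flank=15)
    assert oligo.flank5 == oligo.flank3 == 15
    assert oligo.sequence[15:18] == "NNK"
    assert oligo.sequence[:15] == parent_nt[3 : 3 * 6]  # 15 nt upstream of codon 7
    # zero-flank variant carries the coding span only
    (bare,) = design_nnk_walk(eeti, parent_nt, positions=[7], flank=0)
    assert bare.sequence == "NNK"


def test_nnk_walk_position_errors(eeti):
    parent_nt = reverse_translate(eeti.template)
    with pytest.raises(ValueError):
        design_nnk_walk(eeti, parent_nt, positions=[99])


def test_soft_oligo_dopes_exactly_the_targeted_loops(eeti):
    design = LibraryDesign(
        eeti,
        RandomizationScheme(
            {"loop1": LoopScheme("soft"), "loop5": LoopScheme("soft")}
        ),
    )
    parent_nt = reverse_translate(eeti.template)
    oligo = design_soft(design, parent_nt, ["loop1", "loop5"])
    assert set(oligo.target_codons) == set(range(3, 9)) | set(range(22, 27))
    assert set(oligo.doped) == set(oligo.target_codons)
    # untouched backbone translates to the parent outside the loops
    assert translate(oligo.sequence) == eeti.template
    empty = design_soft(design, parent_nt, [])
    assert empty.sequence == parent_nt and not empty.doped


def test_hard_oligo_marks_targeted_loops(eeti, loop5_design):
    oligo = design_hard(loop5_design, ["loop5"], codon_mode="NNK")
    assert set(oligo.target_codons) == set(range(22, 27))
    assert oligo.sequence[3 * 21 : 3 * 26] == "NNK" * 5
    parent_nt = reverse_translate(eeti.template)
    # non-degenerate backbone reproduces the parent outside targeted loops
    assert oligo.sequence[: 3 * 21] == parent_nt[: 3 * 21]
    tri = design_hard(loop5_design, ["loop5"], codon_mode="trinucleotide")
    assert all("trinucleotide" in tri.annotations[p] for p in tri.target_codons)
    untouched = design_hard(loop5_design, [], codon_mode="NNK")
    assert untouched.sequence == parent_nt


def test_scheme_loops_must_exist_on_scaffold(eeti):
    with pytest.raises(ValueError):
        LibraryDesign(eeti, RandomizationScheme({"loop9": LoopScheme("hard_nnk")}))
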