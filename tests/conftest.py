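import pytest

from dcphage import (
    LibraryDesign,
    LoopScheme,
    RandomizationScheme,
    get_scaffold,
)


@pytest.fixture(scope="session")
def eeti():
    return get_scaffold("EETI-II")


@pytest.fixture(scope="session")
def loop5_design(eeti):
    """EETI-II with loop5 hard-randomized at native length (19 aa, no Cys)."""
    return LibraryDesign(
        eeti,
        RandomizationScheme({"loop5": LoopScheme("hard_trinucleotide")}),
        name="eeti-loop5",
    )


@pytest.fixture(scope="session")
def loop1_loop5_design(eeti):
    """EETI-II with loop1 (length 6/8/10) and loop5 hard-randomized."""
    return LibraryDesign(
        eeti,
        RandomizationScheme(
            {
                "loop1": LoopScheme("hard_trinucleotide"),
                "loop5": LoopScheme("hard_trinucleotide"),
            }
        ),
        name="eeti-loop1-loop5",
    )


@pytest.fixture(scope="session")
def fixed_length_loop1_loop5_design(eeti):
    """Like loop1+loop5 but loop1 pinned at native length 6 (single length class)."""
    return LibraryDesign(
        eeti,
        RandomizationScheme(
            {
                "loop1": LoopScheme("hard_trinucleotide", lengths=frozenset({6})),
                "loop5": LoopScheme("hard_trinucleotide"),
            }
        ),
        name="eeti-loop1n-loop5",
    )
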