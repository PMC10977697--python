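"""Synthetic panning campaigns: naive library sampling, selection, sequencing.

Selection is modelled as multiplicative frequency reweighting followed by
multinomial resampling: a clone ``s`` with pre-round frequency ``F(s)``
and fitness weight ``w(s)`` has post-round frequency

    F'(s) = F(s) w(s) / sum_t F(t) w(t)

and the observed round is a multinomial sample of the sequencing depth
``D`` from ``F'``.  This is the simplest model producing the monotone
round-over-round enrichment seen in real panning data, and is what the
enrichment-score pipeline is calibrated and validated against.  There
are deliberately no PCR-bias or phage-growth terms.

Fitness weights are ``w(s) = exp(sum_i e[i, s_i])`` with additive
per-position energies, optionally multiplied by a per-sequence factor
(for clone-specific scenarios additive energies cannot express) and
gated to zero for sequences failing scaffold validation when the fold
gate is on.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .codons import STOP
from .design import LibraryDesign, positional_profiles, reverse_translate
from .scaffolds import validate_framework


class ExtinctLibraryError(RuntimeError):
    """Every clone in the pool has zero fitness weight; selection cannot proceed."""


@dataclass
class RoundCounts:
    """Clone -> read count for one selection round."""

    round_label: Union[int, str]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        t = self.total
        return {s: c / t for s, c in self.counts.items()}

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class FitnessModel:
    """Ground-truth selection model for simulated campaigns."""

    #: additive per-(position, amino-acid) energy; missing entries are 0.
    energies: dict[tuple[int, str], float] = field(default_factory=dict)
    #: clone-specific multiplicative weight factors.
    sequence_weights: dict[str, float] = field(default_factory=dict)
    #: zero out sequences that fail scaffold validation.
    fold_gate: bool = False
    design: Optional[LibraryDesign] = None

    def weight(self, seq: str) -> float:
        if self.fold_gate:
            if self.design is None:
                raise ValueError("fold_gate requires a design")
            if not validate_framework(seq, self.design.scaffold, design=self.design):
                return 0.0
        energy = 0.0
        for i, a in enumerate(seq, start=1):
            e = self.energies.get((i, a))
            if e is not None:
                if e == -math.inf:
                    return 0.0
                energy += e
        return math.exp(energy) * self.sequence_weights.get(seq, 1.0)

    @classmethod
    def neutral(cls) -> "FitnessModel":
        return cls()

    @classmethod
    def from_preferences(
        cls, preferences: Mapping[int, str], bonus: float = 2.0
    ) -> "FitnessModel":
        """Energy ``bonus`` for a preferred residue at each given position."""
        return cls(energies={(i, a): bonus for i, a in preferences.items()})

    @classmethod
    def gated(cls, parent: str, positions: Iterable[int]) -> "FitnessModel":
        """Hard gate: any non-parental residue at the positions is lethal."""
        energies: dict[tuple[int, str], float] = {}
        for i in positions:
            wt = parent[i - 1]
            for a in "ACDEFGHIKLMNPQRSTVWY":
                if a != wt:
                    energies[(i, a)] = -math.inf
        return cls(energies=energies)

    @classmethod
    def favored_clone(cls, seq: str, fold: float = 100.0) -> "FitnessModel":
        """One clone with ``fold`` times the weight of every other sequence."""
        return cls(sequence_weights={seq: fold})


@dataclass
class SelectionConfig:
    """Campaign parameters; defaults mirror a four-round panning experiment."""

    rounds: int = 4
    naive_size: int = 100_000
    depth: int = 100_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0 or self.naive_size < 1 or self.depth < 1:
            raise ValueError("rounds >= 0, naive_size >= 1, depth >= 1 required")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_naive_library(
    design: LibraryDesign,
    n: int,
    seed: Union[int, np.random.Generator] = 0,
    parent_nt: Optional[str] = None,
) -> RoundCounts:
    """Draw ``n`` displayable clones from the design's positional profiles.

    The loop-length class of each draw is uniform over the allowed
    classes; positions are sampled independently.  Stop codons never
    enter the library (a stop-containing clone cannot display): each
    position is sampled from its profile conditioned on non-stop
    outcomes, which is distributionally identical to redrawing whole
    sequences until stop-free because positions are independent.
    """
    rng = _rng(seed)
    profiles = positional_profiles(design, parent_nt=parent_nt)
    classes = list(profiles)
    per_class = rng.multinomial(n, np.full(len(classes), 1.0 / len(classes)))
    counter: Counter[str] = Counter()
    for cls, n_cls in zip(classes, per_class):
        if n_cls == 0:
            continue
        cols = []
        for prof in profiles[cls]:
            if prof.stop_probability:
                prof = prof.condition_on_sense()
            letters = sorted(prof.support)
            probs = np.array([float(prof[a]) for a in letters])
            probs /= probs.sum()
            if len(letters) == 1:
                cols.append(np.full(n_cls, letters[0], dtype="U1"))
            else:
                cols.append(rng.choice(np.array(letters, dtype="U1"), size=n_cls, p=probs))
        mat = np.stack(cols, axis=1)
        for row in mat:
            counter["".join(row)] += 1
    return RoundCounts(0, dict(counter))


def sample_nnk_walk_library(
    design: LibraryDesign,
    parent: str,
    positions: Iterable[int],
    n: int,
    seed: Union[int, np.random.Generator] = 0,
) -> RoundCounts:
    """Naive pool of an NNK-walking library: single-position variants of a parent.

    Each draw picks one walked position uniformly and a residue from the
    NNK codon profile conditioned on non-stop outcomes (the parental
    residue is reachable, so parent copies are present).  This is the
    pool shape against which per-position conservation is read out.
    """
    from .codons import NNK, codon_profile

    rng = _rng(seed)
    prof = codon_profile(NNK).condition_on_sense()
    letters = sorted(prof.support)
    probs = np.array([float(prof[a]) for a in letters])
    probs /= probs.sum()
    positions = sorted(set(positions))
    if any(not 1 <= p <= len(parent) for p in positions):
        raise ValueError("walked position outside the parent sequence")
    clones = [
        parent[: p - 1] + a + parent[p:] for p in positions for a in letters
    ]
    weights = np.tile(probs / len(positions), len(positions))
    draw = rng.multinomial(n, weights)
    counter: Counter[str] = Counter()
    for clone, c in zip(clones, draw):
        if c:
            counter[clone] += int(c)
    return RoundCounts(0, dict(counter))


def simulate_round(
    counts: RoundCounts,
    fitness: FitnessModel,
    depth: int,
    seed: Union[int, np.random.Generator] = 0,
    round_label: Union[int, str, None] = None,
) -> RoundCounts:
    """One panning round: reweight frequencies by fitness, resample at ``depth``."""
    if not counts.counts:
        raise ValueError("empty library")
    rng = _rng(seed)
    seqs = sorted(counts.counts)  # stable order for reproducibility
    f = np.array([counts.counts[s] for s in seqs], dtype=float)
    f /= f.sum()
    w = np.array([fitness.weight(s) for s in seqs])
    mass = float((f * w).sum())
    if mass == 0.0:
        raise ExtinctLibraryError("all clones have zero fitness weight")
    p = f * w / mass
    draw = rng.multinomial(depth, p)
    label = round_label if round_label is not None else (
        counts.round_label + 1 if isinstance(counts.round_label, int) else "next"
    )
    return RoundCounts(label, {s: int(c) for s, c in zip(seqs, draw) if c})


def simulate_campaign(
    design: LibraryDesign,
    fitness: FitnessModel,
    config: SelectionConfig,
    parent_nt: Optional[str] = None,
    spike_in: Optional[Mapping[str, int]] = None,
    initial: Optional[RoundCounts] = None,
) -> list[RoundCounts]:
    """Full campaign: naive library (round 0) plus ``rounds`` selection rounds.

    ``spike_in`` adds specific clones at given counts to the naive pool
    (e.g. to guarantee a rare favored clone is present before selection);
    ``initial`` replaces naive sampling with an explicit round-0 pool
    (e.g. an NNK-walking library).  Reproducible: the same config yields
    byte-identical rounds.
    """
    rng = np.random.default_rng(config.seed)
    if initial is not None:
        naive = RoundCounts(0, dict(initial.counts))
    else:
        naive = sample_naive_library(design, config.naive_size, rng, parent_nt=parent_nt)
    if spike_in:
        merged = Counter(naive.counts)
        merged.update(spike_in)
        naive = RoundCounts(0, dict(merged))
    rounds = [naive]
    for r in range(1, config.rounds + 1):
        rounds.append(
            simulate_round(rounds[-1], fitness, config.depth, rng, round_label=r)
        )
    return rounds


def emit_reads(
    counts: RoundCounts,
    design: LibraryDesign,
    error_rate: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
    quality_char: str = "I",
) -> list[tuple[str, str, str]]:
    """Sequencing reads for a round: (read id, nucleotide sequence, quality).

    Each clone is reverse-translated with the package's fixed codon
    table, replicated per count, and subjected to i.i.d. per-base
    substitution errors at ``error_rate`` (no indels, so reading frame
    and length class are preserved).  Quality strings are uniform.
    """
    rng = _rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[tuple[str, str, str]] = []
    idx = 0
    for seq in sorted(counts.counts):
        n = counts.counts[seq]
        nt = reverse_translate(seq)
        arr = np.tile(np.frombuffer(nt.encode(), dtype=np.uint8), (n, 1))
        if error_rate > 0:
            mask = rng.random(arr.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                # substitute with one of the three other bases, uniformly
                current = arr[mask]
                choice = rng.integers(0, 3, size=n_err)
                base_idx = np.searchsorted(bases, current)
                new_idx = (base_idx + 1 + choice) % 4
                arr[mask] = bases[new_idx]
        qual = quality_char * len(nt)
        strings = np.char.decode(arr.view(f"S{arr.shape[1]}").ravel(), "ascii").tolist()
        label = counts.round_label
        reads.extend(
            (f"read_{label}_{i:07d}", s, qual) for i, s in enumerate(strings, start=idx)
        )
        idx += n
    return reads
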