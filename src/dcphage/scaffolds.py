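"""Registry of disulfide-constrained peptide (DCP) scaffolds.

A scaffold is a peptide template whose fold is pinned by a fixed framework
of cysteines (three disulfides for cystine-knot peptides, two for CBD).
The residues between framework cysteines form surface loops that phage
display libraries randomize.  This module houses the seven built-in
scaffold definitions and validates candidate clone sequences against
them.

Positions are 1-based inclusive on the mature displayed peptide, which is
how individual residues (e.g. ``Ile3``, ``Glu22``) are referred to
throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Literal, NamedTuple, Optional

import yaml

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Character class for a randomized loop residue (cysteine excluded:
#: loops may not introduce extra cysteines without breaking the fold).
_NON_CYS = "".join(a for a in AA20 if a != "C")

ValidationMode = Literal["strict", "cys_only"]


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside the 20-letter amino-acid code."""


class FrameworkError(ValueError):
    """Sequence cannot be anchored onto the scaffold's cysteine framework."""


class ValidationResult(NamedTuple):
    ok: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:  # truthiness mirrors the verdict
        return self.ok


class Segment(NamedTuple):
    """One piece of the template partition: ``kind`` is ``cys`` | ``fixed`` | ``loop``."""

    kind: str
    name: Optional[str]
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass(frozen=True)
class Scaffold:
    """A DCP scaffold: template sequence, cysteine framework and loop map."""

    name: str
    template: str
    loops: dict[str, tuple[int, int]]
    allowed_loop_lengths: dict[str, frozenset[int]]
    display: str = "p8"
    aliases: tuple[str, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        _check_alphabet(self.template)
        covered: set[int] = set()
        for loop, (s, e) in self.loops.items():
            if not (1 <= s <= e <= len(self.template)):
                raise ValueError(f"{self.name}: loop {loop} interval {s}-{e} outside template")
            span = set(range(s, e + 1))
            if span & covered:
                raise ValueError(f"{self.name}: loop {loop} overlaps another loop")
            if span & set(self.cys_positions):
                raise ValueError(f"{self.name}: loop {loop} contains a framework cysteine")
            covered |= span
            native = e - s + 1
            if native not in self.allowed_loop_lengths.get(loop, frozenset()):
                raise ValueError(f"{self.name}: loop {loop} native length {native} not in allowed set")

    @property
    def cys_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, a in enumerate(self.template) if a == "C")

    @property
    def length(self) -> int:
        return len(self.template)

    def loop_sequence(self, loop: str) -> str:
        s, e = self.loops[loop]
        return self.template[s - 1 : e]

    def native_loop_length(self, loop: str) -> int:
        s, e = self.loops[loop]
        return e - s + 1

    def segments(self) -> list[Segment]:
        """Ordered partition of the template into cys / fixed / loop segments."""
        loop_at = {s: (name, e) for name, (s, e) in self.loops.items()}
        out: list[Segment] = []
        i = 1
        while i <= len(self.template):
            if i in loop_at:
                name, e = loop_at[i]
                out.append(Segment("loop", name, i, e))
                i = e + 1
            elif self.template[i - 1] == "C":
                out.append(Segment("cys", None, i, i))
                i += 1
            else:
                j = i
                while (
                    j + 1 <= len(self.template)
                    and self.template[j] != "C"
                    and (j + 1) not in loop_at
                ):
                    j += 1
                out.append(Segment("fixed", None, i, j))
                i = j + 1
        return out

    @property
    def fixed_regions(self) -> tuple[tuple[int, int], ...]:
        return tuple((s.start, s.end) for s in self.segments() if s.kind == "fixed")

    def pattern(self, loop_lengths: Optional[dict[str, frozenset[int]]] = None) -> re.Pattern:
        """Anchored regex matching any sequence compatible with the framework.

        Loop content is free (any non-Cys residue) but loop lengths are
        restricted to the allowed set; fixed segments and cysteines must
        match the template exactly.
        """
        lengths = dict(self.allowed_loop_lengths)
        if loop_lengths:
            lengths.update(loop_lengths)
        parts = ["^"]
        for seg in self.segments():
            text = self.template[seg.start - 1 : seg.end]
            if seg.kind == "cys":
                parts.append("C")
            elif seg.kind == "fixed":
                parts.append(re.escape(text))
            else:
                alts = "|".join(
                    f"[{_NON_CYS}]{{{n}}}" for n in sorted(lengths[seg.name])
                )
                parts.append(f"(?P<{seg.name}>{alts})")
        parts.append("$")
        return re.compile("".join(parts))


@dataclass
class LoopAssignment:
    """Concrete loop contents extracted from one clone sequence."""

    scaffold: Scaffold
    sequence: str
    loops: dict[str, str]
    #: Ordered (kind, name, text) parts covering the whole clone sequence.
    parts: list[tuple[str, Optional[str], str]] = field(default_factory=list)

    @property
    def loop_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.loops.items()}

    def reassemble(self) -> str:
        """Concatenate parts in template order; reproduces the input exactly."""
        return "".join(text for _, _, text in self.parts)


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set(AA20)
    if bad:
        raise InvalidAlphabetError(
            f"non-amino-acid characters {sorted(bad)!r} in sequence"
        )


def _load_registry() -> list[Scaffold]:
    text = resources.files("dcphage.data").joinpath("scaffolds.yaml").read_text()
    raw = yaml.safe_load(text)
    out = []
    for rec in raw["scaffolds"]:
        out.append(
            Scaffold(
                name=rec["name"],
                template=rec["template"],
                loops={k: tuple(v) for k, v in rec["loops"].items()},
                allowed_loop_lengths={
                    k: frozenset(v) for k, v in rec["allowed_loop_lengths"].items()
                },
                display=rec.get("display", "p8"),
                aliases=tuple(rec.get("aliases", ())),
                notes=rec.get("notes", ""),
            )
        )
    return out


@lru_cache(maxsize=1)
def builtin_scaffolds() -> tuple[Scaffold, ...]:
    """The seven built-in DCP scaffolds shipped with the package."""
    return tuple(_load_registry())


def get_scaffold(name: str) -> Scaffold:
    """Look a scaffold up by name or alias (case-insensitive)."""
    key = name.strip().lower()
    for sc in builtin_scaffolds():
        if key == sc.name.lower() or key in (a.lower() for a in sc.aliases):
            return sc
    known = ", ".join(sc.name for sc in builtin_scaffolds())
    raise KeyError(f"unknown scaffold {name!r}; built-ins: {known}")


def validate_framework(
    seq: str,
    scaffold: Scaffold,
    design=None,
    mode: ValidationMode = "strict",
) -> ValidationResult:
    """Check a clone sequence against a scaffold framework.

    ``strict`` requires the full framework: every cysteine in the
    template's inter-cysteine topology, fixed regions identical to the
    template, and each loop length within the allowed set (the set is
    taken from ``design`` when supplied, else from the scaffold).

    ``cys_only`` checks only that the cysteine framework is intact: same
    number of cysteines, and internal segments that are empty in the
    template (adjacent Cys-Cys) are empty in the clone and vice versa.
    This is the "intact sequence containing all cysteines" criterion used
    for hit triage, and is the right mode for affinity-maturation clones
    whose formerly fixed regions were intentionally mutated.
    """
    if not seq:
        return ValidationResult(False, "empty sequence")
    _check_alphabet(seq)

    if mode == "cys_only":
        t_parts = scaffold.template.split("C")
        s_parts = seq.split("C")
        if len(s_parts) != len(t_parts):
            return ValidationResult(
                False,
                f"missing framework cysteine ({len(s_parts) - 1} found, "
                f"{len(t_parts) - 1} expected)",
            )
        # internal empty segments mark adjacent cysteines (knot topology)
        for i, (tp, sp) in enumerate(zip(t_parts, s_parts)):
            internal = 0 < i < len(t_parts) - 1
            if internal and (len(tp) == 0) != (len(sp) == 0):
                return ValidationResult(False, "cysteine spacing breaks framework topology")
        return ValidationResult(True)

    if mode != "strict":
        raise ValueError(f"unknown validation mode {mode!r}")

    loop_lengths = None
    if design is not None:
        loop_lengths = design.loop_length_sets()
    if scaffold.pattern(loop_lengths).match(seq):
        return ValidationResult(True)
    # diagnose the most informative failure
    if seq.count("C") != len(scaffold.cys_positions):
        return ValidationResult(False, "missing framework cysteine")
    cys_ok = validate_framework(seq, scaffold, mode="cys_only")
    if not cys_ok:
        return ValidationResult(False, cys_ok.reason)
    return ValidationResult(False, "fixed region or loop length mismatch")


def extract_loops(
    scaffold: Scaffold,
    seq: str,
    design=None,
    mode: ValidationMode = "strict",
) -> LoopAssignment:
    """Extract each loop's residues from a clone sequence.

    In ``strict`` mode the clone must match the full framework regex; in
    ``cys_only`` mode the clone is split at its cysteines and each
    inter-cysteine segment is mapped onto the corresponding template
    segment (fixed anchor residues inside a segment, e.g. AVR9 Val19, are
    assigned to the framework, the remainder to the loop).
    """
    _check_alphabet(seq)
    if mode == "strict":
        loop_lengths = design.loop_length_sets() if design is not None else None
        m = scaffold.pattern(loop_lengths).match(seq)
        if not m:
            verdict = validate_framework(seq, scaffold, design=design, mode="strict")
            raise FrameworkError(
                f"sequence does not fit {scaffold.name} framework: {verdict.reason}"
            )
        parts: list[tuple[str, Optional[str], str]] = []
        pos = 0
        for seg in scaffold.segments():
            if seg.kind == "loop":
                text = m.group(seg.name)
            else:
                text = scaffold.template[seg.start - 1 : seg.end]
            parts.append((seg.kind, seg.name, text))
            pos += len(text)
        loops = {s.name: m.group(s.name) for s in scaffold.segments() if s.kind == "loop"}
        return LoopAssignment(scaffold, seq, loops, parts)

    verdict = validate_framework(seq, scaffold, mode="cys_only")
    if not verdict:
        raise FrameworkError(f"sequence does not fit {scaffold.name} framework: {verdict.reason}")
    t_segments = _inter_cys_segments(scaffold)
    s_parts = seq.split("C")
    parts = []
    loops = {}
    for seg_list, observed in zip(t_segments, s_parts):
        consumed = _assign_segment(seg_list, observed, scaffold)
        for kind, name, text in consumed:
            parts.append((kind, name, text))
            if kind == "loop":
                loops[name] = text
        parts.append(("cys", None, "C"))
    parts.pop()  # no trailing cysteine after the final segment
    return LoopAssignment(scaffold, seq, loops, parts)


def _inter_cys_segments(scaffold: Scaffold) -> list[list[Segment]]:
    """Group non-cys segments by the inter-cysteine region they fall in."""
    groups: list[list[Segment]] = [[]]
    for seg in scaffold.segments():
        if seg.kind == "cys":
            groups.append([])
        else:
            groups[-1].append(seg)
    return groups


def _assign_segment(
    seg_list: list[Segment], observed: str, scaffold: Scaffold
) -> list[tuple[str, Optional[str], str]]:
    """Distribute one observed inter-cys stretch over the template segments.

    Fixed anchors keep their template length (variable-length loops absorb
    any length difference); a stretch where the template has no segments
    (clone overhang) is kept as an ``extra`` part so reassembly is exact.
    """
    if not seg_list:
        return [("extra", None, observed)] if observed else []
    out = []
    fixed_len = sum(
        s.end - s.start + 1 for s in seg_list if s.kind == "fixed"
    )
    spare = len(observed) - fixed_len
    i = 0
    n_loops = sum(1 for s in seg_list if s.kind == "loop")
    for seg in seg_list:
        native = seg.end - seg.start + 1
        if seg.kind == "fixed":
            take = min(native, len(observed) - i)
        else:
            take = max(0, spare // n_loops) if n_loops > 1 else max(0, spare)
        out.append((seg.kind, seg.name, observed[i : i + take]))
        i += take
    if i < len(observed):  # remainder goes to the last loop (or as overhang)
        tail = observed[i:]
        for k in range(len(out) - 1, -1, -1):
            if out[k][0] == "loop":
                out[k] = (out[k][0], out[k][1], out[k][2] + tail)
                break
        else:
            out.append(("extra", None, tail))
    return out
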