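"""Enrichment-score analysis of panning NGS data.

The central statistic compares an amino acid's positional frequency in
the sorted pool (``F1``) with its frequency in the unsorted pool
(``F0``):

    ES = (F1 - F0) / (1 - F0)   if F1 > F0   (enrichment)
    ES = (F1 - F0) / F0         if F1 < F0   (de-enrichment)
    ES = 0                      if F1 = F0   (including F1 = F0 = 0)

so every value lies in [-1, 1]; -1 means complete de-enrichment (the
residue vanished from the sorted pool) and +1 complete takeover.  The
position x amino-acid ES matrix is rendered as a blue-white-red heatmap
(blue at -1, white at 0, red at +1).

Reads are stratified by length class before any frequency computation:
sequences of different loop-length classes occupy different position
registers and must never be pooled (no alignment is performed; library
positions are structurally fixed and the reading frame is frame 0 by
construction of the amplicons).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .codons import STANDARD_CODE, STOP
from .design import LibraryDesign, translate
from .scaffolds import AA20, validate_framework
from .simulate import RoundCounts

_NT_ALPHABET = set("ACGTN")


@dataclass
class CloneRecord:
    """One unique amino-acid sequence observed in one round."""

    sequence: str
    count: int
    round_label: Union[int, str] = 0
    valid: bool = True
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class FrequencyMatrix:
    """Positions (1-based rows) x 20 amino acids (columns) -> fraction."""

    values: pd.DataFrame
    length: int
    total: int

    def __post_init__(self) -> None:
        if self.total > 0:
            sums = self.values.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("each position's fractions must sum to 1")


@dataclass
class ESMatrix:
    """Positions x amino acids -> enrichment score, in [-1, 1].

    Orientation note: when plotted, positions run along the x-axis and
    the 20 amino acids along the y-axis.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.nanmin(v) < -1 - 1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("ES values must lie in [-1, 1]")


def _looks_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= _NT_ALPHABET


def translate_and_filter(
    reads: Iterable,
    design: LibraryDesign,
    round_label: Union[int, str] = 0,
) -> list[CloneRecord]:
    """Translate reads, validate against the design, aggregate per clone.

    ``reads`` may be nucleotide or amino-acid sequences (plain strings,
    ``(id, seq, qual)`` tuples, or Biopython ``SeqRecord`` objects) but
    not a mixture of both.  Records are rejected — kept, flagged invalid,
    with a reason — for internal stop codons, lengths outside the
    design's allowed length classes, and framework-cysteine failures.
    """
    seqs: list[str] = []
    for r in reads:
        if isinstance(r, str):
            seqs.append(r.upper())
        elif isinstance(r, tuple):
            seqs.append(r[1].upper())
        else:  # SeqRecord-like
            seqs.append(str(r.seq).upper())
    if not seqs:
        return []
    nt_flags = {_looks_nucleotide(s) for s in seqs}
    if len(nt_flags) > 1:
        raise ValueError("mixed nucleotide and protein input")
    is_nt = nt_flags.pop()

    raw = Counter(seqs)
    allowed = design.allowed_total_lengths()
    aggregated: dict[tuple[str, bool, Optional[str]], int] = {}
    for seq, n in raw.items():
        if is_nt:
            if len(seq) % 3:
                _tally(aggregated, seq, n, False, "length not a multiple of 3")
                continue
            if "N" in seq:
                _tally(aggregated, seq, n, False, "ambiguous base")
                continue
            aa = translate(seq)
        else:
            aa = seq
        if STOP in aa:
            _tally(aggregated, aa, n, False, "stop codon")
            continue
        if len(aa) not in allowed:
            _tally(aggregated, aa, n, False, f"length {len(aa)} not in allowed classes")
            continue
        verdict = validate_framework(aa, design.scaffold, design=design)
        if not verdict:
            _tally(aggregated, aa, n, False, verdict.reason)
            continue
        _tally(aggregated, aa, n, True, None)
    return [
        CloneRecord(seq, n, round_label, valid, reason)
        for (seq, valid, reason), n in sorted(aggregated.items(), key=lambda kv: kv[0][0])
    ]


def _tally(agg, seq, n, valid, reason) -> None:
    key = (seq, valid, reason)
    agg[key] = agg.get(key, 0) + n


def position_frequencies(
    records: Sequence[CloneRecord],
    length: Optional[int] = None,
    weighting: Literal["count", "unique"] = "count",
) -> FrequencyMatrix:
    """Per-position amino-acid fractions from valid records of one length class.

    ``count`` weighting (default) weights each clone by its read count;
    ``unique`` counts each distinct clone once.
    """
    valid = [r for r in records if r.valid]
    if length is not None:
        valid = [r for r in valid if len(r.sequence) == length]
    else:
        lengths = {len(r.sequence) for r in valid}
        if len(lengths) > 1:
            raise ValueError(
                f"records span multiple length classes {sorted(lengths)}; "
                "pass an explicit length to stratify"
            )
        length = lengths.pop() if lengths else None
    if not valid or length is None:
        raise ValueError("no valid records in the requested length class")

    counts = np.zeros((length, len(AA20)))
    aa_index = {a: j for j, a in enumerate(AA20)}
    total = 0
    for r in valid:
        w = r.count if weighting == "count" else 1
        total += w
        for i, a in enumerate(r.sequence):
            counts[i, aa_index[a]] += w
    values = pd.DataFrame(
        counts / total, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list(AA20),
    )
    return FrequencyMatrix(values, length, total)


def enrichment_score(f0: float, f1: float) -> float:
    """Piecewise enrichment score for one (position, amino acid) cell."""
    if not (0 <= f0 <= 1) or not (0 <= f1 <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if f1 == f0:
        return 0.0
    if f1 > f0:
        return (f1 - f0) / (1 - f0)
    return (f1 - f0) / f0


def es_matrix(f_unsorted: FrequencyMatrix, f_sorted: FrequencyMatrix) -> ESMatrix:
    """Elementwise enrichment score of sorted vs unsorted frequency matrices."""
    if f_unsorted.length != f_sorted.length:
        raise ValueError(
            f"length classes differ ({f_unsorted.length} vs {f_sorted.length}); "
            "cross-class comparison is refused"
        )
    f0 = f_unsorted.values.to_numpy()
    f1 = f_sorted.values.to_numpy()
    out = np.zeros_like(f0)
    up = f1 > f0
    down = f1 < f0
    out[up] = (f1[up] - f0[up]) / (1 - f0[up])
    out[down] = (f1[down] - f0[down]) / f0[down]
    return ESMatrix(pd.DataFrame(out, index=f_unsorted.values.index, columns=f_unsorted.values.columns))


def export_heatmap(es: ESMatrix, path: Union[str, Path]) -> tuple[Path, Path]:
    """Write the ES table as CSV (bit-exact source of truth) and a heatmap image.

    The image uses a diverging blue-white-red scale anchored at
    -1 / 0 / +1, positions on the x-axis, amino acids on the y-axis.
    Returns ``(csv_path, png_path)``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = Path(path)
    csv_path = base.with_suffix(".csv")
    png_path = base.with_suffix(".png")
    es.values.to_csv(csv_path)

    grid = es.values.T  # amino acids on y, positions on x
    fig, ax = plt.subplots(figsize=(max(4.0, 0.3 * len(es.values)), 5.0))
    im = ax.imshow(grid.to_numpy(), cmap="bwr", vmin=-1.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(len(grid.columns)), [str(p) for p in grid.columns], fontsize=6)
    ax.set_yticks(range(len(grid.index)), list(grid.index), fontsize=6)
    ax.set_xlabel("position")
    ax.set_ylabel("amino acid")
    fig.colorbar(im, ax=ax, label="enrichment score")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return csv_path, png_path


def read_es_csv(path: Union[str, Path]) -> ESMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "position"
    return ESMatrix(df)


def rank_clones(rounds: Sequence[Union[RoundCounts, Sequence[CloneRecord]]]) -> pd.DataFrame:
    """Per-round fractions and final-round ranking of every clone.

    Accepts simulator ``RoundCounts`` or lists of ``CloneRecord`` (only
    valid records contribute).  Returns a DataFrame indexed by sequence
    with one ``round_<label>`` fraction column per round plus ``rank``
    (1 = most abundant in the final round; ties broken lexicographically
    by sequence).
    """
    if not rounds:
        raise ValueError("at least one round required")
    tables: list[tuple[Union[int, str], dict[str, float]]] = []
    for rd in rounds:
        if isinstance(rd, RoundCounts):
            tables.append((rd.round_label, rd.frequencies()))
        else:
            counts = Counter()
            label = 0
            for rec in rd:
                if rec.valid:
                    counts[rec.sequence] += rec.count
                label = rec.round_label
            total = sum(counts.values())
            tables.append((label, {s: c / total for s, c in counts.items()}))
    all_seqs = sorted(set().union(*(t[1] for t in tables)))
    data = {
        f"round_{label}": [freqs.get(s, 0.0) for s in all_seqs]
        for label, freqs in tables
    }
    df = pd.DataFrame(data, index=pd.Index(all_seqs, name="sequence"))
    final = df.columns[-1]
    df = df.sort_values([final, "sequence"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def conserved_positions(
    es: ESMatrix,
    parent: str,
    tau: float = 0.8,
) -> set[int]:
    """Positions where every observed non-parental residue is strongly depleted.

    A position is conserved when every non-parent amino acid with a
    non-zero ES has ES <= -tau and at least one such residue exists.
    Cells with ES exactly 0 are treated as unobserved (the 0/0
    convention): residues absent from both pools — e.g. Cys under a
    19-amino-acid mixture, or anything at a non-randomized position —
    carry no evidence either way.
    """
    if len(parent) != len(es.values):
        raise ValueError("parent length does not match the ES matrix")
    out: set[int] = set()
    for pos in es.values.index:
        wt = parent[pos - 1]
        row = es.values.loc[pos]
        observed = [a for a in row.index if a != wt and row[a] != 0.0]
        if observed and all(row[a] <= -tau for a in observed):
            out.add(pos)
    return out


@dataclass
class LogoMatrix:
    """Positions x amino acids -> letter height for a sequence logo."""

    values: pd.DataFrame
    mode: Literal["frequency", "information_bits"]


def logo_matrix(
    source: Union[Sequence[CloneRecord], FrequencyMatrix],
    mode: Literal["frequency", "information_bits"] = "information_bits",
    weighting: Literal["count", "unique"] = "count",
) -> LogoMatrix:
    """Sequence-logo letter heights from aligned clones of one length class.

    ``frequency`` mode reports the raw fractions; ``information_bits``
    scales each position's fractions by its information content
    ``log2(20) - H(i)`` (Shannon entropy in bits), the classic logo
    height.  No small-sample correction is applied.
    """
    if isinstance(source, FrequencyMatrix):
        freq = source
    else:
        freq = position_frequencies(source, weighting=weighting)
    f = freq.values
    if mode == "frequency":
        return LogoMatrix(f.copy(), mode)
    if mode != "information_bits":
        raise ValueError(f"unknown logo mode {mode!r}")
    arr = f.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(arr > 0, arr * np.log2(arr), 0.0)
    entropy = -plogp.sum(axis=1)
    info = math.log2(20) - entropy
    return LogoMatrix(f.mul(info, axis=0), mode)


# crude chemistry-based coloring for logo letters
_LOGO_COLORS = {
    **{a: "tab:green" for a in "STNQ"},
    **{a: "tab:blue" for a in "KRH"},
    **{a: "tab:red" for a in "DE"},
    **{a: "black" for a in "AVLIMFWPG"},
    "C": "goldenrod", "Y": "tab:green",
}


def render_logo(logo: LogoMatrix, path: Union[str, Path]) -> Path:
    """Draw a sequence logo (stacked scaled letters) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    path = Path(path)
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    fig, ax = plt.subplots(figsize=(max(4.0, 0.4 * len(logo.values)), 2.5))
    for x, (pos, row) in enumerate(logo.values.iterrows()):
        y = 0.0
        for aa, h in sorted(row.items(), key=lambda kv: kv[1]):
            if h <= 0:
                continue
            tp = TextPath((0, 0), aa, size=1.0, prop=fp)
            bbox = tp.get_extents()
            scale = Affine2D().translate(-bbox.x0, -bbox.y0).scale(
                0.9 / bbox.width, h / bbox.height
            ).translate(x + 0.05, y)
            ax.add_patch(PathPatch(scale.transform_path(tp),
                                   facecolor=_LOGO_COLORS.get(aa, "black"), edgecolor="none"))
            y += h
    ax.set_xlim(0, len(logo.values))
    top = math.log2(20) if logo.mode == "information_bits" else 1.0
    ax.set_ylim(0, top)
    ax.set_xticks([i + 0.5 for i in range(len(logo.values))],
                  [str(p) for p in logo.values.index], fontsize=6)
    ax.set_ylabel("bits" if logo.mode == "information_bits" else "frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
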