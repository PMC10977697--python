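"""File formats, run configuration and reproducibility manifests.

FASTA/FASTQ go through Biopython; clone-count tables, ES matrices and
campaign summaries are plain CSV (comma-separated, UTF-8, header row
required).  Every CLI run writes a JSON manifest with the package
version, the full configuration and the seed, sufficient to reproduce
deterministic outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import RoundCounts


class FormatError(ValueError):
    """Malformed record in an input file; message carries the line number."""


def read_fasta(path: Union[str, Path]) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable, path: Union[str, Path]) -> Path:
    path = Path(path)
    recs = []
    for r in records:
        if isinstance(r, SeqRecord):
            recs.append(r)
        else:
            name, seq = r
            recs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")
    return path


def read_fastq(path: Union[str, Path]) -> list[SeqRecord]:
    """Sanger-quality FASTQ reader (quality parsed but unused by default)."""
    return list(SeqIO.parse(str(path), "fastq"))


def write_fastq(reads: Iterable[tuple[str, str, str]], path: Union[str, Path]) -> Path:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            if len(seq) != len(qual):
                raise FormatError(f"{name}: quality length differs from sequence length")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


def read_clone_counts_csv(path: Union[str, Path]) -> list[RoundCounts]:
    """Pre-tabulated clone counts: columns ``sequence, count, round``."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sequence", "count", "round"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: header must contain {sorted(required)}")
    rounds = []
    for label, grp in df.groupby("round", sort=True):
        counts: dict[str, int] = {}
        for line, row in enumerate(grp.itertuples(index=True), start=2):
            if not isinstance(row.sequence, str) or not row.sequence:
                raise FormatError(f"{path}: line {row.Index + 2}: empty sequence")
            if row.count < 0:
                raise FormatError(f"{path}: line {row.Index + 2}: negative count")
            counts[row.sequence] = counts.get(row.sequence, 0) + int(row.count)
        rounds.append(RoundCounts(label, counts))
    return rounds


def write_clone_counts_csv(rounds: Sequence[RoundCounts], path: Union[str, Path]) -> Path:
    rows = [
        {"sequence": s, "count": c, "round": rd.round_label}
        for rd in rounds
        for s, c in sorted(rd.counts.items())
    ]
    pd.DataFrame(rows, columns=["sequence", "count", "round"]).to_csv(path, index=False)
    return Path(path)


@dataclass
class RunConfig:
    """Pipeline configuration; see the CLI subcommands for which fields apply."""

    output_dir: str = "."
    scaffold: str = "EETI-II"
    design_name: str = ""
    # thresholds
    signal_threshold: float = 0.3
    sn_threshold: float = 2.0
    tau: float = 0.8
    # simulator
    rounds: int = 4
    naive_size: int = 100_000
    depth: int = 100_000
    error_rate: float = 0.0
    seed: int = 0
    # analysis
    weighting: str = "count"
    logo_mode: str = "information_bits"

    def __post_init__(self) -> None:
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in [0, 1]")
        if self.weighting not in {"count", "unique"}:
            raise ValueError("weighting must be 'count' or 'unique'")
        if self.logo_mode not in {"frequency", "information_bits"}:
            raise ValueError("logo_mode must be 'frequency' or 'information_bits'")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise KeyError(f"invalid config keys: {sorted(bad)}")
        return cls(**raw)


def write_manifest(
    out_dir: Union[str, Path],
    command: str,
    config: dict,
    seed: Optional[int] = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "dcphage",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
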