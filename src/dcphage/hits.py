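"""ELISA hit calling and selection-campaign tabulation.

Primary hits from spot phage ELISA are called positive when the clone's
sequence carries an intact cysteine framework, the raw ELISA signal
reaches the signal threshold (default 0.3 absorbance units) and the
signal-to-noise ratio — target signal over the BSA background signal —
exceeds 2.  Unique positive clones are tabulated per scaffold x target
to give per-scaffold totals and hit rates, and SPR follow-up of
synthesized peptides is summarized as a confirmation rate.

The signal threshold is applied inclusively (>= 0.3): the selected-hit
tables include a clone with an ELISA signal of exactly 0.3, so a strict
"above 0.3" reading would contradict the published hit list.  The
comparison is configurable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from numbers import Real
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .scaffolds import Scaffold, ValidationMode, get_scaffold, validate_framework

KdValue = Union[float, str, None]


@dataclass
class ElisaRecord:
    """One spot-ELISA measurement of a clone against a target."""

    clone: str
    scaffold: str
    target: str
    sequence: str
    signal_target: Optional[float] = None
    signal_bsa: Optional[float] = None
    sn: Optional[float] = None          # precomputed ratio, if BSA signal unavailable
    kd: KdValue = None                  # µM; float, bound string like ">20", or "n/d"

    def __post_init__(self) -> None:
        for v in (self.signal_target, self.signal_bsa):
            if v is not None and v < 0:
                raise ValueError("signals must be non-negative")


def signal_to_noise(rec: ElisaRecord) -> float:
    """Target signal over BSA background signal."""
    if rec.signal_bsa is not None:
        if rec.signal_bsa == 0:
            raise ZeroDivisionError(
                f"{rec.clone}: BSA background signal is zero; S/N undefined"
            )
        if rec.signal_target is None:
            raise ValueError(f"{rec.clone}: missing target signal")
        return rec.signal_target / rec.signal_bsa
    if rec.sn is not None:
        return rec.sn
    raise ValueError(f"{rec.clone}: neither BSA signal nor precomputed S/N available")


def call_positive(
    rec: ElisaRecord,
    scaffold: Optional[Scaffold] = None,
    signal_threshold: float = 0.3,
    sn_threshold: float = 2.0,
    signal_inclusive: bool = True,
    validation_mode: ValidationMode = "cys_only",
) -> tuple[bool, list[str]]:
    """Positivity call with the list of failed criteria.

    Positive requires: scaffold validation (default ``cys_only`` — the
    intact-cysteine criterion used for hit triage), ELISA signal meeting
    the signal threshold, and S/N strictly above the S/N threshold.
    """
    if not rec.sequence:
        raise ValueError(f"{rec.clone}: sequence required for a positivity call")
    sc = scaffold or get_scaffold(rec.scaffold)
    reasons: list[str] = []
    verdict = validate_framework(rec.sequence, sc, mode=validation_mode)
    if not verdict:
        reasons.append(f"invalid scaffold ({verdict.reason})")
    signal = rec.signal_target
    if signal is None:
        reasons.append("missing ELISA signal")
    else:
        ok = signal >= signal_threshold if signal_inclusive else signal > signal_threshold
        if not ok:
            reasons.append(f"signal {signal} below threshold {signal_threshold}")
    sn = signal_to_noise(rec)
    if not sn > sn_threshold:
        reasons.append(f"S/N {sn} not above {sn_threshold}")
    return (not reasons, reasons)


@dataclass
class HitTable:
    """ELISA records with computed S/N and positivity flags."""

    records: list[ElisaRecord]
    positive: list[bool]
    reasons: list[list[str]]

    @classmethod
    def from_records(cls, records: Iterable[ElisaRecord], **thresholds) -> "HitTable":
        records = list(records)
        flags, reasons = [], []
        for r in records:
            ok, why = call_positive(r, **thresholds)
            flags.append(ok)
            reasons.append(why)
        return cls(records, flags, reasons)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, ok, why in zip(self.records, self.positive, self.reasons):
            rows.append(
                {
                    "clone": r.clone, "scaffold": r.scaffold, "target": r.target,
                    "sequence": r.sequence, "signal": r.signal_target,
                    "sn": signal_to_noise(r), "positive": ok,
                    "reasons": "; ".join(why),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CampaignSummary:
    """Unique positive clone counts per scaffold x target, with hit rates."""

    counts: pd.DataFrame            # targets (rows) x scaffolds (columns)
    targets_screened: dict[str, list[str]]

    @property
    def scaffold_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def hit_rate(self, scaffold: str) -> tuple[int, int]:
        screened = self.targets_screened[scaffold]
        hits = int((self.counts.loc[screened, scaffold] >= 1).sum())
        return hits, len(screened)

    def hit_rate_fraction(self, scaffold: str) -> float:
        h, n = self.hit_rate(scaffold)
        return h / n

    @property
    def overall_success(self) -> tuple[int, int]:
        """Targets with at least one hit from any scaffold, over targets screened."""
        all_targets = sorted({t for ts in self.targets_screened.values() for t in ts})
        hit = int((self.counts.loc[all_targets].sum(axis=1) >= 1).sum())
        return hit, len(all_targets)

    @property
    def overall_success_fraction(self) -> float:
        h, n = self.overall_success
        return h / n

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: targets as rows, scaffolds as columns, plus totals."""
        df = self.counts.copy()
        df.loc["total"] = self.scaffold_totals
        return df


def tabulate(
    hits: HitTable,
    targets_screened: Optional[Mapping[str, Sequence[str]]] = None,
) -> CampaignSummary:
    """Count unique positive clones per scaffold x target.

    Uniqueness is exact amino-acid sequence identity within a
    scaffold x target cell (no clustering of near-duplicates).  When
    ``targets_screened`` is omitted, every scaffold is assumed screened
    against the union of targets present in the table.
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for rec, ok in zip(hits.records, hits.positive):
        if not ok:
            continue
        seen.setdefault((rec.target, rec.scaffold), set()).add(rec.sequence)
    targets = sorted({r.target for r in hits.records})
    scaffolds = sorted({r.scaffold for r in hits.records})
    if targets_screened is None:
        targets_screened = {sc: targets for sc in scaffolds}
    else:
        targets_screened = {sc: list(ts) for sc, ts in targets_screened.items()}
        scaffolds = sorted(set(scaffolds) | set(targets_screened))
        targets = sorted(set(targets) | {t for ts in targets_screened.values() for t in ts})
    counts = pd.DataFrame(0, index=targets, columns=scaffolds)
    for (t, sc), seqs in seen.items():
        counts.loc[t, sc] = len(seqs)
    full = {sc: targets_screened.get(sc, targets) for sc in scaffolds}
    return CampaignSummary(counts, full)


def summarize_counts(
    counts: pd.DataFrame,
    targets_screened: Optional[Mapping[str, Sequence[str]]] = None,
) -> CampaignSummary:
    """CampaignSummary from an already-aggregated unique-clone count matrix."""
    counts = counts.astype(int)
    if targets_screened is None:
        targets_screened = {sc: list(counts.index) for sc in counts.columns}
    return CampaignSummary(counts, {sc: list(ts) for sc, ts in targets_screened.items()})


def parse_kd(value: KdValue) -> tuple[bool, Optional[float]]:
    """Interpret a Kd field: (confirmed binder?, numeric value or None).

    Numeric entries and bound strings (``">20"``) are confirmed binders;
    bounds carry no numeric value for statistics.  ``"n/d"``, empty and
    missing entries are unconfirmed.
    """
    if value is None:
        return False, None
    if isinstance(value, Real) and not isinstance(value, bool):
        v = float(value)
        if math.isnan(v):
            return False, None
        return True, v
    text = str(value).strip()
    if text == "" or text.lower() in {"n/d", "nd", "na", "n/a"}:
        return False, None
    if text.startswith(">") or text.startswith("<"):
        try:
            float(text[1:].strip())
        except ValueError:
            raise ValueError(f"unparseable Kd bound {value!r}") from None
        return True, None
    try:
        return True, float(text)
    except ValueError:
        raise ValueError(f"unparseable Kd value {value!r}") from None


def confirmation_rate(
    records: Iterable[Union[ElisaRecord, KdValue]],
) -> tuple[int, int, int]:
    """(confirmed, total, percent) of clones whose synthetic peptide bound by SPR."""
    confirmed = total = 0
    for r in records:
        kd = r.kd if isinstance(r, ElisaRecord) else r
        ok, _ = parse_kd(kd)
        total += 1
        confirmed += ok
    pct = round(100 * confirmed / total) if total else 0
    return confirmed, total, pct


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("dcphage.data").joinpath(name).read_text()


def load_unique_clone_counts() -> pd.DataFrame:
    """Published unique-positive-clone counts per target (rows) x scaffold (columns)."""
    df = pd.read_csv(io.StringIO(_data_text("unique_clone_counts.csv")), index_col="target")
    return df.astype(int)


def load_primary_hits() -> list[ElisaRecord]:
    """Selected primary hits (sequence, ELISA signal, S/N, SPR Kd) across scaffolds."""
    df = pd.read_csv(io.StringIO(_data_text("primary_hits.csv")), dtype={"kd_um": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ElisaRecord(
                clone=row.clone, scaffold=row.scaffold, target=row.target,
                sequence=row.sequence, signal_target=float(row.elisa_signal),
                sn=float(row.sn_ratio), kd=row.kd_um,
            )
        )
    return out


def load_maturation_hits() -> pd.DataFrame:
    """Affinity-maturation lineages of the anti-Notch2 clones (sequence, ELISA, Kd)."""
    return pd.read_csv(io.StringIO(_data_text("maturation_hits.csv")), dtype={"kd_um": str})
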