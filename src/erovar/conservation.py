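"""Natural-occurrence background from a reference-anchored ortholog alignment.

An ortholog alignment holds, for each ortholog, one residue symbol per
reference protein position (gap '-' where the ortholog lacks the position).
From it we build a per-position conservation profile (residue and gap
counts), report mutant/wild-type occurrence percentages, and classify a
substitution as naturally occurring when the mutant residue is present in at
least one retained ortholog at that position.

Outlier orthologs are removed when they carry an internal indel longer than
a threshold (default 10 residues): a maximal run of gaps not touching either
alignment terminus, or a recorded insertion block relative to the reference.
Leading/trailing gap runs are length variation, not internal indels, and are
ignored.
"""

from __future__ import annotations

import decimal
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .accessibility import AaSubstitution
from .seqcore import AMINO_ACIDS, SequenceError

__all__ = [
    "OrthologAlignment",
    "ConservationProfile",
    "PositionSummary",
    "filter_orthologs",
    "build_profile",
    "position_summary",
    "classify_natural",
]

GAP = "-"
_ALPHABET = AMINO_ACIDS | {GAP, "X"}


def _round1(x: float) -> float:
    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class OrthologAlignment:
    """Reference-anchored residues, one string per ortholog.

    ``insertions`` optionally records, per ortholog, insertion blocks
    relative to the reference as (after_position, length) pairs; these do
    not appear in the anchored residue strings but count toward the internal
    indel filter.
    """

    reference_id: str
    reference_length: int
    entries: Dict[str, str]
    insertions: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for oid, row in self.entries.items():
            if len(row) != self.reference_length:
                raise SequenceError(
                    f"ortholog {oid!r} has length {len(row)}, expected "
                    f"{self.reference_length}"
                )
            bad = set(row) - _ALPHABET
            if bad:
                raise SequenceError(
                    f"ortholog {oid!r} contains invalid symbols: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PositionSummary:
    position: int
    counts: Dict[str, int]
    gap_count: int
    n_entries: int
    percentages: Dict[str, float]
    occurring_residues: frozenset


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position residue and gap counts over the retained orthologs."""

    reference_id: str
    n_entries: int
    counts: Tuple[Dict[str, int], ...]   # one dict per position, residues only
    gap_counts: Tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.counts)


def _internal_gap_runs(row: str) -> List[int]:
    """Lengths of maximal gap runs not touching either terminus."""
    runs = [(m.start(), m.end()) for m in re.finditer(r"-+", row)]
    return [e - s for s, e in runs if s > 0 and e < len(row)]


def max_internal_indel_length(
    aln: OrthologAlignment, ortholog_id: str
) -> int:
    """Longest internal indel (gap run or insertion block) for one entry."""
    row = aln.entries[ortholog_id]
    gap_runs = _internal_gap_runs(row)
    ins = [length for _, length in aln.insertions.get(ortholog_id, [])]
    candidates = gap_runs + ins
    return max(candidates) if candidates else 0


def filter_orthologs(
    aln: OrthologAlignment, max_internal_indel: int = 10
) -> OrthologAlignment:
    """Drop entries whose longest internal indel strictly exceeds the cutoff.

    The boundary is strict: an entry with a 10-residue internal gap run is
    retained, an 11-residue run is removed. Idempotent and order-independent.
    """
    kept = {
        oid: row
        for oid, row in aln.entries.items()
        if max_internal_indel_length(aln, oid) <= max_internal_indel
    }
    return OrthologAlignment(
        reference_id=aln.reference_id,
        reference_length=aln.reference_length,
        entries=kept,
        insertions={oid: v for oid, v in aln.insertions.items() if oid in kept},
    )


def build_profile(aln: OrthologAlignment) -> ConservationProfile:
    """Tally residue and gap counts at every reference position."""
    L = aln.reference_length
    counts: List[Dict[str, int]] = [dict() for _ in range(L)]
    gaps = [0] * L
    for row in aln.entries.values():
        for i, sym in enumerate(row):
            if sym == GAP:
                gaps[i] += 1
            else:
                counts[i][sym] = counts[i].get(sym, 0) + 1
    return ConservationProfile(
        reference_id=aln.reference_id,
        n_entries=len(aln.entries),
        counts=tuple(counts),
        gap_counts=tuple(gaps),
    )


def position_summary(profile: ConservationProfile, pos: int) -> PositionSummary:
    """Counts, percentages (to one decimal) and occurring residues at ``pos``.

    Percentages use the total number of retained entries as denominator
    (gapped entries included), i.e. "percentage of entries in the alignment".
    """
    if not 1 <= pos <= profile.length:
        raise SequenceError(f"position {pos} out of range 1..{profile.length}")
    counts = dict(profile.counts[pos - 1])
    n = profile.n_entries
    pct = {r: _round1(100.0 * c / n) for r, c in counts.items()} if n else {}
    return PositionSummary(
        position=pos,
        counts=counts,
        gap_count=profile.gap_counts[pos - 1],
        n_entries=n,
        percentages=pct,
        occurring_residues=frozenset(r for r, c in counts.items() if c >= 1),
    )


def classify_natural(profile: ConservationProfile, sub: AaSubstitution) -> bool:
    """True iff the mutant residue occurs in at least one retained ortholog.

    Operates on raw counts, never on rounded percentages, so a residue seen
    once among many entries (a displayed 0.0%) still classifies as natural
    only when its count is nonzero.
    """
    if not 1 <= sub.position <= profile.length:
        raise SequenceError(
            f"substitution position {sub.position} out of range 1..{profile.length}"
        )
    return profile.counts[sub.position - 1].get(sub.mut, 0) >= 1


def percent_mt_wt(
    profile: ConservationProfile, sub: AaSubstitution
) -> Tuple[float, float]:
    """(%MT, %WT) for a substitution, each rounded to one decimal."""
    summary = position_summary(profile, sub.position)
    return (
        summary.percentages.get(sub.mut, 0.0),
        summary.percentages.get(sub.wt, 0.0),
    )
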