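"""Single-nucleotide missense accessibility.

Enumerates every amino acid substitution reachable from a coding sequence by
exactly one nucleotide change: the mutational neighbourhood that a single
round of point mutagenesis can explore. Synonymous changes and stop-gains
are excluded (the landscape is one of full-length missense variants), the
terminal stop codon is skipped, and substitutions reachable by several
distinct nucleotide paths are counted once, with the path multiplicity kept
as an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Tuple

from .seqcore import (
    CODON_TO_AA,
    STOP_CODONS,
    CodingSequence,
    SequenceError,
)

__all__ = ["AaSubstitution", "AccessibleSet", "enumerate_accessible"]


@dataclass(frozen=True, order=True)
class AaSubstitution:
    """A single amino acid substitution on 1-based protein coordinates."""

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise SequenceError(f"substitution at {self.position} is synonymous")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


@dataclass(frozen=True)
class AccessibleSet:
    """The set of single-nucleotide-accessible missense substitutions.

    ``convention_flags`` records the enumeration conventions so that counts
    are reproducible and auditable; ``multiplicity`` maps each substitution
    to the number of distinct nucleotide changes that reach it.
    """

    substitutions: FrozenSet[AaSubstitution]
    source_cds_id: str
    convention_flags: Dict[str, object] = field(default_factory=dict)
    multiplicity: Dict[AaSubstitution, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.substitutions)

    def __contains__(self, sub: AaSubstitution) -> bool:
        return sub in self.substitutions

    def positions(self) -> FrozenSet[int]:
        return frozenset(s.position for s in self.substitutions)


def enumerate_accessible(
    cds: CodingSequence,
    include_start_codon: bool = True,
    position_range: Optional[Tuple[int, int]] = None,
) -> AccessibleSet:
    """Enumerate all missense substitutions one nucleotide change away.

    Parameters
    ----------
    cds
        A reference-origin coding sequence (in frame, terminal stop).
    include_start_codon
        Whether substitutions in codon 1 are counted. Defaults to True:
        the initiator codon encodes an ordinary Met residue at the protein
        level and its missense neighbours are structurally scoreable.
    position_range
        Optional inclusive (first, last) protein positions to restrict the
        enumeration to, e.g. the residues resolved in a crystal structure
        when the downstream stability predictor needs coordinates.

    Returns
    -------
    AccessibleSet
        Unique (position, wt, mut) substitutions with path multiplicities.
    """
    if cds.origin != "reference":
        raise SequenceError(
            "accessibility enumeration requires a reference-origin CDS; "
            "frameshifted sequences have no stable codon frame"
        )
    n_sense = cds.n_codons - 1  # terminal stop excluded
    first = 1 if include_start_codon else 2
    last = n_sense
    if position_range is not None:
        first = max(first, position_range[0])
        last = min(last, position_range[1])

    mult: Dict[AaSubstitution, int] = {}
    for ci in range(first, last + 1):
        codon = cds.codon(ci)
        wt = CODON_TO_AA[codon]
        for j in range(3):
            for base in "ACGT":
                if base == codon[j]:
                    continue
                alt_codon = codon[:j] + base + codon[j + 1:]
                if alt_codon in STOP_CODONS:
                    continue  # stop-gain: not a substitution variant
                mut = CODON_TO_AA[alt_codon]
                if mut == wt:
                    continue  # synonymous
                sub = AaSubstitution(position=ci, wt=wt, mut=mut)
                mult[sub] = mult.get(sub, 0) + 1

    flags = {
        "include_start_codon": include_start_codon,
        "exclude_stop_gains": True,
        "exclude_synonymous": True,
        "terminal_stop_skipped": True,
        "position_range": position_range,
    }
    return AccessibleSet(
        substitutions=frozenset(mult),
        source_cds_id=cds.id,
        convention_flags=flags,
        multiplicity=mult,
    )
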