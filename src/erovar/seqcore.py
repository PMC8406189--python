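"""Coding-sequence model: mutation application, translation, protein
consequences, and molecular weight.

The module embodies the DNA -> protein bookkeeping needed to characterise
erosive alleles of a coding gene: a single base substitution, an indel that
may or may not respect the codon frame, and the resulting protein-level
description (substitution, in-frame indel, nonsense truncation, or
frameshift with a novel C-terminal tail) together with the average molecular
weight of the product.

Coordinate convention: all positions are 1-based and deletion ranges are
inclusive, so a deletion "from 187 to 504" removes 318 nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodingSequence",
    "ProteinSequence",
    "MutationSpec",
    "ConsequenceDescriptor",
    "VariantRecord",
    "translate",
    "apply_mutation",
    "protein_consequence",
    "molecular_weight",
    "AVERAGE_RESIDUE_MASSES",
    "WATER_MASS",
]

NUCLEOTIDES = frozenset("ACGT")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: Average (isotope-abundance-weighted) residue masses in Da, i.e. the mass of
#: each amino acid minus one water. Values follow the standard ExPASy table.
AVERAGE_RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Average mass of one water molecule in Da, added once per chain.
WATER_MASS = 18.01524


class SequenceError(ValueError):
    """Raised for malformed sequences or invalid mutation specs."""


@dataclass(frozen=True)
class CodingSequence:
    """A nucleotide coding sequence.

    ``origin`` distinguishes an in-frame reference (length divisible by 3,
    terminal stop codon) from a mutated sequence, which may have any length
    >= 1 because frameshifting indels are allowed.
    """

    id: str
    seq: str
    origin: Literal["reference", "mutated"] = "reference"

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceError("coding sequence must be non-empty")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise SequenceError(
                f"coding sequence {self.id!r} contains invalid symbols: {sorted(bad)}"
            )
        if self.origin == "reference":
            if len(self.seq) % 3 != 0:
                raise SequenceError(
                    f"reference sequence {self.id!r} has length {len(self.seq)}, "
                    "not divisible by 3"
                )
            if self.seq[-3:] not in STOP_CODONS:
                raise SequenceError(
                    f"reference sequence {self.id!r} does not end in a stop codon"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, i: int) -> str:
        """Return the i-th codon (1-based)."""
        if not 1 <= i <= self.n_codons:
            raise SequenceError(f"codon index {i} out of range 1..{self.n_codons}")
        return self.seq[3 * (i - 1): 3 * i]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 one-letter amino acid codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("protein sequence must be non-empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise SequenceError(
                f"protein {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MutationSpec:
    """A DNA-level edit: substitution, deletion, or insertion.

    Substitution: ``position`` (1-based), ``ref_base`` and ``alt_base``.
    Deletion: inclusive 1-based range ``start``..``end``.
    Insertion: ``inserted_seq`` placed between ``after_position`` and
    ``after_position + 1``.
    """

    kind: Literal["substitution", "deletion", "insertion"]
    position: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    after_position: Optional[int] = None
    inserted_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.position is None or self.ref_base is None or self.alt_base is None:
                raise SequenceError("substitution needs position, ref_base, alt_base")
            if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
                raise SequenceError("substitution bases must be one of A,C,G,T")
        elif self.kind == "deletion":
            if self.start is None or self.end is None:
                raise SequenceError("deletion needs start and end")
            if self.start > self.end:
                raise SequenceError(f"deletion start {self.start} > end {self.end}")
        elif self.kind == "insertion":
            if self.after_position is None or not self.inserted_seq:
                raise SequenceError("insertion needs after_position and inserted_seq")
            if set(self.inserted_seq) - NUCLEOTIDES:
                raise SequenceError("inserted_seq must be over A,C,G,T")
        else:
            raise SequenceError(f"unknown mutation kind {self.kind!r}")


@dataclass(frozen=True)
class ConsequenceDescriptor:
    """Protein-level description of an alt/ref relationship.

    ``substitutions`` holds (position, wt, mut) triples on reference protein
    coordinates. For in-frame indels, ``deleted_range`` / ``inserted_block``
    describe the contiguous block; a frameshift or nonsense truncation
    carries the last conserved reference position and (for frameshifts) the
    length of the novel tail read in the shifted frame.
    """

    klass: Literal[
        "identical", "substitutions", "inframe_deletion", "inframe_insertion",
        "frameshift", "nonsense_truncation", "complex",
    ]
    substitutions: tuple = ()
    deleted_range: Optional[tuple] = None          # (first, last) 1-based inclusive
    inserted_block: Optional[tuple] = None         # (after_position, residues)
    truncation_position: Optional[int] = None
    novel_tail_length: Optional[int] = None

    def describe(self) -> str:
        """Human-readable one-line description, catalog style."""
        if self.klass == "identical":
            return "identical"
        if self.klass == "substitutions":
            return ", ".join(f"{w}{p}{m}" for p, w, m in self.substitutions)
        if self.klass == "inframe_deletion":
            a, b = self.deleted_range
            subs = "".join(
                f" + {w}{p}{m}" for p, w, m in self.substitutions
            )
            return f"In-frame deletion of {b - a + 1} aa (positions {a}-{b}){subs}"
        if self.klass == "inframe_insertion":
            after, block = self.inserted_block
            return (
                f"In-frame insertion of {block} between positions "
                f"{after} and {after + 1}"
            )
        if self.klass == "nonsense_truncation":
            return f"Truncation after position {self.truncation_position}"
        if self.klass == "frameshift":
            return (
                f"Frameshift: truncation with a {self.novel_tail_length}-aa "
                f"novel tail after position {self.truncation_position}"
            )
        return "complex"


@dataclass(frozen=True)
class VariantRecord:
    """A catalogued allele: DNA edit plus derived consequence and mass."""

    allele_name: str
    mutation: MutationSpec
    consequence: ConsequenceDescriptor
    molecular_weight_kda: float
    selection_class: Literal["heat_selected", "control"] = "heat_selected"

    def __post_init__(self) -> None:
        if self.molecular_weight_kda <= 0:
            raise SequenceError("molecular weight must be positive")


def translate(cds: CodingSequence) -> ProteinSequence:
    """Translate in frame 0 using the standard genetic code.

    Reading starts at position 1 (ATG initiation is not required), halts at
    the first stop codon (excluded from the output) or at the last complete
    codon when no stop is reached; 1-2 trailing nucleotides left over after a
    frameshift are ignored.
    """
    residues = []
    seq = cds.seq
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            break
        residues.append(CODON_TO_AA[codon])
    if not residues:
        raise SequenceError(
            f"translation of {cds.id!r} is empty (first codon is a stop or "
            "sequence is shorter than one codon)"
        )
    return ProteinSequence(id=cds.id, residues="".join(residues))


def apply_mutation(cds: CodingSequence, spec: MutationSpec) -> CodingSequence:
    """Return a new mutated-origin sequence with ``spec`` applied.

    The input is never modified. A substitution whose ``ref_base`` does not
    match the sequence raises an error naming the position and both bases.
    """
    seq = cds.seq
    n = len(seq)
    if spec.kind == "substitution":
        p = spec.position
        if not 1 <= p <= n:
            raise SequenceError(f"substitution position {p} out of bounds 1..{n}")
        observed = seq[p - 1]
        if observed != spec.ref_base:
            raise SequenceError(
                f"ref base mismatch at position {p}: expected {spec.ref_base}, "
                f"observed {observed}"
            )
        new = seq[: p - 1] + spec.alt_base + seq[p:]
    elif spec.kind == "deletion":
        if not (1 <= spec.start <= spec.end <= n):
            raise SequenceError(
                f"deletion {spec.start}-{spec.end} out of bounds 1..{n}"
            )
        new = seq[: spec.start - 1] + seq[spec.end:]
        if not new:
            raise SequenceError("deletion removes the entire sequence")
    else:  # insertion
        if not 0 <= spec.after_position <= n:
            raise SequenceError(
                f"insertion after_position {spec.after_position} out of bounds 0..{n}"
            )
        new = seq[: spec.after_position] + spec.inserted_seq + seq[spec.after_position:]
    return CodingSequence(id=f"{cds.id}_mut", seq=new, origin="mutated")


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def protein_consequence(ref: ProteinSequence, alt: ProteinSequence) -> ConsequenceDescriptor:
    """Classify the protein-level relationship between ``alt`` and ``ref``.

    The classification anchors the longest common prefix and suffix. In-frame
    indels are recognised as a single contiguous gained/lost block, allowing
    at most one flanking substitution on the deletion side (a non-codon-
    aligned DNA deletion merges the two broken codons into one residue, which
    reads as a substitution adjacent to the deleted block). An alt that is a
    strict prefix of ref is a nonsense truncation; an alt that shares a
    prefix and then diverges (no usable suffix anchor) is a frameshift whose
    novel tail is everything past the shared prefix. Anything else falls
    through to ``complex``.
    """
    r, a = ref.residues, alt.residues
    if r == a:
        return ConsequenceDescriptor(klass="identical")
    if len(r) == len(a):
        subs = tuple(
            (i + 1, r[i], a[i]) for i in range(len(r)) if r[i] != a[i]
        )
        return ConsequenceDescriptor(klass="substitutions", substitutions=subs)

    p = _lcp(r, a)
    s = _lcs(r, a)

    if len(a) < len(r):
        if p == len(a):  # strict prefix
            return ConsequenceDescriptor(
                klass="nonsense_truncation", truncation_position=len(a)
            )
        d = len(r) - len(a)
        # cap prefix+suffix so anchors do not overlap on the shorter string
        s_cap = min(s, len(a) - p)
        if p + s_cap == len(a):
            # pure in-frame deletion; anchored at the longest common prefix
            return ConsequenceDescriptor(
                klass="inframe_deletion", deleted_range=(p + 1, p + d)
            )
        if p + s_cap == len(a) - 1:
            # one flanking substitution at the left edge of the deleted block
            return ConsequenceDescriptor(
                klass="inframe_deletion",
                deleted_range=(p + 2, p + d + 1),
                substitutions=((p + 1, r[p], a[p]),),
            )
        if p >= 1 and s == 0:
            return ConsequenceDescriptor(
                klass="frameshift",
                truncation_position=p,
                novel_tail_length=len(a) - p,
            )
        return ConsequenceDescriptor(klass="complex")

    # alt longer than ref
    ins = len(a) - len(r)
    s_cap = min(s, len(r) - p)
    if p + s_cap == len(r):
        return ConsequenceDescriptor(
            klass="inframe_insertion",
            inserted_block=(p, a[p:p + ins]),
        )
    if p >= 1 and s == 0:
        return ConsequenceDescriptor(
            klass="frameshift", truncation_position=p, novel_tail_length=len(a) - p
        )
    return ConsequenceDescriptor(klass="complex")


def molecular_weight(p: ProteinSequence) -> float:
    """Average molecular weight in Da: residue-mass sum plus one water."""
    try:
        return sum(AVERAGE_RESIDUE_MASSES[r] for r in p.residues) + WATER_MASS
    except KeyError as exc:  # pragma: no cover - ProteinSequence validates
        raise SequenceError(f"unknown residue symbol {exc.args[0]!r}") from exc


def molecular_weight_kda(p: ProteinSequence) -> float:
    """Molecular weight in kDa, rounded half-up to one decimal."""
    import decimal

    kda = decimal.Decimal(molecular_weight(p)) / 1000
    return float(kda.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))
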