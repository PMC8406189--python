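"""Thermodynamic stability (ddG) records and variant-class assembly.

Predicted folding free-energy changes are consumed as a table keyed by
mutation codes in the FoldX dialect (wt residue, chain letter, position,
mutant residue, e.g. ``KA5A``). The module aggregates prediction repeats,
collapses homomultimer chains onto protein positions, and assembles the
three distributions compared in the stability analysis:

* ``heat_selected`` — substitutions recovered by selection,
* ``accessible``    — every single-nucleotide-accessible missense variant
                      with a ddG record,
* ``natural``       — substitutions observed in at least one ortholog.

ddG values are never computed here: the structure-based predictor is
external software whose output is an input table. ``foldx_adapter`` emits a
mutation-list file in the predictor's individual-list format and parses its
tabular output, but performs no computation itself.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .accessibility import AaSubstitution, AccessibleSet
from .conservation import ConservationProfile
from .seqcore import AMINO_ACIDS, SequenceError

__all__ = [
    "MutationCode",
    "StabilityRecord",
    "ClassedDdg",
    "parse_foldx_code",
    "aggregate_repeats",
    "collapse_chains",
    "assemble_variant_classes",
]

log = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^([A-Za-z])([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class MutationCode:
    """FoldX-dialect mutation code: wt residue, chain, position, mutant."""

    wt: str
    chain: str
    position: int
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in AMINO_ACIDS:
            raise SequenceError(f"invalid wild-type residue {self.wt!r}")
        if self.mut not in AMINO_ACIDS:
            raise SequenceError(f"invalid mutant residue {self.mut!r}")
        if not (len(self.chain) == 1 and self.chain.isalpha()):
            raise SequenceError(f"invalid chain id {self.chain!r}")
        if self.wt == self.mut:
            raise SequenceError(f"mutation code {self} is synonymous")

    def __str__(self) -> str:
        return f"{self.wt}{self.chain}{self.position}{self.mut}"


def parse_foldx_code(code: str) -> MutationCode:
    """Parse ``wt + chain + position + mut``; formatting inverts exactly."""
    if not code:
        raise SequenceError("empty mutation code")
    m = _CODE_RE.match(code)
    if not m:
        if re.match(r"^[A-Za-z]\d", code):
            raise SequenceError(f"mutation code {code!r}: missing chain letter")
        if not re.search(r"\d", code):
            raise SequenceError(f"mutation code {code!r}: missing digit position")
        raise SequenceError(f"malformed mutation code {code!r}")
    wt, chain, pos, mut = m.groups()
    return MutationCode(wt=wt.upper(), chain=chain.upper(),
                        position=int(pos), mut=mut.upper())


@dataclass(frozen=True)
class StabilityRecord:
    """Mean and SD of a ddG prediction over ``n_repeats`` runs (kcal/mol)."""

    code: MutationCode
    ddg_mean: float
    ddg_sd: float
    n_repeats: int = 3

    def __post_init__(self) -> None:
        if self.ddg_sd < 0:
            raise SequenceError("ddG SD must be non-negative")
        if self.n_repeats < 1:
            raise SequenceError("n_repeats must be >= 1")


def aggregate_repeats(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator; 0.0 for n=1)."""
    if len(values) == 0:
        raise SequenceError("cannot aggregate an empty list of repeats")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) >= 2 else 0.0
    return mean, sd


def collapse_chains(
    records: Iterable[StabilityRecord],
) -> Dict[Tuple[int, str], StabilityRecord]:
    """Key records by (position, mut), averaging over chains of a multimer.

    When the same substitution is scored on several chains, the mean of the
    per-chain means (and of the SDs) is used and the first chain's code is
    retained for display.
    """
    grouped: Dict[Tuple[int, str], List[StabilityRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.code.position, rec.code.mut), []).append(rec)
    out: Dict[Tuple[int, str], StabilityRecord] = {}
    for key, recs in grouped.items():
        if len(recs) == 1:
            out[key] = recs[0]
        else:
            out[key] = StabilityRecord(
                code=recs[0].code,
                ddg_mean=statistics.fmean(r.ddg_mean for r in recs),
                ddg_sd=statistics.fmean(r.ddg_sd for r in recs),
                n_repeats=recs[0].n_repeats,
            )
    return out


@dataclass(frozen=True)
class ClassedDdg:
    """The three labelled ddG vectors compared in the stability analysis."""

    heat_selected: Tuple[float, ...]
    accessible: Tuple[float, ...]
    natural: Tuple[float, ...]
    heat_selected_subs: Tuple[AaSubstitution, ...] = ()
    n_missing_accessible: int = 0
    natural_restricted_to_accessible: bool = False

    def sizes(self) -> Dict[str, int]:
        return {
            "heat_selected": len(self.heat_selected),
            "accessible": len(self.accessible),
            "natural": len(self.natural),
        }

    def as_groups(self) -> Dict[str, Tuple[float, ...]]:
        return {
            "heat_selected": self.heat_selected,
            "accessible": self.accessible,
            "natural": self.natural,
        }


def assemble_variant_classes(
    accessible: AccessibleSet,
    profile: ConservationProfile,
    selected: Sequence[AaSubstitution],
    ddg: Mapping[Tuple[int, str], StabilityRecord],
    restrict_natural_to_accessible: bool = False,
) -> ClassedDdg:
    """Assemble selected / accessible / natural ddG vectors.

    A selected substitution without a ddG record is an error (no silent
    drops in the class under study); accessible or natural substitutions
    lacking records are logged and skipped. Naturalness is independent of
    accessibility unless ``restrict_natural_to_accessible`` is set.
    """
    sel_vals: List[float] = []
    seen_sel = set()
    for sub in selected:
        key = (sub.position, sub.mut)
        if key not in ddg:
            raise SequenceError(
                f"selected substitution {sub} has no ddG record"
            )
        if key in seen_sel:
            continue
        seen_sel.add(key)
        sel_vals.append(ddg[key].ddg_mean)

    acc_vals: List[float] = []
    missing = 0
    for sub in sorted(accessible.substitutions):
        key = (sub.position, sub.mut)
        rec = ddg.get(key)
        if rec is None:
            missing += 1
            continue
        acc_vals.append(rec.ddg_mean)
    if missing:
        log.info("%d accessible substitutions lack ddG records and were skipped",
                 missing)

    nat_vals: List[float] = []
    if restrict_natural_to_accessible:
        candidates = [
            (sub.position, sub.mut) for sub in sorted(accessible.substitutions)
        ]
    else:
        candidates = sorted(ddg.keys())
    seen_nat = set()
    for pos, mut in candidates:
        if (pos, mut) in seen_nat:
            continue
        seen_nat.add((pos, mut))
        rec = ddg.get((pos, mut))
        if rec is None:
            continue
        wt_counts = profile.counts[pos - 1] if 1 <= pos <= profile.length else {}
        if wt_counts.get(mut, 0) >= 1:
            nat_vals.append(rec.ddg_mean)

    return ClassedDdg(
        heat_selected=tuple(sel_vals),
        accessible=tuple(acc_vals),
        natural=tuple(nat_vals),
        heat_selected_subs=tuple(selected),
        n_missing_accessible=missing,
        natural_restricted_to_accessible=restrict_natural_to_accessible,
    )
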