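"""Seeded generators for every input class the pipeline consumes.

The generators emulate the statistical structure of the study's inputs so
the whole analysis is testable without any external download: a random valid
coding sequence, a reference-anchored ortholog alignment with a per-position
conservation profile and injected internal indels, a ddG table with
class-specific location shifts, and per-cell microcolony outcomes with a
configurable survival ratio and lag-time shift.

A single top-level seed fans out into independent per-generator streams
(fixed stream ids), so adding a generator never perturbs fixtures produced
by the others. All randomness uses numpy's PCG64 ``default_rng``.

Default microcolony parameters emulate the study's single-cell experiment:
~3 generations per microcolony (8 cells, exactly one PA-bearing cell when
the founder was induced), a PA-free survival probability of 0.48 with a
1.9-fold PA+ advantage, and right-skewed (lognormal) resuscitation times
whose PA- median sits 2.5 h above the PA+ median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .accessibility import AaSubstitution, AccessibleSet
from .conservation import GAP, OrthologAlignment
from .groupstats import MicrocolonyOutcome
from .seqcore import (
    CODON_TO_AA,
    STOP_CODONS,
    CodingSequence,
    ProteinSequence,
    SequenceError,
)
from .stability import MutationCode, StabilityRecord, aggregate_repeats

__all__ = [
    "SyntheticSpec",
    "gen_cds",
    "gen_ortholog_alignment",
    "gen_ddg_table",
    "gen_microcolonies",
]

SENSE_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)
_STOPS = sorted(STOP_CODONS)
AA20 = sorted(set(CODON_TO_AA.values()))

# fixed stream ids: fan a top-level seed out to independent generators
_STREAMS = {"cds": 1, "alignment": 2, "ddg": 3, "microcolony": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the full synthetic input bundle."""

    seed: int = 0
    cds_codons: int = 472
    n_orthologs: int = 218
    conservation: Union[float, Sequence[float]] = 0.8
    indel_fraction: float = 0.0
    indel_length: int = 11
    ddg_means: Dict[str, float] = field(
        default_factory=lambda: {"heat_selected": 5.0, "natural": 0.5,
                                 "accessible": 1.5}
    )
    ddg_sd: float = 1.0
    n_colonies_induced: int = 78
    n_colonies_noninduced: int = 35
    generations: int = 3
    survival_p_minus: float = 0.48
    survival_ratio: float = 1.9
    lag_log_mean: float = np.log(2.0)
    lag_log_sd: float = 0.4
    lag_shift_h: float = 2.5

    def __post_init__(self) -> None:
        if self.cds_codons < 2:
            raise SequenceError("cds_codons must be >= 2")
        if not 0 < self.survival_p_minus <= 1:
            raise ValueError("survival_p_minus must be in (0, 1]")
        if self.survival_ratio * self.survival_p_minus > 1:
            raise ValueError("survival_ratio * survival_p_minus exceeds 1")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")


def gen_cds(n_codons: int, seed: int = 0) -> CodingSequence:
    """Random valid CDS: ATG, n_codons-2 sense codons, one terminal stop."""
    if n_codons < 2:
        raise SequenceError("a CDS needs at least a start and a stop codon")
    rng = _rng(seed, "cds")
    body = rng.choice(SENSE_CODONS, size=n_codons - 2) if n_codons > 2 else []
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    seq = "ATG" + "".join(body) + stop
    return CodingSequence(id=f"synthetic_cds_{seed}", seq=seq, origin="reference")


def gen_ortholog_alignment(
    ref: ProteinSequence, spec: SyntheticSpec
) -> OrthologAlignment:
    """Alignment whose entries keep the reference residue with per-position
    probability ``spec.conservation`` and otherwise draw a uniform different
    residue; a fraction of entries receives one internal gap run of
    ``spec.indel_length`` residues at a random internal location."""
    L = len(ref)
    cons = np.asarray(
        [spec.conservation] * L
        if np.isscalar(spec.conservation)
        else list(spec.conservation),
        dtype=float,
    )
    if cons.size != L:
        raise SequenceError("conservation profile length must match reference")
    if np.any((cons < 0) | (cons > 1)):
        raise ValueError("conservation probabilities must lie in [0, 1]")
    rng = _rng(spec.seed, "alignment")
    others = {r: [a for a in AA20 if a != r] for r in AA20}
    entries: Dict[str, str] = {}
    for k in range(spec.n_orthologs):
        keep = rng.random(L) < cons
        row = [
            ref.residues[i] if keep[i]
            else others[ref.residues[i]][rng.integers(0, 19)]
            for i in range(L)
        ]
        if spec.indel_fraction and rng.random() < spec.indel_fraction:
            m = min(spec.indel_length, max(1, L - 2))
            # internal: never touching either terminus
            start = int(rng.integers(1, L - m)) if L - m > 1 else 1
            row[start:start + m] = [GAP] * m
        entries[f"ortholog_{k:04d}"] = "".join(row)
    return OrthologAlignment(
        reference_id=ref.id, reference_length=L, entries=entries
    )


def gen_ddg_table(
    accessible: AccessibleSet,
    natural: Sequence[AaSubstitution],
    selected: Sequence[AaSubstitution],
    spec: SyntheticSpec,
    chain: str = "A",
) -> Dict[Tuple[int, str], StabilityRecord]:
    """ddG records for every accessible substitution (plus any selected or
    natural ones not in the accessible set), drawn per class.

    Class precedence for the location shift is selected > natural >
    accessible. Three per-repeat values are drawn N(class mean, class sd),
    so the recorded mean/SD are realised from repeats exactly as a
    prediction table would report them.
    """
    rng = _rng(spec.seed, "ddg")
    nat = {(s.position, s.mut) for s in natural}
    sel = {(s.position, s.mut) for s in selected}
    universe: Dict[Tuple[int, str], AaSubstitution] = {
        (s.position, s.mut): s for s in sorted(accessible.substitutions)
    }
    for s in list(natural) + list(selected):
        universe.setdefault((s.position, s.mut), s)
    out: Dict[Tuple[int, str], StabilityRecord] = {}
    for key in sorted(universe):
        s = universe[key]
        if key in sel:
            mu = spec.ddg_means["heat_selected"]
        elif key in nat:
            mu = spec.ddg_means["natural"]
        else:
            mu = spec.ddg_means["accessible"]
        repeats = rng.normal(mu, spec.ddg_sd, size=3)
        mean, sd = aggregate_repeats(list(repeats))
        out[key] = StabilityRecord(
            code=MutationCode(wt=s.wt, chain=chain, position=s.position, mut=s.mut),
            ddg_mean=float(mean), ddg_sd=float(sd), n_repeats=3,
        )
    return out


def gen_microcolonies(spec: SyntheticSpec) -> List[MicrocolonyOutcome]:
    """Per-cell outcomes for induced and non-induced microcolonies.

    Each colony holds 2**generations cells; induced colonies contain exactly
    one PA-bearing cell (the aggregate segregates asymmetrically, so a
    single sibling inherits it). Survival is Bernoulli(p_minus) for PA-free
    cells and Bernoulli(ratio * p_minus) for the PA-bearing cell. Survivor
    resuscitation times are lognormal; PA-free survivors are shifted later
    by ``lag_shift_h`` hours, so the PA+/PA- median lag difference equals
    the shift exactly in expectation.
    """
    rng = _rng(spec.seed, "microcolony")
    p_minus = spec.survival_p_minus
    p_plus = spec.survival_ratio * p_minus
    n_cells = 2 ** spec.generations
    out: List[MicrocolonyOutcome] = []

    def lag(pa_plus: bool) -> float:
        base = float(rng.lognormal(spec.lag_log_mean, spec.lag_log_sd))
        return base if pa_plus else base + spec.lag_shift_h

    for c in range(spec.n_colonies_induced):
        colony = f"trp_{c:04d}"
        pa_cell = int(rng.integers(0, n_cells))
        for i in range(n_cells):
            pa = i == pa_cell
            survived = bool(rng.random() < (p_plus if pa else p_minus))
            out.append(
                MicrocolonyOutcome(
                    colony_id=colony,
                    cell_id=f"{colony}_c{i}",
                    pa_status="PA_plus" if pa else "PA_minus",
                    induced=True,
                    survived=survived,
                    resuscitation_time=lag(pa) if survived else None,
                )
            )
    for c in range(spec.n_colonies_noninduced):
        colony = f"notrp_{c:04d}"
        for i in range(n_cells):
            survived = bool(rng.random() < p_minus)
            out.append(
                MicrocolonyOutcome(
                    colony_id=colony,
                    cell_id=f"{colony}_c{i}",
                    pa_status="PA_minus",
                    induced=False,
                    survived=survived,
                    resuscitation_time=lag(False) if survived else None,
                )
            )
    return out
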