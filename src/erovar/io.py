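"""Readers and writers for the toolkit's file dialects.

Canonical formats are plain text: FASTA for sequences (60-column wrap, IDs
preserved verbatim), aligned FASTA or a wide TSV for ortholog alignments,
and tab-delimited UTF-8 tables with a header row for everything else. XLSX
ingestion (for spreadsheet replicas of the supplementary tables) is a thin
adapter over the TSV paths.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .accessibility import AccessibleSet
from .conservation import OrthologAlignment
from .groupstats import MicrocolonyOutcome
from .seqcore import CodingSequence, MutationSpec, ProteinSequence, SequenceError
from .stability import StabilityRecord, collapse_chains, parse_foldx_code

PathLike = Union[str, Path]


# -- FASTA -------------------------------------------------------------------

def read_cds_fasta(path: PathLike, origin: str = "reference") -> CodingSequence:
    """Read the first record of a nucleotide FASTA as a CodingSequence."""
    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise SequenceError(f"no FASTA records in {path}")
    return CodingSequence(id=rec.id, seq=str(rec.seq).upper(), origin=origin)


def write_fasta(path: PathLike, records: List[Tuple[str, str]]) -> None:
    """Write (id, sequence) pairs wrapped at 60 columns."""
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: PathLike) -> ProteinSequence:
    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise SequenceError(f"no FASTA records in {path}")
    return ProteinSequence(id=rec.id, residues=str(rec.seq).upper())


# -- ortholog alignments -----------------------------------------------------

def read_alignment_fasta(path: PathLike, reference_id: str) -> OrthologAlignment:
    """Aligned (equal-length, gapped) FASTA -> OrthologAlignment.

    If a record with ``reference_id`` is present it defines the reference
    length and is excluded from the entries; otherwise the common record
    length is used and every record is an entry.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if reference_id in records:
        L = len(records[reference_id])
        entries = {k: v for k, v in records.items() if k != reference_id}
    else:
        L = len(next(iter(records.values())))
        entries = records
    return OrthologAlignment(
        reference_id=reference_id, reference_length=L, entries=entries
    )


def read_alignment_wide_tsv(path: PathLike, reference_id: str) -> OrthologAlignment:
    """Wide TSV (rows = orthologs, columns = reference positions).

    The first column holds the ortholog id; remaining columns are one
    residue (or '-') per reference position, mirroring the supplementary
    spreadsheet layout.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    entries = {
        str(row[id_col]): "".join(str(v) for v in row.iloc[1:])
        for _, row in df.iterrows()
    }
    L = len(df.columns) - 1
    return OrthologAlignment(
        reference_id=reference_id, reference_length=L, entries=entries
    )


def write_alignment_fasta(path: PathLike, aln: OrthologAlignment) -> None:
    write_fasta(path, list(aln.entries.items()))


def read_alignment_xlsx(
    path: PathLike, reference_id: str, sheet: Union[int, str] = 0
) -> OrthologAlignment:
    """XLSX adapter: first column ortholog id, one column per position."""
    df = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("-")
    id_col = df.columns[0]
    entries = {
        str(row[id_col]): "".join(str(v) for v in row.iloc[1:])
        for _, row in df.iterrows()
    }
    return OrthologAlignment(
        reference_id=reference_id,
        reference_length=len(df.columns) - 1,
        entries=entries,
    )


# -- variant catalog ---------------------------------------------------------

_CATALOG_INT_COLS = ("position", "start", "end", "after_position")


def _opt_int(v) -> Optional[int]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return int(float(v))


def _opt_str(v) -> Optional[str]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return str(v)


def read_variant_catalog(path: PathLike) -> pd.DataFrame:
    """Variant catalog TSV -> DataFrame with a parsed ``mutation`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            MutationSpec(
                kind=row.kind,
                position=_opt_int(getattr(row, "position", None)),
                ref_base=_opt_str(getattr(row, "ref_base", None)),
                alt_base=_opt_str(getattr(row, "alt_base", None)),
                start=_opt_int(getattr(row, "start", None)),
                end=_opt_int(getattr(row, "end", None)),
                after_position=_opt_int(getattr(row, "after_position", None)),
                inserted_seq=_opt_str(getattr(row, "inserted_seq", None)),
            )
        )
    out = df.copy()
    out["mutation"] = specs
    return out


# -- accessibility -----------------------------------------------------------

def write_accessible_tsv(path: PathLike, acc: AccessibleSet) -> None:
    rows = [
        {"position": s.position, "wt": s.wt, "mut": s.mut,
         "n_nt_paths": acc.multiplicity.get(s, 1)}
        for s in sorted(acc.substitutions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_accessible_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- ddG tables --------------------------------------------------------------

def read_ddg_tsv(path: PathLike) -> Dict[Tuple[int, str], StabilityRecord]:
    """ddG TSV (mutation_code, ddg_mean_kcal_mol, ddg_sd_kcal_mol, ...)
    keyed by (position, mut) with chains collapsed."""
    df = pd.read_csv(path, sep="\t")
    records = [
        StabilityRecord(
            code=parse_foldx_code(str(row.mutation_code)),
            ddg_mean=float(row.ddg_mean_kcal_mol),
            ddg_sd=float(getattr(row, "ddg_sd_kcal_mol", 0.0) or 0.0),
        )
        for row in df.itertuples(index=False)
    ]
    return collapse_chains(records)


def write_ddg_tsv(path: PathLike, ddg: Dict[Tuple[int, str], StabilityRecord]) -> None:
    rows = [
        {
            "mutation_code": str(rec.code),
            "ddg_mean_kcal_mol": rec.ddg_mean,
            "ddg_sd_kcal_mol": rec.ddg_sd,
            "original_aa": rec.code.wt,
            "mutant_aa": rec.code.mut,
            "position": rec.code.position,
        }
        for _, rec in sorted(ddg.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ddg_xlsx(
    path: PathLike, sheet: Union[int, str] = 0
) -> Dict[Tuple[int, str], StabilityRecord]:
    """XLSX adapter over the ddG TSV dialect (same column names)."""
    df = pd.read_excel(path, sheet_name=sheet)
    records = [
        StabilityRecord(
            code=parse_foldx_code(str(row.mutation_code)),
            ddg_mean=float(row.ddg_mean_kcal_mol),
            ddg_sd=float(getattr(row, "ddg_sd_kcal_mol", 0.0) or 0.0),
        )
        for row in df.itertuples(index=False)
    ]
    return collapse_chains(records)


# -- microcolony outcomes ----------------------------------------------------

def read_microcolony_tsv(path: PathLike) -> List[MicrocolonyOutcome]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        lag = getattr(row, "resuscitation_time_h", None)
        if lag is not None and isinstance(lag, float) and math.isnan(lag):
            lag = None
        out.append(
            MicrocolonyOutcome(
                colony_id=str(row.colony_id),
                cell_id=str(row.cell_id),
                pa_status=str(row.pa_status),
                induced=bool(row.induced),
                survived=bool(row.survived),
                resuscitation_time=None if lag is None else float(lag),
            )
        )
    return out


def write_microcolony_tsv(path: PathLike, cells: List[MicrocolonyOutcome]) -> None:
    pd.DataFrame(
        [
            {
                "colony_id": c.colony_id,
                "cell_id": c.cell_id,
                "induced": c.induced,
                "pa_status": c.pa_status,
                "survived": c.survived,
                # repr keeps full float precision so the dialect round-trips
                "resuscitation_time_h": ""
                if c.resuscitation_time is None else repr(c.resuscitation_time),
            }
            for c in cells
        ]
    ).to_csv(path, sep="\t", index=False)
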