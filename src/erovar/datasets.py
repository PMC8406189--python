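"""Packaged reference data.

* the E. coli K-12 MG1655 tnaA coding sequence (1,416 bp, 471 aa product),
* the catalog of selected tnaA alleles (DNA edits plus the reported
  protein-change descriptions and molecular weights), and
* the predicted stability changes (FoldX ddG, kcal/mol, mean of three
  repeats) reported for the eight selected single-substitution variants and
  the catalytically inactive K270A control.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .accessibility import AaSubstitution
from .io import read_cds_fasta, read_ddg_tsv, read_variant_catalog
from .seqcore import CodingSequence
from .stability import StabilityRecord


def _data_path(name: str):
    return resources.files("erovar.data").joinpath(name)


def load_tnaa_cds() -> CodingSequence:
    """The MG1655 tnaA coding sequence (reference origin)."""
    with resources.as_file(_data_path("tnaa_mg1655_cds.fasta")) as p:
        return read_cds_fasta(p)


def load_variant_catalog() -> pd.DataFrame:
    """The selected-allele catalog with parsed mutation specs."""
    with resources.as_file(_data_path("tnaa_catalog.tsv")) as p:
        return read_variant_catalog(p)


def load_heat_selected_ddg() -> Dict[Tuple[int, str], StabilityRecord]:
    """ddG records for the selected substitutions and the K270A control."""
    with resources.as_file(_data_path("heat_selected_ddg.tsv")) as p:
        return read_ddg_tsv(p)


def heat_selected_substitutions() -> List[AaSubstitution]:
    """The eight selected single amino acid substitutions (K270A excluded:
    it is the no-destabilisation control, not a selected variant)."""
    with resources.as_file(_data_path("heat_selected_ddg.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        AaSubstitution(position=int(r.position), wt=str(r.original_aa),
                       mut=str(r.mutant_aa))
        for r in df.itertuples(index=False)
        if r.selection_class == "heat_selected"
    ]
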