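"""End-to-end orchestration: enumerate -> conserve -> classify -> compare,
plus the single-cell survival stage when outcomes are provided.

Every report embeds the configuration snapshot (convention flags, filter
threshold, bootstrap size, seed) so that reruns are auditable; a rerun with
an identical config and seed produces byte-identical JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

from . import __version__
from .accessibility import enumerate_accessible
from .conservation import build_profile, filter_orthologs, percent_mt_wt, position_summary
from .groupstats import MicrocolonySurvivalModel, StabilityClassModel
from .io import (
    read_alignment_fasta,
    read_alignment_wide_tsv,
    read_cds_fasta,
    read_ddg_tsv,
    read_microcolony_tsv,
    read_variant_catalog,
    write_accessible_tsv,
)
from .seqcore import (
    apply_mutation,
    molecular_weight_kda,
    protein_consequence,
    translate,
)
from .stability import assemble_variant_classes
from .datasets import heat_selected_substitutions
from .accessibility import AaSubstitution

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run. Defaults follow the study design:
    internal-indel threshold 10 residues, 10,000 bootstrap replicates,
    Bonferroni adjustment."""

    cds_fasta: Optional[str] = None
    catalog_tsv: Optional[str] = None
    selected_tsv: Optional[str] = None
    alignment_path: Optional[str] = None
    alignment_format: str = "fasta"          # "fasta" or "tsv"
    ddg_tsv: Optional[str] = None
    microcolony_tsv: Optional[str] = None
    include_start_codon: bool = True
    position_range: Optional[Tuple[int, int]] = None
    max_internal_indel: int = 10
    bootstrap_B: int = 10_000
    adjust_method: str = "bonferroni"
    restrict_natural_to_accessible: bool = False
    seed: int = 0
    outdir: str = "erovar_out"

    def snapshot(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def run_pipeline(config: PipelineConfig) -> Dict[str, dict]:
    """Execute all stages for which inputs are configured.

    Returns the report bundle (also written as JSON/TSV files under
    ``config.outdir``): a variant report (consequence + molecular weight per
    catalogued allele), a conservation report (%MT/%WT and occurring
    residues per selected substitution), a class-comparison report
    (Kruskal-Wallis + Dunn over the ddG classes), and a survival report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: Dict[str, dict] = {"config": config.snapshot()}

    if config.cds_fasta is None:
        raise FileNotFoundError("pipeline stage 'sequence': no CDS FASTA configured")
    cds = read_cds_fasta(config.cds_fasta)
    ref_protein = translate(cds)

    # --- variant report -----------------------------------------------------
    selected_subs = []
    if config.catalog_tsv:
        catalog = read_variant_catalog(config.catalog_tsv)
        rows = []
        for row in catalog.itertuples(index=False):
            mutated = apply_mutation(cds, row.mutation)
            prot = translate(mutated)
            cons = protein_consequence(ref_protein, prot)
            rows.append(
                {
                    "allele_name": row.allele_name,
                    "consequence_class": cons.klass,
                    "consequence": cons.describe(),
                    "protein_length_aa": len(prot),
                    "mol_wt_kda": molecular_weight_kda(prot),
                    "selection_class": getattr(row, "selection_class", ""),
                }
            )
            if cons.klass == "substitutions" and len(cons.substitutions) == 1:
                p, w, m = cons.substitutions[0]
                selected_subs.append(AaSubstitution(position=p, wt=w, mut=m))
        bundle["variant_report"] = {"alleles": rows}
    if config.selected_tsv:
        import pandas as pd

        sel_df = pd.read_csv(config.selected_tsv, sep="\t")
        selected_subs = [
            AaSubstitution(position=int(r.position), wt=str(r.wt), mut=str(r.mut))
            for r in sel_df.itertuples(index=False)
        ]
    elif not selected_subs:
        # no catalog-derived substitutions: fall back to the packaged
        # selected set only when the reference is the packaged gene
        selected_subs = [
            s for s in heat_selected_substitutions()
            if s.position <= len(ref_protein)
            and ref_protein.residues[s.position - 1] == s.wt
        ]

    # --- accessibility ------------------------------------------------------
    acc = enumerate_accessible(
        cds,
        include_start_codon=config.include_start_codon,
        position_range=config.position_range,
    )
    write_accessible_tsv(outdir / "accessible.tsv", acc)
    bundle["accessibility"] = {
        "n_substitutions": len(acc),
        "convention_flags": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in acc.convention_flags.items()},
    }

    # --- conservation -------------------------------------------------------
    profile = None
    if config.alignment_path:
        reader = (read_alignment_fasta if config.alignment_format == "fasta"
                  else read_alignment_wide_tsv)
        aln = reader(config.alignment_path, reference_id=cds.id)
        n_before = len(aln)
        aln = filter_orthologs(aln, max_internal_indel=config.max_internal_indel)
        log.info("indel filter: %d -> %d entries", n_before, len(aln))
        profile = build_profile(aln)
        rows = []
        # deduplicate substitutions for the report
        seen = set()
        for sub in selected_subs:
            if (sub.position, sub.mut) in seen:
                continue
            seen.add((sub.position, sub.mut))
            mt, wt = percent_mt_wt(profile, sub)
            occ = position_summary(profile, sub.position).occurring_residues
            rows.append(
                {
                    "mutation": str(sub),
                    "pct_mt": mt,
                    "pct_wt": wt,
                    "occurring_residues": ", ".join(sorted(occ)),
                }
            )
        bundle["conservation_report"] = {
            "n_entries_before_filter": n_before,
            "n_entries_retained": len(aln),
            "rows": rows,
        }

    # --- stability classes + comparison ------------------------------------
    if config.ddg_tsv and profile is not None:
        ddg = read_ddg_tsv(config.ddg_tsv)
        classes = assemble_variant_classes(
            acc, profile, selected_subs, ddg,
            restrict_natural_to_accessible=config.restrict_natural_to_accessible,
        )
        results = StabilityClassModel.from_classes(classes).fit(
            adjust=config.adjust_method
        )
        report = results.to_dict()
        report["class_sizes"] = classes.sizes()
        report["n_missing_accessible_ddg"] = classes.n_missing_accessible
        report["natural_restricted_to_accessible"] = (
            classes.natural_restricted_to_accessible
        )
        bundle["class_comparison"] = report

    # --- single-cell survival ----------------------------------------------
    if config.microcolony_tsv:
        cells = read_microcolony_tsv(config.microcolony_tsv)
        res = MicrocolonySurvivalModel(cells).fit(
            B=config.bootstrap_B, seed=config.seed,
            adjust=config.adjust_method,
        )
        bundle["survival_report"] = res.to_dict()

    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
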