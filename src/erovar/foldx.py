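"""Interface-only adapter for an external structure-based ddG predictor.

The stability predictor (FoldX) is licensed external software; this module
only emits the mutation-list file its BuildModel/PositionScan commands
expect and parses the tabular output back into StabilityRecord objects. It
never invokes the predictor and performs no energy computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from .accessibility import AaSubstitution
from .stability import MutationCode, StabilityRecord, aggregate_repeats


def write_individual_list(
    path, substitutions: Sequence[AaSubstitution], chains: Sequence[str] = ("A",)
) -> None:
    """Write an ``individual_list.txt`` (one semicolon-terminated line per
    mutant; homomultimer chains listed comma-separated)."""
    lines = []
    for sub in substitutions:
        codes = ",".join(
            f"{sub.wt}{chain}{sub.position}{sub.mut}" for chain in chains
        )
        lines.append(codes + ";")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_ddg_output(
    path, n_repeats_expected: int = 3
) -> Dict[Tuple[int, str], StabilityRecord]:
    """Parse a whitespace-delimited predictor output of repeated runs.

    Expected columns: mutation code, then one ddG value per repeat (kcal/mol).
    Repeats are aggregated to mean and sample SD.
    """
    out: Dict[Tuple[int, str], StabilityRecord] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        from .stability import parse_foldx_code

        code = parse_foldx_code(parts[0].rstrip(";").split(",")[0])
        values = [float(v) for v in parts[1:]]
        mean, sd = aggregate_repeats(values)
        out[(code.position, code.mut)] = StabilityRecord(
            code=code, ddg_mean=mean, ddg_sd=sd, n_repeats=len(values)
        )
    return out
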