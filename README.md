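# erovar

In-silico analysis of **erosive gene variants** — mutations that destroy a
protein's fold and yet behave as gain-of-function alleles, because the
misfolded product preemptively triggers the heat-shock response and makes
the cell heat resistant. The model system is tryptophanase (TnaA) of
*Escherichia coli* K-12 MG1655: a nonessential enzyme in which directed
evolution under heat stress repeatedly fixed destabilising point mutations,
indels, and frameshifts.

The package is aimed at microbial geneticists and protein-evolution
researchers who want to reproduce or extend this style of analysis:

* **seqcore** — apply DNA-level mutations (substitution / deletion /
  insertion, 1-based inclusive coordinates), translate, classify the
  protein consequence (substitutions, in-frame indels, nonsense
  truncation, frameshift with novel tail), and compute average molecular
  weights.
* **accessibility** — enumerate the *single-nucleotide-accessible missense
  landscape*: every amino acid substitution reachable by exactly one
  nucleotide change (2,816 unique substitutions for the reference gene;
  2,766 when restricted to crystal-resolved positions 9–471).
* **conservation** — build a natural-occurrence background from a
  reference-anchored ortholog alignment: internal-indel outlier filtering
  (strict >10-residue cutoff), per-position occurrence counts, %MT/%WT,
  and the rule that a substitution is *naturally occurring* iff its mutant
  residue appears in at least one retained ortholog.
* **stability** — ΔΔG records in the FoldX mutation-code dialect
  (`KA5A` = Lys, chain A, position 5 → Ala), repeat aggregation, chain
  collapsing, and assembly of the heat-selected / accessible / natural
  variant classes.
* **groupstats** — Kruskal-Wallis with Dunn's post hoc z-tests
  (Bonferroni-adjusted by default), two-sample Kolmogorov-Smirnov,
  10,000-replicate bootstrap standard errors of survival fractions, the
  logarithmic reduction factor log₁₀(N₀/N), and a statsmodels-style
  `MicrocolonySurvivalModel` for single-cell survival/resuscitation data.
* **synthetic** — seeded generators for every input class, so the full
  pipeline is testable without any download.
* **cli** — `erovar` with subcommands `mutate`, `enumerate`, `conserve`,
  `classify`, `compare`, `singlecell`, `simulate`, `run`.

## Worked example

```python
import erovar
from erovar.datasets import load_tnaa_cds

cds = load_tnaa_cds()
ref = erovar.translate(cds)                      # 471-aa protein

# a heat-selected point mutation: G1075C
mut = erovar.apply_mutation(cds, erovar.MutationSpec(
    kind="substitution", position=1075, ref_base="G", alt_base="C"))
prot = erovar.translate(mut)
cons = erovar.protein_consequence(ref, prot)
print(cons.describe(), erovar.molecular_weight_kda(prot))
# A359P 52.8     <- alanine 359 -> proline, 52.8 kDa product

print(len(erovar.enumerate_accessible(cds)))
# 2816           <- unique missense substitutions one nucleotide away

# single-cell survival at the study's design scale (synthetic data with a
# generative survival ratio of 1.9 and a 2.5 h lag shift)
from erovar.synthetic import SyntheticSpec, gen_microcolonies
cells = gen_microcolonies(SyntheticSpec(seed=1))
res = erovar.MicrocolonySurvivalModel(cells).fit(B=10_000, seed=1)
print(res.summary())
```

```
Single-cell survival and resuscitation
==============================================
SE method: per-cell bootstrap (B = 10000)

bin                        n  surv    frac      SE
PA_minus_induced         546   238   0.436   0.021
PA_minus_noninduced      280   137   0.489   0.030
PA_plus_induced           78    69   0.885   0.036

PA+/PA- survival ratio (induced arm): 2.029
median lag PA_minus_induced: 4.54 h (n = 238 survivors)
median lag PA_minus_noninduced: 4.46 h (n = 137 survivors)
median lag PA_plus_induced: 1.69 h (n = 69 survivors)

Pairwise KS on resuscitation times (Bonferroni-adjusted):
  PA_minus_induced vs PA_minus_noninduced: D = 0.067, p_raw = 0.798, p_adj = 1 ns
  PA_minus_induced vs PA_plus_induced: D = 0.898, p_raw = 5.41e-53, p_adj = 1.62e-52 **
  PA_minus_noninduced vs PA_plus_induced: D = 0.913, p_raw = 3.23e-49, p_adj = 9.7e-49 **
```

Reading the table: aggregate-bearing (PA⁺) siblings survive the heat
challenge about twice as often as their aggregate-free (PA⁻) siblings and
resuscitate ~2.8 h faster (this seed); the non-induced arm is statistically
indistinguishable from the induced PA⁻ bin, as expected when the founder's
elevated chaperone levels have dampened out.

The same analyses run from the shell:

```bash
erovar simulate --seed 11 --outdir fixtures/
erovar run --cds fixtures/reference_cds.fasta \
           --alignment fixtures/orthologs.afa --ddg fixtures/ddg.tsv \
           --selected fixtures/selected.tsv \
           --outcomes fixtures/microcolonies.tsv --outdir report/
```

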