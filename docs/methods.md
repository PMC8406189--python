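# Methods

`erovar` reimplements, as a tested library, the in-silico half of an
analysis of *erosive* gene variants — mutations that wreck a protein's fold
yet act as gain-of-function alleles because the misfolded product
preemptively triggers the heat-shock response. The reference system is
tryptophanase (TnaA) of *Escherichia coli* K-12 MG1655: a nonessential,
stationary-phase-expressed enzyme in which heat selection repeatedly fixed
destabilising mutations.

## Sequence model and consequence calling

A `CodingSequence` is a validated A/C/G/T string; reference-origin
sequences must be in frame with a terminal stop, mutated-origin sequences
may have any length ≥ 1 (frameshifts are first-class). All coordinates are
1-based and deletion ranges inclusive. Translation always starts in frame 0
and does not require ATG initiation: mutated alleles keep the native start,
and re-calling starts is not part of the analysis. Translation halts at the
first stop codon, or at the last complete codon when a frameshift removed
the stop; 1–2 trailing nucleotides are ignored. Stop-codon read-through is
never modelled.

`protein_consequence(ref, alt)` anchors the longest common prefix and
suffix of the two proteins. Equal length ⇒ substitution list; a strict
prefix ⇒ nonsense truncation; a contiguous gained block ⇒ in-frame
insertion; a contiguous lost block (optionally with one flanking
substitution) ⇒ in-frame deletion; a shared prefix followed by total
divergence ⇒ frameshift, whose `novel_tail_length` counts residues read in
the shifted frame before its first stop. Anything else is `complex`.

The flanking-substitution deletion case is not cosmetic. A 318-bp deletion
of nucleotides 188–505 is not codon-aligned: it merges the broken halves of
codons 63 (ATG) and 169 (GGC) into AGC, a serine. The product is therefore
365 aa — a net loss of 106 residues — and the derived consequence is M63S
plus an in-frame deletion of residues 64–169. The catalog's verbal
description of this allele ("105 aa, 64–168") implies a 366-aa product at
40.7 kDa, which contradicts the catalog's own 40.6 kDa mass cell; the
40.6 kDa value matches the 365-aa product derived here, so the derivation,
not the verbal description, is taken as authoritative.

## Molecular weight

Masses are average (isotope-abundance-weighted) residue masses plus one
water, using the standard ExPASy table frozen in
`seqcore.AVERAGE_RESIDUE_MASSES`; display rounding is half-up to 0.1 kDa.
Under this convention 14 of the 17 catalogued mass cells reproduce exactly,
including all four truncated products (40.6, 49.3, 50.4, 32.2 kDa) and the
wild-type subunit at 52.8 kDa (52,773.4 Da, the canonical value for this
protein). Three cells (the two Gln→Pro substitutions, reported 52.8 vs
52.7 computed; the one-residue Tyr insertion, reported 53.0 vs 52.9)
disagree by exactly one display step. No constant offset to the mass sum
can reconcile all 17 cells simultaneously (the insertion cell needs
≥ +14 Da while the 365-aa deletion cell tolerates < +13.7 Da), so the three
outliers reflect the original mass tool's own convention, sitting ~15 Da
above the residue-mass sum. The package keeps the standard table and
documents the three borderline cells rather than fitting a bespoke one.

## Missense accessibility

`enumerate_accessible` walks every sense codon, applies each of the nine
single-nucleotide changes, and keeps unique (position, wt, mut) pairs that
are neither synonymous nor stop-gains; the terminal stop codon is skipped
and the initiator codon is included by default. Deduplication is on
(position, mut) — the number of distinct nucleotide paths to a substitution
is kept as an annotation, not multiplicity. Stop-gains are excluded because
the landscape feeds a structure-based stability predictor that presupposes
full-length proteins.

For the reference gene this yields **2,816** unique substitutions over the
471 sense codons. The originally reported landscape size is 2,765. No
combination of sequence-level convention flags (start codon in/out,
terminal-codon handling) reproduces that number; the closest interpretable
convention — restricting to positions 9–471, i.e. dropping the N-terminal
residues typically unresolved in the 2oqx crystal used for ΔΔG scoring —
gives 2,766, one away. The default convention therefore stays at the full
sequence, the `position_range` flag exposes the restriction, and both
counts are reported; the discrepancy (51 of 2,765, 1.8%, or 1 under the
restricted convention) is treated as the documented convention delta. The
slow oracle (apply every point mutation with the generic mutation
machinery, translate the whole sequence, diff proteins) lives in the test
suite only and must agree exactly with the fast path on random CDSs.

## Conservation background

An `OrthologAlignment` maps ortholog ids to one residue per reference
position (gap `-`), with optional recorded insertion blocks. The outlier
filter removes entries whose longest **internal** indel — a maximal gap run
or insertion block touching neither terminus — strictly exceeds 10
residues; leading/trailing gap runs are length variants, not internal
indels. Percentages use the number of retained entries as denominator
(gapped entries included): that rule makes a single occurrence among 218
entries display as 0.5%, matching the reported occurrence table. Display
rounding is half-up to one decimal, but the naturalness classifier compares
raw counts, never rounded percentages: a substitution is *naturally
occurring* iff its mutant residue appears in ≥ 1 retained ortholog. Whether
the reference itself is among the entries is deliberately left to the
input; all outputs are functions of the provided entries.

The real 218-ortholog alignment is a supplementary spreadsheet that is not
redistributable here, so the conservation numbers attached to it are
exercised against constructed and synthetic backgrounds with known truth;
passing those tests shows the counting and classification rules are exact,
not that any particular biological alignment was reproduced.

## Stability classes

ΔΔG values are consumed, never computed: the predictor (FoldX) is licensed
external software. `parse_foldx_code` handles the `KA5A` dialect
(wt, chain, position, mut); repeats aggregate to mean and sample SD (n−1;
SD 0 for a single repeat). Homomultimer chains are collapsed onto
(position, mut) by averaging per-chain records. Three classes are
assembled: heat-selected (a missing record is an error), accessible, and
natural (records whose substitution occurs in the background). Naturalness
is independent of accessibility by default; a flag can restrict the natural
class to single-nucleotide-accessible substitutions, and the choice is
recorded in the output metadata. No ΔΔG significance cutoff is imposed —
the raw distributions are exposed and compared.

## Statistics

* **Kruskal-Wallis + Dunn.** H and its chi-square p come from
  `scipy.stats.kruskal` (tie-corrected). Dunn's pairwise z-statistics are
  computed in-package from pooled mean ranks with the tie correction
  Σ(t³−t)/(12(N−1)); two-sided normal p-values are Bonferroni-adjusted by
  default (configurable, e.g. Holm via statsmodels). Significance tiers are
  `*` at 0.05 and `**` at 0.01. An all-identical input returns H = 0,
  p = 1 rather than an error. The original figure does not name its Dunn
  correction; Bonferroni is the package default because that correction is
  used throughout the study's other comparisons.
* **KS tests.** Two-sample, asymptotic p (`scipy.stats.ks_2samp`,
  `method="asymp"`); exact small-sample p-values are not needed at the
  sample sizes involved. Resuscitation-time comparisons are
  Bonferroni-adjusted over the number of comparisons made.
* **Bootstrap SE of a fraction.** n outcomes resampled with replacement
  B = 10,000 times (the study's replicate count); the SE is the SD of the
  B fractions. Seeded and deterministic; chunked to bound memory.
* **Survival analysis.** Cells bin into (induced PA⁺, induced PA⁻,
  non-induced PA⁻). The PA⁺/PA⁻ survival ratio is computed within the
  induced arm and is undefined (error) when the PA⁻ fraction is 0. Lag
  distributions cover survivors only. The original per-colony
  random-effects model (GLMM) is out of scope; the package substitutes a
  colony-clustered bootstrap (resample colonies, then cells within
  colonies), labelled as such in the output. The default SE estimator is
  the study's own per-cell bootstrap.
* **Log reduction.** log10(N0/N); N = 0 raises an error directing callers
  to the 1,000 CFU/ml quantification limit.

## Synthetic data

Generators are seeded with a single top-level seed fanned out to fixed
per-generator streams (PCG64), so adding a generator never disturbs
existing fixtures. `gen_cds` builds ATG + uniform sense codons + one stop.
`gen_ortholog_alignment` keeps the reference residue with per-position
probability `conservation` (default 0.8, a mid-range identity for a
bacterial enzyme family) and otherwise draws a uniform different residue;
internal gap runs of configurable length are injected into a configurable
fraction of entries to exercise the indel filter. `gen_ddg_table` draws
three per-repeat values N(class mean, sd) per substitution with class
location shifts (defaults: selected 5.0, accessible 1.5, natural 0.5
kcal/mol, sd 1.0 — ordered as the real classes are). `gen_microcolonies`
emulates the single-cell experiment at its design scale: 78 induced + 35
non-induced colonies of 2³ = 8 cells (≈3 generations), exactly one PA⁺
cell per induced colony, survival Bernoulli(0.48) for PA⁻ and
Bernoulli(1.9 × 0.48) for PA⁺, and lognormal lag times (log-median 2 h,
σ = 0.4) with the PA⁻ bins shifted +2.5 h so the PA⁺/PA⁻ median lag
difference equals the shift by construction. The generative survival ratio
(1.9) and lag shift (2.5 h) are the study's reported effect sizes; the
generator does not model segregation of aggregates over generations,
colony-level correlation of survival, censoring at the 8-h observation
window, or measurement error in lag calling — so recovery tests validate
the estimators, not the biology.

## Problem sizes and numerical choices

The test suite runs the brute-force accessibility oracle on 100 random
CDSs of ≤ 50 codons, calibrates the Kruskal-Wallis type-I error on 1,000
null simulations (3 × n = 20), and recovers the survival ratio and lag
shift over 200 seeded replicates at the design scale above; these sizes
give stable Monte-Carlo bands while keeping the whole suite in seconds.
Bootstrap SEs inside the replicate loops use B = 50 (only point estimates
are consumed there); headline SEs use B = 10,000. Ties in ranks use
average ranks; rounding for display is always half-up (never banker's);
classification logic never consumes rounded values.

## Known limitations

* The three mass cells and the landscape-size discrepancy discussed above.
* The real ortholog alignment, the exhaustive ΔΔG table, and the raw
  single-cell outcomes are not redistributable/deposited; those analyses
  are validated on synthetic inputs with known truth.
* The colony-clustered bootstrap is an approximation to a random-effects
  model; with few colonies it can underestimate between-colony variance.
* The FoldX adapter is interface-only (mutation-list emission and output
  parsing) and is not exercised against the real predictor.
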