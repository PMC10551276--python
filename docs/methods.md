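# Methods

## Coordinate model and annotation

All coordinates are rCRS (NC_012920.1) 1-based inclusive; mutations are
written `<ref><position><alt>` on the heavy strand (e.g. `G1888A`). The
feature table is embedded as a compiled-in constant: 13 protein genes, 22
tRNAs, 2 rRNAs, and the control region, which is modeled as one feature with
two segments (16024–16569 and 1–576) so wrap-around positions classify
identically. Known gene overlaps (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4,
MT-ATP6/MT-CO3 at 9207, TRNC/TRNY at 5826) are preserved rather than
truncated.

**Overlap tie-break.** When a position falls in more than one gene, the
*primary* assignment is the feature with the smaller start coordinate; all
overlapping features are always reported so callers can re-count under a
different convention. This is a deterministic package choice — cohort
reports that attribute each mutation to one gene must pick something, and
smallest-start is auditable.

**Region dichotomy.** `coding` means the primary feature is a protein gene;
control region, rRNA, tRNA and intergenic positions are `noncoding`. This
matches the convention of tabulating rRNA/tRNA mutations under noncoding.

**Codon effects.** Translation uses the vertebrate mitochondrial genetic
code (NCBI table 2). Light-strand genes (MT-ND6 among the proteins) are
reverse-complemented before codon extraction; the reading frame starts at
the gene's first base. Trailing incomplete codons (several mitochondrial
stop codons are completed post-transcriptionally by polyadenylation) yield
undefined amino-acid fields rather than an error. The observation's ref base
is checked against the supplied reference and a mismatch is a hard error.
No genuine rCRS sequence ships with the package; annotation is
sequence-free except for codon effects, which accept any caller-supplied
16,569-bp FASTA. The test suite exercises the machinery with a clearly
labelled synthetic random reference against an independent whole-CDS
translation oracle.

## Filters and somatic calling

* **Sample coverage**: a sample participates only if mean coverage is
  *strictly greater than* 1000×.
* **Variant support**: variants with fewer than 100 mutant reads are
  discarded; exactly 100 reads is kept.
* **Somatic definition**: a tumor variant is somatic iff no observation with
  the identical (position, ref, alt) triple exists in the filtered matched
  normal, and the triple is not flagged as a haplogroup marker in the
  known-variant table. Matching is **allele-level**: a normal-side variant
  at the same position with a different alt does not suppress the tumor
  variant. Calling without a matched normal is a hard error; excluded
  samples drop their patient from the cohort run with a recorded reason.

**MAF vs alt fraction.** `maf_percent = alt_reads / ref_reads × 100` is a
mutant-to-wild-type *ratio* (not the conventional mutant/total fraction);
it is kept because ratio-style MAF tables exist in the mtDNA literature and
round-tripping them requires it. It is unbounded and undefined at fully
mutant sites, where a `None` sentinel is stored and the mutation is
retained (fully homoplasmic sites are biologically meaningful). The bounded
`alt_fraction = alt / (alt + ref)` is carried separately and drives
heteroplasmy classification. Zero reads on both alleles is a validation
error (no evidence).

**Homoplasmy threshold.** A mutation is homoplasmic when its alt fraction
is ≥ 0.95. The threshold is not a literature constant; 0.95 is this
package's default, prominently configurable (`FilterConfig`,
`--homoplasmy-threshold`). At the cohort level a *distinct* mutation counts
as homoplasmic if it is homoplasmic in at least one carrier (the
"any-carrier" convention); this choice is monotone in the threshold, which
the property tests rely on.

## Cohort statistics

Two counting modes are kept explicit and never mixed: spectrum, region,
complex, substitution and homoplasmy totals count **distinct mutation
types** (a mutation shared by k patients counts once); mutational loads
count **per-patient occurrences** divided by group size
(`load = Σ_patients |mutations in region| / group size`, reported to one
decimal). Per-mutation frequency is carriers / cohort size.

**Rounding.** All report percentages use half-up rounding to integers
(12/32 → 38%), loads half-up to one decimal. Published tables this package
mirrors are not always consistent with any single policy (e.g. 13/23
printed as 56% where half-up gives 57%); the strict policy is applied
everywhere and this known divergence is accepted.

**Hotspot panel.** Mutations with cohort frequency ≥ `min_frequency`
(default 0.19), ordered by descending frequency then position. The example
panel in `mitoprofile.datasets` names eleven members; eight are individually
documented mutations (A3520C, T3572A, T3599A, T3605A, A10935G, T7953G,
T14894G, T4434G), two are recurrent ND5 mutations reported in matched
tumor/EV profiles (T12922G, A13780G), and one MT-CO3 slot (T9540C) is a
synthetic placeholder; the panel is plain data and fully configurable.

**Novelty / pathogenicity.** Defined purely by lookup in the user-supplied
known-variant table: novel ⇔ absent from the table's reported records;
pathogenic ⇔ flagged there. No online database queries — determinism and
offline testability over completeness.

## EV concordance

Pooled traceability is the union view `|∪ traceable| / |∪ tumor| × 100`
over EV-bearing patients (per-patient fractions are also reported), where a
tumor mutation is traceable if its exact key appears in the patient's
filtered EV profile. EV mutations matching the patient's matched normal are
treated as germline carry-over and excluded from both the traceable and the
EV-exclusive sets, paralleling the somatic definition. EV-exclusive
mutations (EV minus tumor minus normal) are annotated like somatic calls and
flagged in the output catalog. The panel detection rate is the share of
panel mutations found in at least one EV profile; note it is a
detection/sensitivity-style rate, although such rates are sometimes loosely
labelled "specificity" in the biomarker literature.

## Synthetic cohort generator

The generator emulates the study design the pipeline assumes, with defaults
set to the study's conditions: 32 patients split 7 African / 25 European,
9 with EV profiles, group mean somatic loads 7.5 / 4.6 with a hard minimum
of 3 per patient (counts drawn as `min + Poisson(target − min)`, so the
configured mean is exact), mean depth 5000× with negative-binomial
dispersion 10 (floored at 1500× so read support stays far from the filter
thresholds), homoplasmic mixture weight 0.18 (homoplasmic alt fractions
uniform on 0.97–1.0, heteroplasmic uniform on 0.15–0.90 — both kept clear
of the 0.95 boundary so classification is unambiguous at simulated depths),
transition:transversion odds 4:1, EV detection probability 0.38, and
EV-exclusive counts Poisson(11/9).

**Haplogroup marker pool.** Haplogroup variants are population-level sites,
so the generator draws one fixed pool of 400 marker variants per cohort and
gives each patient a homoplasmic subset (Poisson mean 30) shared across the
patient's normal, tumor and EV profiles. Somatic and EV-exclusive positions
never land on pool sites — mirroring the caller's marker-exclusion step and
making the truth ledger exactly recoverable when read support is far from
the thresholds (the recovery tests assert sensitivity = precision = 1
there).

**Position weighting.** Somatic positions are sampled with per-region-class
weights: the default is proportional to region length; the "paper-like"
preset weights classes to an RCI-dominated profile (RCI 74 : RCIII 11 :
RCIV 30 : RCV 8 : rRNA 25 : tRNA 20, no control-region or intergenic mass).
Read counts are `depth ~ NB`, `alt ~ Binomial(depth, fraction)` — the
simplest model matching the filter semantics.

**What it does not emulate.** No read-level (FASTQ) simulation, sequencing
error, strand bias, NUMT contamination, position-specific mutability, or
linkage between mutations; germline variants are exactly homoplasmic.
Passing recovery tests therefore demonstrates the correctness of the
filtering/calling/aggregation logic under the stated statistical structure,
not robustness to artifacts real amplicon data may contain — those are an
upstream caller's responsibility.

## Example catalogs

`mitoprofile.datasets` rebuilds, at the level of printed counts, the
structure of a published 32-patient cohort (168 distinct mutations: 134
transitions, 123 coding split 74/11/30/8 across RCI/RCIII/RCIV/RCV, 25
rRNA + 20 tRNA noncoding, 31 homoplasmic, 23 novel, 15 pathogenic) and its
9-patient EV sub-study (45 pooled tumor mutations, 17 EV-traceable, 9/11
panel members detected, 11 EV-exclusive with 8 in RCI). Named mutations sit
at their real coordinates; filler entries are synthetic placeholders inside
the correct gene intervals. Two caveats: the source tables are internally
inconsistent about the coding total (123 vs 124; the per-complex counts sum
to 123, which is what the fixture uses, and only the invariant
coding + noncoding = total is asserted) and about the homoplasmic
distribution over noncoding regions (the fixture places the 8 noncoding
homoplasmic mutations in rRNA/tRNA features, since the region split leaves
no control-region mutations).

## Numerical and degenerate-input conventions

* Positions outside 1..16,569, non-ACGT bases, ref = alt, negative read
  counts, and alt + ref > depth are validation errors at construction time.
* An empty cohort yields an empty summary, not an error; zero patients is a
  validation error for frequency/load denominators; an empty hotspot panel
  or absent EV-bearing patients are validation errors for the rates defined
  over them.
* Aggregation is deterministic: patients are visited in sorted order, ties
  broken by position, so identical inputs give byte-identical JSON.
* Percent values are integers (half-up); exact fractions are preserved in
  the underlying fields for anyone who needs them.

## Problem sizes used in tests and the acceptance script

The recovery checks run on 200-patient cohorts (~1100 distinct mutations,
about a second end-to-end); the hotspot-frequency concentration check uses
800 patients; property suites use 25-position random catalogs. These sizes
put binomial standard errors comfortably inside the asserted tolerances
(e.g. ±3 percentage points for shares estimated from ≥300 draws).
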