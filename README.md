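# mitoprofile

Somatic mutation profiling of the human mitochondrial genome (mtDNA) for
matched **normal / tumor / extracellular-vesicle (EV)** sample cohorts, such
as liquid-biopsy studies in triple-negative breast cancer.

The mitochondrial genome (rCRS, NC_012920.1, 16,569 bp) encodes 13 protein
subunits of the OXPHOS respiratory complexes (RCI: *MT-ND1–ND6, ND4L*;
RCIII: *MT-CYTB*; RCIV: *MT-CO1–CO3*; RCV: *MT-ATP6/8*), 22 tRNAs, 2 rRNAs
and the D-loop control region. Deep amplicon sequencing of tumor and matched
normal tissue yields per-sample variant calls; this package takes those calls
(VCF or TSV) and produces the cohort-level mutation profile:

* **Somatic calling.** A variant is somatic when present in the tumor but
  absent from the matched normal, the reference, and a supplied list of
  haplogroup marker variants (inherited lineage variants used for
  haplotyping). Samples must exceed 1000× mean coverage; variants with
  fewer than 100 mutant reads are discarded.
* **Allele quantities.** For mutant read count *m* and wild-type count *w*,
  the mutant-allele frequency is reported as the ratio
  `MAF = m / w × 100` (undefined at fully mutant sites), alongside the
  bounded fraction `f = m / (m + w)` used to classify a mutation as
  **homoplasmic** (`f ≥ 0.95` by default) or **heteroplasmic**.
* **Annotation.** Every mutation is mapped onto the embedded rCRS feature
  table (gene, coding/noncoding class, respiratory complex,
  transition/transversion; codon-level amino-acid effect under the
  vertebrate mitochondrial code when a reference sequence is supplied).
* **Cohort statistics.** Spectrum counts over distinct mutation types,
  per-mutation patient frequencies (half-up integer percents), a hotspot
  panel (frequency ≥ 19% by default), novelty/pathogenicity flags from a
  known-variant table, and per-group mutational loads
  (`mutations observed in group / group size`).
* **Tumor–EV concordance.** Pooled traceability
  `|∪ traceable| / |∪ tumor| × 100` over EV-bearing patients, hotspot-panel
  detection rate in EVs, and EV-exclusive mutations (present in the EV but
  in neither tumor nor normal).
* **Synthetic cohorts.** A seeded generator produces matched
  normal/tumor/EV profiles with a shared haplogroup background, tumor-private
  somatic mutations (≥3 per patient), ~5000× negative-binomial depth, a
  heteroplasmy mixture, configurable EV detection probability — plus a truth
  ledger so every pipeline stage can be scored exactly.

## Worked example

```python
from mitoprofile import SimulationConfig, simulate_cohort, profile_cohort
from mitoprofile.simulate import known_variants_from_ledger

config = SimulationConfig(n_patients=32, seed=5)   # study-shaped defaults
patients, ledger = simulate_cohort(config)
known = known_variants_from_ledger(ledger)
result = profile_cohort(patients, known)

s = result.summary
print(f"distinct somatic muts  : {s.n_distinct_mutations}")
print(f"coding / noncoding     : {s.coding_count} / {s.noncoding_count}")
print(f"transition share       : {s.transition_share}%")
print(f"homoplasmic share      : {s.homoplasmic_share}%")
print(f"loads (per ancestry)   : {s.group_loads}")
print(f"EV traceability        : {result.concordance.traceability_percent}%")
```

prints

```
distinct somatic muts  : 171
coding / noncoding     : 127 / 44
transition share       : 80%
homoplasmic share      : 20%
loads (per ancestry)   : {'African': 7.9, 'European': 4.6}
EV traceability        : 28%
```

i.e. the 32 simulated patients carry 171 distinct somatic mtDNA mutations,
80% of them transitions (the generator's 4:1 transition odds), 20%
homoplasmic (18% mixture weight plus sampling noise), a higher mutational
load in the African-ancestry group (7.9 vs 4.6 mutations per patient, the
configured group means), and 28% of the pooled tumor mutations of the nine
EV-bearing patients were re-detected in their EV profiles (38% detection
probability; the pooled estimate over ~50 mutations is noisy at this cohort
size). `result.per_patient` holds the annotated calls;
`mitoprofile.variants_io.write_annotated_catalog` writes them as a TSV.

The same analysis is available from the shell:

```sh
mitoprofile simulate --out sim/ --seed 5
mitoprofile call --manifest sim/manifest.tsv \
    --known-variants sim/known_variants.tsv --out results/
mitoprofile cohort-stats  --catalog results/annotated_catalog.tsv --out stats.json
mitoprofile ev-concordance --catalog results/annotated_catalog.tsv --out conc.json
```

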