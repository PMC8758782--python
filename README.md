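# ocaphase

Pedigree-based cis/trans phasing and diplotype classification for the *TYR*
p.(Ser192Tyr)/p.(Arg402Gln) haplotype in oculocutaneous albinism type 1
(OCA1).

## The problem

~25–30% of people with a clinical OCA diagnosis carry only one clearly
pathogenic variant — the "missing heritability" of albinism. Two common *TYR*
missense variants, S192Y (allele frequency ~36%) and R402Q (~27%), are
individually benign, but when they sit **in cis** (on the same chromosome
copy) they form a hypomorphic allele: inherited in trans with a null *TYR*
allele it causes partial OCA1B, and in homozygous form a mild but fully
penetrant phenotype. Unphased diagnostic genotypes cannot distinguish cis
from trans, so establishing pathogenicity — and using the haplotype
diagnostically — requires resolving phase through families.

`ocaphase` implements that inference chain as a tested, reusable pipeline for
anyone working on variant phasing in rare recessive disease:

- **core** — PED/VCF/TSV I/O for small variant panels, single-locus Mendelian
  validation (`read_pedigree`, `read_genotypes`,
  `validate_mendelian_single_locus`);
- **phasing** — exact cis/trans resolution from unphased dosages by
  constraint propagation over the pedigree, with a brute-force oracle for
  validation (`solve_pedigree_phase`, `phase_variant_pair`,
  `exhaustive_phase_oracle`);
- **classification** — haplotype → allele type → deterministic phenotype
  prediction with concordance scoring (`haplotype_possible`,
  `classify_diplotype`, `classify_pedigree`);
- **cohort_stats** — aggregation of published cohort counts and Pearson
  chi-squared enrichment testing (`aggregate_cohorts`, `pearson_chi2_2x2`,
  `enrichment_report`);
- **synthetic** — gene-dropping pedigree simulator with population haplotype
  frequency models, plus the packaged four-family fixture
  (`simulate_pedigrees`, `make_fixture_families`).

## The model in brief

For a panel of k ≤ 4 loci treated as recombination-free, each individual's
unphased dosages admit a set of ordered diplotypes (paternal, maternal
haplotype); Mendelian transmission constrains each non-founder's paternal
haplotype to one of the father's two, and likewise maternally. The engine
computes, per individual, the union of diplotypes over all globally
consistent configurations (arc consistency + backtracking), then projects
onto a variant pair: CIS if every surviving configuration puts both alternate
alleles on one haplotype, TRANS if every configuration splits them,
UNINFORMATIVE if both survive, INCONSISTENT if nothing does. Enrichment uses
the classic 2×2 Pearson statistic
χ² = N(|ad−bc| − N/2)²/((a+b)(c+d)(a+c)(b+d)) (Yates-corrected by default).
See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Reproduce the cohort-level analysis from the packaged published count tables:

```sh
$ ocaphase reproduce-tables --out report.json
missing-heritability screening: 144/284 (50.7%)
molecularly diagnosed screening: 2/101 (2.0%)
informative-cohort cis-in-trans: 64/64 (100.0%)
diagnostic uplift: 64/251 (25.5%)
chi-squared (corrected): chi2 = 73.08, p < 2.2e-16
chi-squared (uncorrected): chi2 = 75.13, p < 2.2e-16
```

Reading: half (50.7%) of missing-heritability OCA cases have genotypes
compatible with carrying the S192Y/R402Q cis haplotype, against 2.0% of
molecularly diagnosed cases — a massive enrichment (p below the software
reporting floor). In every one of the 64 phaseable cases the haplotype was
confirmed in cis and in trans to the pathogenic variant, i.e. it completes
the molecular diagnosis in 25.5% of all missing-heritability cases.

The same stages run on family data. Simulate an Amish-like pedigree, phase
it, and classify:

```sh
ocaphase simulate --families 3 --generations 3 --population AMISH \
    --seed 1 --out-dir sim/
ocaphase phase --ped sim/pedigree.ped --geno sim/genotypes.tsv \
    --pair S192Y,R402Q --also-anchor M252R --out calls.tsv
ocaphase classify --ped sim/pedigree.ped --geno sim/genotypes.tsv \
    --pheno-sidecar sim/labels.tsv --out predictions.tsv
```

`calls.tsv` holds one phase call per individual (CIS / TRANS /
UNINFORMATIVE / NOT_DOUBLE_HET), `predictions.tsv` the phenotype predictions
(COMPLETE_OCA, PARTIAL_OCA1B, MILD_HYPOMORPHIC, UNAFFECTED_CARRIER,
UNAFFECTED, INDETERMINATE) with per-individual concordance against the
observed labels.

From Python, the packaged four-family fixture runs end to end:

```python
from ocaphase import (make_fixture_families, solve_pedigree_phase,
                      classify_pedigree)

fix = make_fixture_families()
solution = solve_pedigree_phase(fix.pedigree, fix.genotypes, fix.panel)
predictions, summary = classify_pedigree(fix.pedigree, solution,
                                         fix.genotypes, fix.panel)
print(summary["concordant"], "of", summary["n"], "concordant")
# 34 of 34 concordant
```

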