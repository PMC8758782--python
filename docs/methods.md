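# Methods

## Problem and model

Oculocutaneous albinism type 1 (OCA1) is recessive: a phenotype requires two
functionally compromised *TYR* alleles. Two common missense variants,
p.(Ser192Tyr) (S192Y, population allele frequency ~0.36) and p.(Arg402Gln)
(R402Q, ~0.27), are individually benign but form a hypomorphic allele when
they sit on the same chromosome copy (in *cis*). Whether a patient carries
that cis haplotype cannot be read from unphased genotypes: a double
heterozygote may carry S192Y+R402Q on one haplotype (cis) or one variant on
each (trans). This package implements the inference chain that resolves that
ambiguity from family data and quantifies the haplotype's contribution at
cohort level.

The genetic model is deliberately minimal and matches how segregation is read
off a pedigree by hand:

- a panel of 2–4 biallelic loci in one gene (default: S192Y, M252R, R402Q
  spanning ~106 kb of *TYR* on chromosome 11, GRCh38 coordinates);
- no recombination within the panel span in any meiosis (per-meiosis
  recombination over ~106 kb is ~1e-3; within a single pedigree an apparent
  recombinant is overwhelmingly more likely to be a genotyping or sample
  error, so it surfaces as an INCONSISTENT pedigree rather than being
  silently explained);
- faithful transmission: de novo mutation and genotyping error are not
  modelled. Single-locus Mendelian violations are detected first and the
  offending child genotypes are excluded from phasing;
- deterministic penetrance given the diplotype (below).

## Phase resolution

Every individual's unphased dosages admit a set of ordered (paternal,
maternal) haplotype pairs: 2^h orderings for h heterozygous loci, times 4 per
missing locus. Transmission adds binary constraints: a non-founder's paternal
haplotype must be one of the father's two haplotypes, and likewise on the
maternal side. The solver computes, per individual, the union of states
attained in at least one globally consistent assignment:

1. arc-consistency (AC-3) pruning over all child–parent constraint arcs;
2. per connected component, either direct enumeration of all consistent
   assignments (when the product of pruned domain sizes is at most
   `max_exhaustive`, default 4096) or witness search: for each surviving
   state, a backtracking satisfiability check with that state pinned, with
   every found solution marking all of its states as witnessed.

Individuals are processed parents-before-children in sorted-iid order, and
candidate states in sorted order, so output is bit-for-bit reproducible. A
brute-force oracle with the identical contract (plain depth-first enumeration
of all joint assignments, no pruning) is part of the public API and refuses
pedigrees above 10 members; solver–oracle equivalence is property-tested on
random pedigrees, with and without injected genotype corruption.

Pair-level calls project the surviving states onto two loci. A state is
cis-type if some haplotype carries the alternate allele at both loci. An
individual carrying both variants is called CIS if only cis-type states
survive, TRANS if only trans-type, UNINFORMATIVE if both kinds survive, and
INCONSISTENT if the pedigree admits no global configuration. Carriers with a
hom-alt dosage at either locus are phase-forced and report CIS without family
information — the study's affected compound heterozygotes are exactly this
case (S192Y 1, R402Q 2, because the null allele also carries R402Q).
Individuals lacking either variant report NOT_DOUBLE_HET. `n_cis_configs` /
`n_trans_configs` count surviving per-individual unordered states of each
kind, not global configurations (whose count is exponential in pedigree
size); the call semantics only need existence, which the union preserves
exactly.

Phase calls are order-invariant in the pair, monotone under added relatives
(UNINFORMATIVE can resolve; CIS/TRANS never flip), and sound on simulations
(zero contradictions of truth phase in the no-error regime) — all three are
tested.

## Allele typing and penetrance

Each haplotype reduces to an allele type: NULL_PATHOGENIC if it carries any
null-class variant (M252R; the R402Q it also carries does not soften this),
HYPOMORPHIC_CIS if it carries both hypomorphic-component variants,
SINGLE_VARIANT for exactly one variant, REFERENCE otherwise. The unordered
allele-type pair maps deterministically to a phenotype prediction:

| diplotype                  | prediction         |
|----------------------------|--------------------|
| null / null                | COMPLETE_OCA       |
| null / cis-haplotype       | PARTIAL_OCA1B      |
| cis / cis                  | MILD_HYPOMORPHIC   |
| null / single or reference | UNAFFECTED_CARRIER |
| cis / single or reference  | UNAFFECTED_CARRIER (extrapolated) |
| single/reference pairs     | UNAFFECTED         |

Penetrance is modelled as fully deterministic: no probability parameter is
exposed. Apparent non-penetrance of the cis-haplotype homozygote in the
literature is treated as a phenotyping-depth artefact (the mild phenotype —
foveal hypoplasia, subtle iris transillumination — is easily missed), not as
stochastic penetrance; the simulator can still inject label noise to emulate
misphenotyping. Cis-haplotype-over-single-variant pairings were never
observed in the source families; they default to UNAFFECTED_CARRIER, are
flagged EXTRAPOLATED, and can be overridden per analysis. Predicted-mild vs
observed-unaffected disagreements are tallied separately in concordance
summaries (`mild_counts_affected` controls whether they score as discordant),
since such individuals routinely self-report as unaffected.

An individual is classified only when every surviving phase configuration
implies the same allele-type pair; otherwise the prediction is INDETERMINATE.
This makes classification conservative under unresolved phase and missing
data by construction.

## Cohort statistics

Cohort stages consume count tables, not genotypes (per-individual genotypes
for the published cohorts are not available). Aggregation sums numerators and
denominators across cohorts and reports percentages rounded half-up to one
decimal, matching published table style. The enrichment test is the Pearson
chi-squared on the 2×2 screening table,

    chi2 = N (|ad − bc| − c)^2 / ((a+b)(c+d)(a+c)(b+d)),

with c = N/2 under Yates continuity correction (default on, mirroring the
conventional default of mainstream statistical software for 2×2 tables; the
uncorrected statistic is always reported alongside) and the corrected
difference clamped at zero. p-values come from the chi-squared distribution
with 1 df; the exact double-precision value is kept and a display string
renders the conventional "< 2.2e-16" floor. The implementation is
cross-checked against an independent library routine in tests. On the
packaged counts the test compares 144/284 (50.7%) against 2/101 (2.0%):
chi2 = 73.1 corrected / 75.1 uncorrected, both far past the floor. The
control-cohort comparison (16.9% in unaffected Amish exomes) is not
recomputable because its denominator is not published; the packaged tables
therefore carry only the two fully printed groups.

## Simulator

`simulate_pedigrees` gene-drops founder haplotypes: founders (including
marry-in spouses) draw two haplotypes independently from a population
frequency model; each child receives one uniformly chosen haplotype per
parent, no recombination. Defaults encode the study populations:

- EUROPEAN: marginals S192Y 0.36, R402Q 0.27 (gnomAD v2.1.1); cis haplotype
  0.015, the midpoint of the 1.1–1.9% range estimated for European
  populations (both endpoints reachable via the `cis` parameter); no M252R.
- AMISH: adds the M252R haplotype at 0.0023 (its frequency in an Amish
  control exome dataset), carrying R402Q in cis as observed.

Residual single-variant and reference haplotype masses are solved so the
marginals hold exactly; a negative residual raises an error naming the
violated bound — never silent renormalisation. Structure defaults (3
generations, Poisson sibship with mean 4) reflect the large Amish sibships
that made the study's segregation analysis possible. One seeded NumPy
generator drives all sampling in a fixed order, so a fixed seed yields
byte-identical outputs. Phenotype labels are computed from truth diplotypes
via the deterministic classifier and then corrupted (to UNKNOWN or a wrong
label) with probability `label_noise`.

What the simulator does not emulate: explicit consanguinity loops (endogamy
enters only through founder-haplotype enrichment; the packaged fixture is
loop-free too), recombinant haplotype origins, genotyping error, and
ascertainment bias. Passing tests on simulations therefore demonstrate
correctness of the inference given the model's assumptions, not robustness
to violations of them.

## The packaged family fixture

`make_fixture_families` builds a deterministic four-family pedigree encoding
every textual constraint of the source segregation data: 14 affected (9 in
the large family, in generations IX/X), 13 of them compound heterozygous for
M252R and the cis haplotype (predicted PARTIAL_OCA1B), one M252R homozygote
with complete OCA, and the seven named unaffected relatives (five carrying
M252R with R402Q-only in trans, two with S192Y-only). Parental genotypes are
chosen so the engine resolves every individual's diplotype uniquely. The true
single pedigree diagram is not published as machine-readable text, so
sibship sizes and marriage links beyond those constraints are this package's
own construction — the fixture is synthetic and validates the inference
chain against the reported counts, not the families' actual structure.

## Problem sizes and numerical choices

Property tests run the solver–oracle equivalence on 100+ random pedigrees of
at most 10 members, soundness on 1000 gene-dropped pedigrees (2 generations,
mean sibship 3, alternating population models), and frequency recovery on
10,000 founders within 3 binomial standard errors; these sizes give the
properties real statistical force while keeping the default suite fast.
Haplotype-frequency feasibility uses exact arithmetic on the input floats
with a 1e-9 tolerance on the unit-sum check. Dosage decoding treats any GT
separator as unphased by contract, so pre-phased VCFs cannot leak phase into
the engine. Ties everywhere break by sorted identifier, making every output
deterministic.

## Known limitations

- Hard-constraint phasing only: no likelihood mode, no error tolerance, no
  recombination-aware pedigree likelihoods (Lander–Green/Elston–Stewart).
  At panel scale (≤4 loci, ≤106 kb) these add nothing but failure modes.
- The phenotype model grades no severity differences among null alleles and
  does not model modifier genes or quantitative pigmentation.
- Cohort statistics reproduce published aggregate counts; they cannot
  re-derive per-cohort numbers from raw data that was never deposited.
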