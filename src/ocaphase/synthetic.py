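"""Pedigree and genotype simulation with the statistical structure the
analysis assumes, plus the packaged multigenerational family fixture.

The simulator gene-drops founder haplotypes drawn from a population frequency
model over the three-variant TYR panel (no recombination across the ~106 kb
span), transmits one uniformly chosen haplotype per parent per meiosis, and
labels phenotypes deterministically from the truth diplotypes, optionally
corrupting labels with noise.  Frequency defaults:

* EUROPEAN -- marginal allele frequencies 0.36 (S192Y) and 0.27 (R402Q) as in
  gnomAD v2.1.1, with the S192Y/R402Q in-cis haplotype at 0.015, the midpoint
  of the 1.1-1.9% range estimated for European populations; no M252R.
* AMISH -- additionally an M252R-bearing haplotype at 0.0023 (the frequency in
  an Amish control exome dataset), carrying R402Q in cis as observed.

Residual single-variant and reference haplotype masses are solved so the
marginals hold exactly; an infeasible combination is an error, never a silent
renormalisation.

:func:`make_fixture_families` builds the deterministic four-family fixture
encoding the published segregation pattern: 14 affected individuals (9 in the
large family), 13 of them compound heterozygous for M252R and the S192Y/R402Q
cis haplotype, one M252R homozygote with complete OCA, and seven named
unaffected relatives carrying M252R with only one of the common variants in
trans.  Parental genotypes are chosen so the phasing engine can resolve every
individual's diplotype.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classification import (
    PredictedPhenotype,
    assign_allele_type,
    classify_diplotype,
)
from .core import (
    DataError,
    GenotypeMatrix,
    Individual,
    Pedigree,
    Phenotype,
    Sex,
    TYR_PANEL,
    VariantPanel,
    write_genotypes_tsv,
    write_pedigree,
)
from .phasing import DiplotypeState, Haplotype

__all__ = [
    "Population",
    "HaplotypeFrequencyModel",
    "SimulationConfig",
    "SimulationResult",
    "default_frequency_model",
    "simulate_pedigrees",
    "truth_pair_phase",
    "FixtureFamilies",
    "make_fixture_families",
]


class Population(str, enum.Enum):
    EUROPEAN = "EUROPEAN"
    AMISH = "AMISH"


@dataclass(frozen=True)
class HaplotypeFrequencyModel:
    """Founder haplotype frequencies over the panel loci."""

    panel: VariantPanel
    freqs: tuple[tuple[Haplotype, float], ...]

    def __post_init__(self) -> None:
        haps = [h for h, _ in self.freqs]
        if len(set(haps)) != len(haps):
            raise DataError("duplicate haplotypes in frequency model")
        for h, p in self.freqs:
            if len(h) != len(self.panel):
                raise DataError(f"haplotype {h} does not match panel size {len(self.panel)}")
            if p < 0:
                raise DataError(f"negative frequency {p} for haplotype {h}")
        total = sum(p for _, p in self.freqs)
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"haplotype frequencies sum to {total!r}, not 1")

    def marginal(self, vid: str) -> float:
        """Implied marginal (population) allele frequency of one variant."""
        i = self.panel.index(vid)
        return sum(p for h, p in self.freqs if h[i] == 1)

    def haplotype_frequency(self, hap: Haplotype) -> float:
        for h, p in self.freqs:
            if h == hap:
                return p
        return 0.0

    def as_arrays(self) -> tuple[list[Haplotype], np.ndarray]:
        haps = [h for h, _ in self.freqs]
        probs = np.array([p for _, p in self.freqs], dtype=float)
        return haps, probs


def default_frequency_model(
    population: Population | str = Population.EUROPEAN,
    s192y: float = 0.36,
    r402q: float = 0.27,
    cis: float = 0.015,
    m252r: float = 0.0023,
    panel: VariantPanel = TYR_PANEL,
) -> HaplotypeFrequencyModel:
    """Population frequency model with residual masses solved from marginals.

    ``cis`` is the S192Y+R402Q in-cis haplotype frequency (default the
    midpoint of the estimated 1.1-1.9% European range); the AMISH model adds
    an M252R haplotype carrying R402Q in cis at frequency ``m252r``.  The
    S192Y-only, R402Q-only and reference haplotype masses are solved so the
    marginals hold; any negative residual is reported as the violated bound.
    """
    population = Population(population)
    i_s, i_m, i_r = (panel.index(v) for v in ("S192Y", "M252R", "R402Q"))

    def hap(**alleles: int) -> Haplotype:
        h = [0] * len(panel)
        for vid, a in alleles.items():
            h[panel.index(vid)] = a
        return tuple(h)

    m_mass = m252r if population is Population.AMISH else 0.0
    s_only = s192y - cis
    r_only = r402q - cis - m_mass
    reference = 1.0 - s_only - r_only - cis - m_mass
    bounds = [
        (s_only, f"S192Y-only mass = {s192y} - {cis} = {s_only:.4f}"),
        (r_only, f"R402Q-only mass = {r402q} - {cis} - {m_mass} = {r_only:.4f}"),
        (reference, f"reference mass = 1 - marginals + cis = {reference:.4f}"),
    ]
    for value, desc in bounds:
        if value < 0:
            raise DataError(f"infeasible frequency model: {desc} is negative")
    freqs = [
        (hap(), reference),
        (hap(S192Y=1), s_only),
        (hap(R402Q=1), r_only),
        (hap(S192Y=1, R402Q=1), cis),
    ]
    if m_mass > 0:
        # The Amish null allele carries R402Q on the same chromosome copy.
        freqs.append((hap(M252R=1, R402Q=1), m_mass))
    return HaplotypeFrequencyModel(panel, tuple(freqs))


@dataclass(frozen=True)
class SimulationConfig:
    """Gene-dropping run parameters; a fixed seed gives byte-identical output.

    Sibship sizes are Poisson(``sibship_mean``) per couple; each non-final
    generation child acquires a founder spouse drawn from the same frequency
    model (marry-in, no loops).  ``label_noise`` is the probability that an
    individual's phenotype label is replaced by UNKNOWN or a wrong label.
    """

    n_families: int = 1
    generations: int = 3
    sibship_mean: float = 4.0
    sibship_dist: str = "poisson"
    population: Population = Population.AMISH
    label_noise: float = 0.0
    seed: int = 0
    model: HaplotypeFrequencyModel | None = None

    def resolved_model(self) -> HaplotypeFrequencyModel:
        return self.model if self.model is not None else default_frequency_model(self.population)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        known = {
            "n_families",
            "generations",
            "sibship_mean",
            "sibship_dist",
            "population",
            "label_noise",
            "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"{path}: unknown config fields {sorted(unknown)}")
        if "population" in raw:
            raw["population"] = Population(raw["population"])
        return cls(**raw)

    def defaults_json(self) -> str:
        return json.dumps(
            {
                "n_families": self.n_families,
                "generations": self.generations,
                "sibship_mean": self.sibship_mean,
                "sibship_dist": self.sibship_dist,
                "population": self.population.value,
                "label_noise": self.label_noise,
                "seed": self.seed,
            },
            indent=2,
        )


#: Observed phenotype implied by each deterministic prediction.
_TRUTH_LABEL = {
    PredictedPhenotype.COMPLETE_OCA: Phenotype.AFFECTED_COMPLETE,
    PredictedPhenotype.PARTIAL_OCA1B: Phenotype.AFFECTED_PARTIAL,
    PredictedPhenotype.MILD_HYPOMORPHIC: Phenotype.AFFECTED_MILD,
    PredictedPhenotype.UNAFFECTED_CARRIER: Phenotype.UNAFFECTED,
    PredictedPhenotype.UNAFFECTED: Phenotype.UNAFFECTED,
}


@dataclass
class SimulationResult:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # dosages only; phase masked
    truth: dict[str, DiplotypeState]  # ordered (paternal, maternal) haplotypes
    truth_predictions: dict[str, PredictedPhenotype]
    panel: VariantPanel

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, outdir / "pedigree.ped", outdir / "labels.tsv")
        write_genotypes_tsv(self.genotypes, self.panel, outdir / "genotypes.tsv")
        lines = ["iid\tpaternal\tmaternal"]
        for iid in sorted(self.truth):
            pat, mat = self.truth[iid]
            lines.append(
                f"{iid}\t{''.join(map(str, pat))}\t{''.join(map(str, mat))}"
            )
        (outdir / "truth.tsv").write_text("\n".join(lines) + "\n")


def _dosages(state: DiplotypeState) -> tuple[int, ...]:
    pat, mat = state
    return tuple(p + m for p, m in zip(pat, mat))


def simulate_pedigrees(config: SimulationConfig) -> SimulationResult:
    """Gene-drop founder haplotypes through simulated families.

    Founders (including marry-in spouses) draw two haplotypes independently
    from the frequency model; every child receives one uniformly chosen
    haplotype from each parent with no recombination.  Truth keeps the ordered
    diplotypes; the returned genotype matrix holds dosages only.  Phenotype
    labels come from the deterministic diplotype classifier applied to truth
    and are then corrupted with probability ``label_noise``.
    """
    if config.sibship_dist != "poisson":
        raise DataError(f"unknown sibship distribution {config.sibship_dist!r}")
    rng = np.random.default_rng(config.seed)
    model = config.resolved_model()
    haps, probs = model.as_arrays()
    panel = model.panel

    individuals: dict[str, Individual] = {}
    truth: dict[str, DiplotypeState] = {}

    def draw_founder_diplotype() -> DiplotypeState:
        i, j = rng.choice(len(haps), size=2, p=probs)
        return (haps[i], haps[j])

    def add(iid, fid, father, mother, sex, state) -> None:
        individuals[iid] = Individual(
            fid=fid, iid=iid, father=father, mother=mother, sex=sex
        )
        truth[iid] = state

    for f in range(config.n_families):
        fid = f"F{f + 1}"
        counter = 0

        def new_iid() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}:{counter}"

        father0, mother0 = new_iid(), new_iid()
        add(father0, fid, None, None, Sex.MALE, draw_founder_diplotype())
        add(mother0, fid, None, None, Sex.FEMALE, draw_founder_diplotype())
        couples = [(father0, mother0)]
        for gen in range(1, config.generations):
            next_couples = []
            for father, mother in couples:
                n_children = int(rng.poisson(config.sibship_mean))
                for _ in range(n_children):
                    child = new_iid()
                    pat = truth[father][int(rng.integers(2))]
                    mat = truth[mother][int(rng.integers(2))]
                    sex = Sex.MALE if rng.integers(2) == 0 else Sex.FEMALE
                    add(child, fid, father, mother, sex, (pat, mat))
                    if gen < config.generations - 1:
                        spouse = new_iid()
                        spouse_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                        add(spouse, fid, None, None, spouse_sex, draw_founder_diplotype())
                        if sex is Sex.MALE:
                            next_couples.append((child, spouse))
                        else:
                            next_couples.append((spouse, child))
            couples = next_couples

    # Deterministic labels from truth diplotypes, then optional noise.
    truth_predictions: dict[str, PredictedPhenotype] = {}
    labelled: dict[str, Individual] = {}
    wrong_pool = [
        Phenotype.AFFECTED_COMPLETE,
        Phenotype.AFFECTED_PARTIAL,
        Phenotype.AFFECTED_MILD,
        Phenotype.UNAFFECTED,
    ]
    for iid in sorted(individuals):
        pat, mat = truth[iid]
        predicted, _ = classify_diplotype(
            assign_allele_type(pat, panel), assign_allele_type(mat, panel)
        )
        truth_predictions[iid] = predicted
        label = _TRUTH_LABEL[predicted]
        if config.label_noise > 0 and rng.random() < config.label_noise:
            options = [Phenotype.UNKNOWN] + [p for p in wrong_pool if p is not label]
            label = options[int(rng.integers(len(options)))]
        labelled[iid] = replace(individuals[iid], phenotype_observed=label)

    genotypes = GenotypeMatrix()
    for iid in sorted(individuals):
        for vid, dosage in zip(panel.ids, _dosages(truth[iid])):
            genotypes.set(iid, vid, dosage)
    return SimulationResult(
        pedigree=Pedigree(labelled),
        genotypes=genotypes,
        truth=truth,
        truth_predictions=truth_predictions,
        panel=panel,
    )


def truth_pair_phase(state: DiplotypeState, ia: int, ib: int) -> str | None:
    """True phase of a variant pair in one truth diplotype.

    "CIS" if some haplotype carries both alt alleles, "TRANS" if both alts are
    present but always on opposite haplotypes, None if either alt is absent.
    """
    dosages = _dosages(state)
    if dosages[ia] == 0 or dosages[ib] == 0:
        return None
    return "CIS" if any(h[ia] == 1 and h[ib] == 1 for h in state) else "TRANS"


# ---------------------------------------------------------------------------
# Packaged four-family fixture
# ---------------------------------------------------------------------------

# Haplotypes over (S192Y, M252R, R402Q):
_CIS = (1, 0, 1)  # S192Y/R402Q in cis (hypomorphic allele)
_M = (0, 1, 1)  # M252R null allele, itself carrying R402Q in cis
_RONLY = (0, 0, 1)
_SONLY = (1, 0, 0)
_REF = (0, 0, 0)

_AFF_P = Phenotype.AFFECTED_PARTIAL
_AFF_C = Phenotype.AFFECTED_COMPLETE
_UNAFF = Phenotype.UNAFFECTED

# fid, iid, father, mother, sex, (paternal hap, maternal hap), phenotype
_FIXTURE_ROWS: tuple = (
    # Family 1: M252R homozygote with complete OCA.
    ("1", "IX:31", None, None, "M", (_M, _REF), _UNAFF),
    ("1", "IX:32", None, None, "F", (_M, _REF), _UNAFF),
    ("1", "X:1", "IX:31", "IX:32", "F", (_M, _M), _AFF_C),
    # Family 2: one compound heterozygote.
    ("2", "IX:41", None, None, "M", (_CIS, _REF), _UNAFF),
    ("2", "IX:42", None, None, "F", (_M, _REF), _UNAFF),
    ("2", "X:2", "IX:41", "IX:42", "M", (_CIS, _M), _AFF_P),
    # Family 3: three compound-heterozygous siblings.
    ("3", "IX:51", None, None, "M", (_CIS, _REF), _UNAFF),
    ("3", "IX:52", None, None, "F", (_M, _REF), _UNAFF),
    ("3", "X:3", "IX:51", "IX:52", "M", (_CIS, _M), _AFF_P),
    ("3", "X:4", "IX:51", "IX:52", "F", (_CIS, _M), _AFF_P),
    ("3", "X:5", "IX:51", "IX:52", "F", (_CIS, _M), _AFF_P),
    # Family 4: the large multigenerational family, 9 affected in IX/X.
    ("4", "VIII:1", None, None, "M", (_CIS, _RONLY), _UNAFF),
    ("4", "VIII:2", None, None, "F", (_M, _REF), _UNAFF),
    ("4", "IX:9", "VIII:1", "VIII:2", "M", (_CIS, _M), _AFF_P),
    ("4", "IX:10", "VIII:1", "VIII:2", "F", (_CIS, _M), _AFF_P),
    ("4", "IX:12", "VIII:1", "VIII:2", "M", (_CIS, _M), _AFF_P),
    ("4", "IX:14", "VIII:1", "VIII:2", "F", (_CIS, _M), _AFF_P),
    ("4", "IX:2", "VIII:1", "VIII:2", "F", (_RONLY, _M), _UNAFF),
    ("4", "IX:21", "VIII:1", "VIII:2", "M", (_RONLY, _M), _UNAFF),
    ("4", "VIII:3", None, None, "M", (_CIS, _REF), _UNAFF),
    ("4", "VIII:9", None, None, "F", (_M, _RONLY), _UNAFF),
    ("4", "IX:15", "VIII:3", "VIII:9", "M", (_CIS, _M), _AFF_P),
    ("4", "IX:16", "VIII:3", "VIII:9", "F", (_CIS, _M), _AFF_P),
    ("4", "IX:20", "VIII:3", "VIII:9", "M", (_CIS, _M), _AFF_P),
    ("4", "IX:22", "VIII:3", "VIII:9", "M", (_CIS, _M), _AFF_P),
    ("4", "VIII:5", None, None, "M", (_SONLY, _REF), _UNAFF),
    ("4", "VIII:6", None, None, "F", (_M, _REF), _UNAFF),
    ("4", "IX:1", "VIII:5", "VIII:6", "M", (_SONLY, _M), _UNAFF),
    ("4", "IX:4", "VIII:5", "VIII:6", "F", (_SONLY, _M), _UNAFF),
    ("4", "IX:3", None, None, "M", (_RONLY, _REF), _UNAFF),
    ("4", "X:6", "IX:3", "IX:2", "M", (_RONLY, _M), _UNAFF),
    ("4", "X:8", "IX:3", "IX:2", "F", (_RONLY, _M), _UNAFF),
    ("4", "IX:23", None, None, "F", (_M, _REF), _UNAFF),
    ("4", "X:15", "IX:22", "IX:23", "M", (_CIS, _M), _AFF_P),
)

#: The unaffected relatives carrying M252R with only one common variant in
#: trans: five with R402Q only, two with S192Y only.
NAMED_UNAFFECTED_CARRIERS: tuple[str, ...] = (
    "VIII:9",
    "IX:2",
    "IX:21",
    "X:6",
    "X:8",
    "IX:1",
    "IX:4",
)


@dataclass
class FixtureFamilies:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth: dict[str, DiplotypeState]
    panel: VariantPanel
    named_unaffected_carriers: tuple[str, ...] = NAMED_UNAFFECTED_CARRIERS

    @property
    def affected(self) -> tuple[str, ...]:
        return tuple(
            iid
            for iid in sorted(self.pedigree.individuals)
            if self.pedigree.individuals[iid].phenotype_observed
            in (Phenotype.AFFECTED_COMPLETE, Phenotype.AFFECTED_PARTIAL, Phenotype.AFFECTED_MILD)
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, outdir / "families.ped", outdir / "phenotypes.tsv")
        write_genotypes_tsv(self.genotypes, self.panel, outdir / "genotypes.tsv")
        self.panel.to_json(outdir / "panel.json")


def make_fixture_families(panel: VariantPanel = TYR_PANEL) -> FixtureFamilies:
    """Deterministic families 1-4 fixture (pedigree, dosages, truth phase)."""
    individuals: dict[str, Individual] = {}
    truth: dict[str, DiplotypeState] = {}
    genotypes = GenotypeMatrix()
    for fid, iid, father, mother, sex, state, phenotype in _FIXTURE_ROWS:
        individuals[iid] = Individual(
            fid=fid,
            iid=iid,
            father=father,
            mother=mother,
            sex=Sex.MALE if sex == "M" else Sex.FEMALE,
            phenotype_observed=phenotype,
        )
        truth[iid] = state
        for vid, dosage in zip(panel.ids, _dosages(state)):
            genotypes.set(iid, vid, dosage)
    return FixtureFamilies(
        pedigree=Pedigree(individuals), genotypes=genotypes, truth=truth, panel=panel
    )
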