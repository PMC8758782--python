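"""Domain types, pedigree/genotype I/O and single-locus Mendelian validation.

The package analyses a small panel (2-4) of biallelic variants in one gene --
by default the three *TYR* missense variants S192Y, M252R and R402Q -- across
a pedigree.  This module holds the shared containers:

* :class:`Variant` / :class:`VariantPanel` -- the loci under study,
* :class:`Individual` / :class:`Pedigree` -- the family graph,
* :class:`GenotypeMatrix` -- unphased allele dosages per (individual, variant),

plus readers for PLINK-style PED files, small VCFs (via pysam) and a plain
genotype TSV dialect, and a report-only single-locus Mendelian checker that
downstream phasing uses to exclude unreliable genotypes.

Coordinates are 1-based GRCh38 throughout; any phase separators present in a
VCF GT field are deliberately ignored (phase is what the engine infers, so
pre-phased input must not leak in).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MISSING",
    "OcaphaseError",
    "StructureError",
    "DataError",
    "PathoClass",
    "Sex",
    "Phenotype",
    "Variant",
    "VariantPanel",
    "TYR_PANEL",
    "Individual",
    "Pedigree",
    "GenotypeMatrix",
    "MendelianViolation",
    "read_pedigree",
    "write_pedigree",
    "read_phenotype_sidecar",
    "read_genotypes",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_tsv",
    "validate_mendelian_single_locus",
]

#: Sentinel dosage for a missing genotype.
MISSING: int = -1


class OcaphaseError(Exception):
    """Base class for all errors raised by this package."""


class StructureError(OcaphaseError):
    """Malformed pedigree, panel or other structural input."""


class DataError(OcaphaseError):
    """Malformed or unsupported genotype / cohort data."""


class PathoClass(str, enum.Enum):
    """Pathogenicity class of a panel variant.

    PATHOGENIC_NULL marks alleles treated as functionally null (here M252R);
    HYPOMORPHIC_COMPONENT marks the common variants that are only deleterious
    in combination on one haplotype (S192Y, R402Q); REFERENCE_SCALE marks
    variants carried along for bookkeeping with no pathogenicity claim.
    """

    PATHOGENIC_NULL = "PATHOGENIC_NULL"
    HYPOMORPHIC_COMPONENT = "HYPOMORPHIC_COMPONENT"
    REFERENCE_SCALE = "REFERENCE_SCALE"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class Phenotype(str, enum.Enum):
    """Observed phenotype label.

    Four informative levels (complete OCA, partial OCA1B, mild hypomorphic
    phenotype, unaffected) plus UNKNOWN.  PED column 6 is binary and maps to
    UNAFFECTED / AFFECTED_PARTIAL by default; a sidecar TSV supplies the full
    four-level labels when available.
    """

    AFFECTED_COMPLETE = "AFFECTED_COMPLETE"
    AFFECTED_PARTIAL = "AFFECTED_PARTIAL"
    AFFECTED_MILD = "AFFECTED_MILD"
    UNAFFECTED = "UNAFFECTED"
    UNKNOWN = "UNKNOWN"


AFFECTED_PHENOTYPES = frozenset(
    {Phenotype.AFFECTED_COMPLETE, Phenotype.AFFECTED_PARTIAL, Phenotype.AFFECTED_MILD}
)


@dataclass(frozen=True)
class Variant:
    """A biallelic locus on the panel.

    ``pos`` is the 1-based genomic coordinate (GRCh38); ``id`` is the short
    label used everywhere else (e.g. ``"S192Y"``).
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    patho_class: PathoClass
    hgvs_c: str | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise StructureError(f"variant {self.id}: pos must be positive, got {self.pos}")
        if self.ref == self.alt:
            raise StructureError(f"variant {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class VariantPanel:
    """An ordered panel of 2-4 variants on one chromosome.

    Variants are stored sorted by position; the engine treats the whole span
    as recombination-free within a pedigree.
    """

    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        variants = tuple(sorted(self.variants, key=lambda v: v.pos))
        object.__setattr__(self, "variants", variants)
        if not 2 <= len(variants) <= 4:
            raise StructureError(
                f"panel must contain 2-4 variants, got {len(variants)} "
                "(the engine enumerates 2^k haplotypes and refuses beyond k=4)"
            )
        chroms = {v.chrom for v in variants}
        if len(chroms) != 1:
            raise StructureError(f"panel variants span several chromosomes: {sorted(chroms)}")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate variant ids in panel: {ids}")
        positions = [v.pos for v in variants]
        if len(set(positions)) != len(positions):
            raise StructureError(f"duplicate variant positions in panel: {positions}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(v.id for v in self.variants)

    @property
    def span_bp(self) -> int:
        return self.variants[-1].pos - self.variants[0].pos

    def index(self, vid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == vid:
                return i
        raise StructureError(f"variant {vid!r} is not on the panel {self.ids}")

    def get(self, vid: str) -> Variant:
        return self.variants[self.index(vid)]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @classmethod
    def from_json(cls, path: str | Path) -> "VariantPanel":
        """Load a panel from a JSON list of {id, chrom, pos, ref, alt, patho_class}."""
        with open(path) as fh:
            records = json.load(fh)
        variants = []
        for rec in records:
            try:
                variants.append(
                    Variant(
                        id=rec["id"],
                        chrom=str(rec["chrom"]),
                        pos=int(rec["pos"]),
                        ref=rec["ref"],
                        alt=rec["alt"],
                        patho_class=PathoClass(rec["patho_class"]),
                        hgvs_c=rec.get("hgvs_c"),
                    )
                )
            except KeyError as exc:
                raise DataError(f"panel record {rec!r} is missing field {exc}") from exc
        return cls(tuple(variants))

    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "id": v.id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "patho_class": v.patho_class.value,
                "hgvs_c": v.hgvs_c,
            }
            for v in self.variants
        ]
        Path(path).write_text(json.dumps(records, indent=2) + "\n")


#: The three-variant TYR panel (GRCh38, NM_000372.4) used throughout the study:
#: two common hypomorphic-component missense variants and the rare
#: Amish-enriched null-like M252R allele, spanning ~106 kb.
TYR_PANEL = VariantPanel(
    (
        Variant("S192Y", "11", 89178528, "C", "A", PathoClass.HYPOMORPHIC_COMPONENT, "c.575C>A"),
        Variant("M252R", "11", 89178708, "T", "G", PathoClass.PATHOGENIC_NULL, "c.755T>G"),
        Variant("R402Q", "11", 89284793, "G", "A", PathoClass.HYPOMORPHIC_COMPONENT, "c.1205G>A"),
    )
)


@dataclass(frozen=True)
class Individual:
    fid: str
    iid: str
    father: str | None
    mother: str | None
    sex: Sex = Sex.UNKNOWN
    phenotype_observed: Phenotype = Phenotype.UNKNOWN

    def __post_init__(self) -> None:
        if self.father == self.iid or self.mother == self.iid:
            raise StructureError(f"individual {self.iid} lists itself as a parent")
        if self.father is not None and self.father == self.mother:
            raise StructureError(
                f"individual {self.iid} lists the same individual {self.father!r} "
                "as both father and mother"
            )

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """A family graph keyed by individual id (iids unique across families)."""

    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        unresolved = []
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    unresolved.append((ind.iid, parent))
        if unresolved:
            listing = "; ".join(f"{iid} -> {parent}" for iid, parent in sorted(unresolved))
            raise StructureError(f"unresolved parent ids: {listing}")
        # A recorded father must not be female and vice versa.
        for ind in self.individuals.values():
            if ind.father is not None and self.individuals[ind.father].sex is Sex.FEMALE:
                raise StructureError(
                    f"{ind.father} is recorded as father of {ind.iid} but has sex FEMALE"
                )
            if ind.mother is not None and self.individuals[ind.mother].sex is Sex.MALE:
                raise StructureError(
                    f"{ind.mother} is recorded as mother of {ind.iid} but has sex MALE"
                )
        cycle = self._find_cycle()
        if cycle is not None:
            raise StructureError("cyclic parentage: " + " -> ".join(cycle))

    def _find_cycle(self) -> list[str] | None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {iid: WHITE for iid in self.individuals}
        stack_trace: list[str] = []

        def visit(iid: str) -> list[str] | None:
            colour[iid] = GREY
            stack_trace.append(iid)
            ind = self.individuals[iid]
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if colour[parent] == GREY:
                    i = stack_trace.index(parent)
                    return stack_trace[i:] + [parent]
                if colour[parent] == WHITE:
                    found = visit(parent)
                    if found is not None:
                        return found
            colour[iid] = BLACK
            stack_trace.pop()
            return None

        for iid in sorted(self.individuals):
            if colour[iid] == WHITE:
                found = visit(iid)
                if found is not None:
                    return found
        return None

    @property
    def founders(self) -> frozenset[str]:
        return frozenset(iid for iid, ind in self.individuals.items() if ind.is_founder)

    def children_of(self, iid: str) -> tuple[str, ...]:
        return tuple(
            sorted(
                c
                for c, ind in self.individuals.items()
                if iid in (ind.father, ind.mother)
            )
        )

    def nuclear_families(self) -> list[tuple[str | None, str | None, tuple[str, ...]]]:
        """(father, mother, children) triples, sorted for determinism."""
        groups: dict[tuple[str | None, str | None], list[str]] = {}
        for iid in sorted(self.individuals):
            ind = self.individuals[iid]
            if ind.father is None and ind.mother is None:
                continue
            groups.setdefault((ind.father, ind.mother), []).append(iid)
        return [
            (f, m, tuple(kids))
            for (f, m), kids in sorted(groups.items(), key=lambda kv: (kv[0][0] or "", kv[0][1] or ""))
        ]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(sorted(self.individuals))

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals


DEFAULT_PHENOTYPE_MAP: Mapping[str, Phenotype] = {
    "1": Phenotype.UNAFFECTED,
    "2": Phenotype.AFFECTED_PARTIAL,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}

_SEX_MAP = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_CODE = {
    Phenotype.UNAFFECTED: "1",
    Phenotype.AFFECTED_PARTIAL: "2",
    Phenotype.AFFECTED_COMPLETE: "2",
    Phenotype.AFFECTED_MILD: "2",
    Phenotype.UNKNOWN: "0",
}


def read_phenotype_sidecar(path: str | Path) -> dict[str, Phenotype]:
    """Read an ``iid<TAB>phenotype`` sidecar (full four-level labels)."""
    labels: dict[str, Phenotype] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataError(f"{path}:{lineno}: expected 'iid<TAB>phenotype', got {line!r}")
        iid, label = fields[0], fields[1]
        if iid.lower() == "iid":  # optional header row
            continue
        try:
            labels[iid] = Phenotype(label)
        except ValueError as exc:
            raise DataError(
                f"{path}:{lineno}: unknown phenotype label {label!r}; "
                f"expected one of {[p.value for p in Phenotype]}"
            ) from exc
    return labels


def read_pedigree(
    path: str | Path,
    phenotype_map: Mapping[str, Phenotype] | None = None,
    phenotype_sidecar: str | Path | None = None,
) -> Pedigree:
    """Read a PLINK-style PED/FAM file (FID IID PAT MAT SEX PHENO ...).

    Column 6 is decoded through ``phenotype_map`` (default: 1 -> UNAFFECTED,
    2 -> AFFECTED_PARTIAL, 0/-9 -> UNKNOWN).  When ``phenotype_sidecar`` is
    given, its four-level labels override column 6 for the listed iids.
    """
    phenotype_map = dict(DEFAULT_PHENOTYPE_MAP if phenotype_map is None else phenotype_map)
    sidecar = read_phenotype_sidecar(phenotype_sidecar) if phenotype_sidecar else {}
    individuals: dict[str, Individual] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise DataError(
                f"{path}:{lineno}: expected >=6 whitespace-delimited columns, got {len(fields)}"
            )
        fid, iid, pat, mat, sex_code, pheno_code = fields[:6]
        if iid in individuals:
            raise DataError(f"{path}:{lineno}: duplicate individual id {iid!r}")
        phenotype = sidecar.get(iid, phenotype_map.get(pheno_code, Phenotype.UNKNOWN))
        individuals[iid] = Individual(
            fid=fid,
            iid=iid,
            father=None if pat == "0" else pat,
            mother=None if mat == "0" else mat,
            sex=_SEX_MAP.get(sex_code, Sex.UNKNOWN),
            phenotype_observed=phenotype,
        )
    return Pedigree(individuals)


def write_pedigree(
    pedigree: Pedigree,
    path: str | Path,
    phenotype_sidecar: str | Path | None = None,
) -> None:
    """Write a PED file (and optionally a four-level phenotype sidecar).

    Column 6 collapses the four-level phenotype to the binary 1/2/0 coding, so
    a PED round trip preserves structure while normalising phenotype coding;
    the sidecar preserves the full labels.
    """
    lines = []
    for iid in sorted(pedigree.individuals):
        ind = pedigree.individuals[iid]
        lines.append(
            "\t".join(
                [
                    ind.fid,
                    ind.iid,
                    ind.father or "0",
                    ind.mother or "0",
                    _SEX_CODE[ind.sex],
                    _PHENO_CODE[ind.phenotype_observed],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
    if phenotype_sidecar is not None:
        rows = ["iid\tphenotype"]
        for iid in sorted(pedigree.individuals):
            rows.append(f"{iid}\t{pedigree.individuals[iid].phenotype_observed.value}")
        Path(phenotype_sidecar).write_text("\n".join(rows) + "\n")


@dataclass
class GenotypeMatrix:
    """Unphased allele dosages keyed by ``(iid, variant id)``.

    Dosages are 0/1/2 or :data:`MISSING`; absent keys read as MISSING so a
    pedigree member absent from the genotype file is simply ungenotyped.
    """

    entries: dict[tuple[str, str], int] = field(default_factory=dict)

    def dosage(self, iid: str, vid: str) -> int:
        return self.entries.get((iid, vid), MISSING)

    def dosages(self, iid: str, panel: VariantPanel) -> tuple[int, ...]:
        return tuple(self.dosage(iid, v.id) for v in panel)

    def set(self, iid: str, vid: str, dosage: int) -> None:
        if dosage not in (0, 1, 2, MISSING):
            raise DataError(f"invalid dosage {dosage!r} for ({iid}, {vid})")
        self.entries[(iid, vid)] = dosage

    def masked(self, keys: Iterable[tuple[str, str]]) -> "GenotypeMatrix":
        """Copy with the given (iid, variant) entries set to MISSING."""
        entries = dict(self.entries)
        for key in keys:
            entries[key] = MISSING
        return GenotypeMatrix(entries)

    def iids(self) -> tuple[str, ...]:
        return tuple(sorted({iid for iid, _ in self.entries}))


def _check_members(iids: Iterable[str], pedigree: Pedigree, source: str) -> list[str]:
    known = [iid for iid in iids if iid in pedigree]
    unknown = sorted(set(iids) - set(known))
    if unknown:
        warnings.warn(
            f"{source}: {len(unknown)} sample(s) not in the pedigree were skipped: "
            f"{', '.join(unknown[:8])}{'...' if len(unknown) > 8 else ''}",
            stacklevel=3,
        )
    return known


def read_genotypes_tsv(
    path: str | Path, panel: VariantPanel, pedigree: Pedigree
) -> GenotypeMatrix:
    """Read the genotype TSV dialect: header ``iid<TAB><variant id>...``, cells 0/1/2/NA."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise DataError(f"{path}: empty genotype table")
    header = lines[0].split("\t")
    if header[0] != "iid":
        raise DataError(f"{path}: first header column must be 'iid', got {header[0]!r}")
    cols = header[1:]
    unknown_cols = [c for c in cols if c not in panel.ids]
    if unknown_cols:
        warnings.warn(f"{path}: ignoring columns not on the panel: {unknown_cols}", stacklevel=2)
    matrix = GenotypeMatrix()
    seen_iids = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise DataError(f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
        seen_iids.append(fields[0])
    members = set(_check_members(seen_iids, pedigree, str(path)))
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        iid = fields[0]
        if iid not in members:
            continue
        for col, cell in zip(cols, fields[1:]):
            if col in unknown_cols:
                continue
            cell = cell.strip()
            if cell in ("NA", "", "."):
                matrix.set(iid, col, MISSING)
            elif cell in ("0", "1", "2"):
                matrix.set(iid, col, int(cell))
            else:
                raise DataError(f"{path}:{lineno}: invalid dosage cell {cell!r} for {col}")
    return matrix


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_genotypes_vcf(
    path: str | Path, panel: VariantPanel, pedigree: Pedigree
) -> GenotypeMatrix:
    """Read dosages from a (possibly gzipped) VCF with GT fields.

    Variants are matched by (chrom, pos, ref, alt) with the ``chr`` prefix
    normalised away.  GT phase separators are ignored -- the input is treated
    as unphased by contract.  Multi-allelic records at a panel position are an
    error; a panel variant absent from the file yields a warning and a fully
    MISSING column.
    """
    import pysam

    wanted = {(_norm_chrom(v.chrom), v.pos): v for v in panel}
    matrix = GenotypeMatrix()
    found: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        samples = _check_members(list(vcf.header.samples), pedigree, str(path))
        for rec in vcf:
            key = (_norm_chrom(rec.chrom), rec.pos)
            variant = wanted.get(key)
            if variant is None:
                continue
            alts = rec.alts or ()
            if len(alts) > 1:
                raise DataError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos} "
                    f"(ALT={','.join(alts)}) overlaps panel variant {variant.id}; "
                    "split multi-allelic sites upstream"
                )
            if rec.ref != variant.ref or (alts and alts[0] != variant.alt):
                continue  # same position, different alleles: not the panel variant
            found.add(variant.id)
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    matrix.set(sample, variant.id, MISSING)
                else:
                    matrix.set(sample, variant.id, sum(1 for a in gt if a == 1))
    for v in panel:
        if v.id not in found:
            warnings.warn(
                f"{path}: panel variant {v.id} ({v.chrom}:{v.pos} {v.ref}>{v.alt}) "
                "not found in VCF; column set to MISSING",
                stacklevel=2,
            )
    return matrix


def read_genotypes(
    path: str | Path, panel: VariantPanel, pedigree: Pedigree
) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` -> VCF reader, else TSV."""
    name = str(path).lower()
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return read_genotypes_vcf(path, panel, pedigree)
    return read_genotypes_tsv(path, panel, pedigree)


def write_genotypes_tsv(
    matrix: GenotypeMatrix, panel: VariantPanel, path: str | Path
) -> None:
    lines = ["iid\t" + "\t".join(panel.ids)]
    for iid in matrix.iids():
        cells = [
            "NA" if d == MISSING else str(d) for d in matrix.dosages(iid, panel)
        ]
        lines.append(iid + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# Alleles a parent with a given dosage can transmit (MISSING is unconstrained).
_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,), MISSING: (0, 1)}


@dataclass(frozen=True)
class MendelianViolation:
    child: str
    variant_id: str
    child_dosage: int
    father_dosage: int
    mother_dosage: int


def validate_mendelian_single_locus(
    pedigree: Pedigree, genotypes: GenotypeMatrix, variant: Variant | str
) -> list[MendelianViolation]:
    """Report children whose dosage is impossible given parental dosages.

    A child dosage is a violation iff no choice of one transmitted allele per
    parent reproduces it; a MISSING parent (or a parent absent from the
    pedigree) is compatible with anything.  De novo mutation is not modelled.
    Report-only: callers decide whether to mask the offending genotypes.
    """
    vid = variant.id if isinstance(variant, Variant) else variant
    violations = []
    for iid in sorted(pedigree.individuals):
        ind = pedigree.individuals[iid]
        child_dosage = genotypes.dosage(iid, vid)
        if child_dosage == MISSING or ind.is_founder:
            continue
        father_dosage = genotypes.dosage(ind.father, vid) if ind.father else MISSING
        mother_dosage = genotypes.dosage(ind.mother, vid) if ind.mother else MISSING
        reachable = {
            af + am
            for af in _TRANSMISSIBLE[father_dosage]
            for am in _TRANSMISSIBLE[mother_dosage]
        }
        if child_dosage not in reachable:
            violations.append(
                MendelianViolation(iid, vid, child_dosage, father_dosage, mother_dosage)
            )
    return violations
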