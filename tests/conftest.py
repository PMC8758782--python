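"""Shared fixtures: small panels, pedigree/genotype builders, the packaged
family fixture, and text-format files generated on the fly."""

from __future__ import annotations

import pytest

from ocaphase import (
    GenotypeMatrix,
    Individual,
    PathoClass,
    Pedigree,
    Phenotype,
    Sex,
    TYR_PANEL,
    Variant,
    VariantPanel,
    make_fixture_families,
)


@pytest.fixture(scope="session")
def tyr_panel() -> VariantPanel:
    return TYR_PANEL


@pytest.fixture(scope="session")
def two_locus_panel() -> VariantPanel:
    """Just the two common variants: the minimal phasing panel."""
    return VariantPanel(
        (
            Variant("S192Y", "11", 89178528, "C", "A", PathoClass.HYPOMORPHIC_COMPONENT),
            Variant("R402Q", "11", 89284793, "G", "A", PathoClass.HYPOMORPHIC_COMPONENT),
        )
    )


@pytest.fixture(scope="session")
def fixture_families():
    return make_fixture_families()


def build_pedigree(rows) -> Pedigree:
    """rows: (iid, father, mother) or (iid, father, mother, sex, phenotype)."""
    individuals = {}
    for row in rows:
        iid, father, mother = row[:3]
        sex = row[3] if len(row) > 3 else Sex.UNKNOWN
        phenotype = row[4] if len(row) > 4 else Phenotype.UNKNOWN
        individuals[iid] = Individual(
            fid="FAM", iid=iid, father=father, mother=mother, sex=sex,
            phenotype_observed=phenotype,
        )
    return Pedigree(individuals)


def build_genotypes(dosages_by_iid, panel: VariantPanel) -> GenotypeMatrix:
    """dosages_by_iid: iid -> tuple of dosages in panel order."""
    matrix = GenotypeMatrix()
    for iid, dosages in dosages_by_iid.items():
        for vid, dosage in zip(panel.ids, dosages):
            matrix.set(iid, vid, dosage)
    return matrix


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return build_pedigree(
        [("dad", None, None, Sex.MALE), ("mum", None, None, Sex.FEMALE), ("kid", "dad", "mum")]
    )
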