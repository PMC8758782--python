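"""Genotype-compatibility rule and deterministic diplotype -> phenotype model.

Each haplotype over the panel is reduced to an allele type:

* ``NULL_PATHOGENIC`` -- carries a null-class variant (here M252R, which
  itself carries R402Q in cis; the accompanying common variants do not soften
  the classification),
* ``HYPOMORPHIC_CIS`` -- carries both hypomorphic-component variants (the
  S192Y/R402Q in-cis haplotype),
* ``SINGLE_VARIANT`` -- exactly one variant, individually benign,
* ``REFERENCE`` -- no variant.

Penetrance is modelled as deterministic given the unordered allele-type pair:
two nulls give complete OCA, null over the cis haplotype gives partial OCA1B,
two cis haplotypes give a mild but fully penetrant hypomorphic phenotype, and
every pairing involving at most one functional hit leaves the carrier
unaffected.  Pairings never observed in the source pedigrees are flagged
EXTRAPOLATED and can be overridden.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    MISSING,
    GenotypeMatrix,
    PathoClass,
    Pedigree,
    Phenotype,
    VariantPanel,
)
from .phasing import DiplotypeState, Haplotype, PhaseSolution

__all__ = [
    "AlleleType",
    "PredictedPhenotype",
    "Confidence",
    "PhenotypePrediction",
    "haplotype_possible",
    "assign_allele_type",
    "classify_diplotype",
    "classify_pedigree",
    "write_predictions",
]


class AlleleType(str, enum.Enum):
    NULL_PATHOGENIC = "NULL_PATHOGENIC"
    HYPOMORPHIC_CIS = "HYPOMORPHIC_CIS"
    SINGLE_VARIANT = "SINGLE_VARIANT"
    REFERENCE = "REFERENCE"


class PredictedPhenotype(str, enum.Enum):
    COMPLETE_OCA = "COMPLETE_OCA"
    PARTIAL_OCA1B = "PARTIAL_OCA1B"
    MILD_HYPOMORPHIC = "MILD_HYPOMORPHIC"
    UNAFFECTED_CARRIER = "UNAFFECTED_CARRIER"
    UNAFFECTED = "UNAFFECTED"
    INDETERMINATE = "INDETERMINATE"


class Confidence(str, enum.Enum):
    """OBSERVED: pairing seen in the source pedigrees; EXTRAPOLATED: inferred."""

    OBSERVED = "OBSERVED"
    EXTRAPOLATED = "EXTRAPOLATED"


@dataclass(frozen=True)
class PhenotypePrediction:
    iid: str
    predicted: PredictedPhenotype
    confidence: Confidence
    observed: Phenotype = Phenotype.UNKNOWN
    concordant: str = "NA"  # "Y" / "N" / "NA"


def haplotype_possible(dosage_s192y: int, dosage_r402q: int) -> bool:
    """Screen rule: could this individual carry the S192Y/R402Q cis haplotype?

    True iff the individual is homozygous or heterozygous for *both* variants
    (dosage >= 1 at each).  MISSING at either locus is conservatively False.
    Monotone non-decreasing in each dosage argument.
    """
    if dosage_s192y == MISSING or dosage_r402q == MISSING:
        return False
    return dosage_s192y >= 1 and dosage_r402q >= 1


def assign_allele_type(hap: Haplotype, panel: VariantPanel) -> AlleleType:
    """Reduce one haplotype to its functional allele type.

    Null-class variants dominate regardless of accompanying common variants;
    otherwise two or more hypomorphic-component variants on one haplotype make
    the hypomorphic cis allele; one variant of any class is SINGLE_VARIANT.
    """
    if len(hap) != len(panel):
        raise ValueError(f"haplotype length {len(hap)} does not match panel size {len(panel)}")
    carried = [v for v, allele in zip(panel, hap) if allele == 1]
    if any(v.patho_class is PathoClass.PATHOGENIC_NULL for v in carried):
        return AlleleType.NULL_PATHOGENIC
    n_hypo = sum(1 for v in carried if v.patho_class is PathoClass.HYPOMORPHIC_COMPONENT)
    if n_hypo >= 2:
        return AlleleType.HYPOMORPHIC_CIS
    if carried:
        return AlleleType.SINGLE_VARIANT
    return AlleleType.REFERENCE


_N = AlleleType.NULL_PATHOGENIC
_H = AlleleType.HYPOMORPHIC_CIS
_S = AlleleType.SINGLE_VARIANT
_R = AlleleType.REFERENCE

# Unordered allele-type pair -> (prediction, confidence).
_DIPLOTYPE_TABLE: dict[frozenset, tuple[PredictedPhenotype, Confidence]] = {
    frozenset({_N}): (PredictedPhenotype.COMPLETE_OCA, Confidence.OBSERVED),
    frozenset({_N, _H}): (PredictedPhenotype.PARTIAL_OCA1B, Confidence.OBSERVED),
    frozenset({_H}): (PredictedPhenotype.MILD_HYPOMORPHIC, Confidence.OBSERVED),
    frozenset({_N, _S}): (PredictedPhenotype.UNAFFECTED_CARRIER, Confidence.OBSERVED),
    frozenset({_N, _R}): (PredictedPhenotype.UNAFFECTED_CARRIER, Confidence.OBSERVED),
    frozenset({_H, _S}): (PredictedPhenotype.UNAFFECTED_CARRIER, Confidence.EXTRAPOLATED),
    frozenset({_H, _R}): (PredictedPhenotype.UNAFFECTED_CARRIER, Confidence.EXTRAPOLATED),
    frozenset({_S}): (PredictedPhenotype.UNAFFECTED, Confidence.OBSERVED),
    frozenset({_S, _R}): (PredictedPhenotype.UNAFFECTED, Confidence.OBSERVED),
    frozenset({_R}): (PredictedPhenotype.UNAFFECTED, Confidence.OBSERVED),
}


def classify_diplotype(
    a1: AlleleType,
    a2: AlleleType,
    overrides: Mapping[frozenset, PredictedPhenotype] | None = None,
) -> tuple[PredictedPhenotype, Confidence]:
    """Deterministic phenotype prediction for an unordered allele-type pair.

    Symmetric in its arguments.  ``overrides`` may remap any pairing (keys are
    ``frozenset`` of one or two :class:`AlleleType`); overridden pairings are
    reported EXTRAPOLATED.
    """
    key = frozenset({a1, a2})
    if overrides and key in overrides:
        return overrides[key], Confidence.EXTRAPOLATED
    return _DIPLOTYPE_TABLE[key]


#: Observed phenotype each prediction implies, for concordance scoring.
_EXPECTED_OBSERVED = {
    PredictedPhenotype.COMPLETE_OCA: Phenotype.AFFECTED_COMPLETE,
    PredictedPhenotype.PARTIAL_OCA1B: Phenotype.AFFECTED_PARTIAL,
    PredictedPhenotype.MILD_HYPOMORPHIC: Phenotype.AFFECTED_MILD,
    PredictedPhenotype.UNAFFECTED_CARRIER: Phenotype.UNAFFECTED,
    PredictedPhenotype.UNAFFECTED: Phenotype.UNAFFECTED,
}


def _allele_type_pairs(
    states: frozenset[DiplotypeState], panel: VariantPanel
) -> set[tuple[AlleleType, AlleleType]]:
    pairs = set()
    for pat, mat in states:
        a, b = assign_allele_type(pat, panel), assign_allele_type(mat, panel)
        pairs.add((a, b) if a.value <= b.value else (b, a))
    return pairs


def classify_pedigree(
    pedigree: Pedigree,
    solution: PhaseSolution,
    genotypes: GenotypeMatrix,
    panel: VariantPanel,
    overrides: Mapping[frozenset, PredictedPhenotype] | None = None,
    mild_counts_affected: bool = True,
) -> tuple[list[PhenotypePrediction], dict]:
    """Per-individual predictions plus a concordance summary.

    An individual is classified only when every surviving phase configuration
    implies the same unordered allele-type pair; otherwise (including fully
    missing genotypes or unresolved phase) the prediction is INDETERMINATE.

    The summary holds a confusion matrix (observed x predicted), counts of
    concordant / discordant / unscored individuals, and a separate count of
    predicted-mild vs observed-unaffected mismatches, which are genuinely
    ambiguous in shallow phenotyping; ``mild_counts_affected`` controls
    whether those count as discordant or are only tallied separately.
    """
    predictions: list[PhenotypePrediction] = []
    mild_vs_unaffected = 0
    for iid in sorted(pedigree.individuals):
        observed = pedigree.individuals[iid].phenotype_observed
        dosages = genotypes.dosages(iid, panel)
        states = solution.states.get(iid, frozenset())
        if all(d == MISSING for d in dosages) or not states:
            predictions.append(
                PhenotypePrediction(
                    iid, PredictedPhenotype.INDETERMINATE, Confidence.EXTRAPOLATED, observed, "NA"
                )
            )
            continue
        pairs = _allele_type_pairs(states, panel)
        if len(pairs) != 1:
            predictions.append(
                PhenotypePrediction(
                    iid, PredictedPhenotype.INDETERMINATE, Confidence.EXTRAPOLATED, observed, "NA"
                )
            )
            continue
        a1, a2 = next(iter(pairs))
        predicted, confidence = classify_diplotype(a1, a2, overrides)
        expected = _EXPECTED_OBSERVED[predicted]
        if observed is Phenotype.UNKNOWN:
            concordant = "NA"
        elif predicted is PredictedPhenotype.MILD_HYPOMORPHIC and observed is Phenotype.UNAFFECTED:
            mild_vs_unaffected += 1
            concordant = "N" if mild_counts_affected else "NA"
        else:
            concordant = "Y" if observed is expected else "N"
        predictions.append(PhenotypePrediction(iid, predicted, confidence, observed, concordant))

    confusion = pd.crosstab(
        pd.Series([p.observed.value for p in predictions], name="observed"),
        pd.Series([p.predicted.value for p in predictions], name="predicted"),
    )
    summary = {
        "n": len(predictions),
        "concordant": sum(1 for p in predictions if p.concordant == "Y"),
        "discordant": sum(1 for p in predictions if p.concordant == "N"),
        "unscored": sum(1 for p in predictions if p.concordant == "NA"),
        "mild_vs_unaffected": mild_vs_unaffected,
        "indeterminate": sum(
            1 for p in predictions if p.predicted is PredictedPhenotype.INDETERMINATE
        ),
        "confusion": confusion,
    }
    return predictions, summary


def write_predictions(predictions: Sequence[PhenotypePrediction], path) -> None:
    """TSV: iid, predicted, confidence, observed, concordant."""
    from pathlib import Path

    lines = ["iid\tpredicted\tconfidence\tobserved\tconcordant"]
    for p in predictions:
        lines.append(
            "\t".join(
                [p.iid, p.predicted.value, p.confidence.value, p.observed.value, p.concordant]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
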