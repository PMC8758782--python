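"""Pedigree cis/trans phase resolution by Mendelian constraint satisfaction.

Given unphased dosages at a small recombination-free panel of loci, every
individual has a set of candidate ordered diplotypes (paternal haplotype,
maternal haplotype); Mendelian transmission requires each non-founder's
paternal haplotype to equal one of the father's two haplotypes, and likewise
on the maternal side.  The engine computes, for every individual, the union
of diplotype states it takes in at least one globally consistent assignment
-- exactly the information a geneticist extracts by reading haplotypes off a
pedigree diagram.

Two implementations share one contract:

* :func:`solve_pedigree_phase` -- arc-consistency pruning plus backtracking,
  scales to realistic pedigrees;
* :func:`exhaustive_phase_oracle` -- direct enumeration of all joint
  assignments, refuses pedigrees above 10 members; used as an independent
  check of the solver.

:func:`phase_variant_pair` projects the surviving states onto a pair of loci
and emits per-individual CIS / TRANS / UNINFORMATIVE calls.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .core import (
    MISSING,
    GenotypeMatrix,
    Pedigree,
    StructureError,
    VariantPanel,
    validate_mendelian_single_locus,
)

__all__ = [
    "Haplotype",
    "DiplotypeState",
    "PhaseType",
    "PhaseCall",
    "PhaseSolution",
    "enumerate_individual_states",
    "solve_pedigree_phase",
    "exhaustive_phase_oracle",
    "phase_variant_pair",
    "write_phase_calls",
]

#: One chromosome copy across the panel loci: 0 = ref, 1 = alt per locus.
Haplotype = tuple[int, ...]

#: Ordered (paternal, maternal) haplotype pair.
DiplotypeState = tuple[Haplotype, Haplotype]

MAX_PANEL = 4
ORACLE_MAX_MEMBERS = 10

#: (paternal allele, maternal allele) options per observed dosage.
_ALLELE_PAIRS: dict[int, tuple[tuple[int, int], ...]] = {
    0: ((0, 0),),
    1: ((0, 1), (1, 0)),
    2: ((1, 1),),
    MISSING: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


class PhaseType(str, enum.Enum):
    CIS = "CIS"
    TRANS = "TRANS"
    UNINFORMATIVE = "UNINFORMATIVE"
    NOT_DOUBLE_HET = "NOT_DOUBLE_HET"
    INCONSISTENT = "INCONSISTENT"


@dataclass(frozen=True)
class PhaseCall:
    """Phase call for one individual at one variant pair.

    ``n_cis_configs`` / ``n_trans_configs`` count the surviving unordered
    diplotype states of each kind for this individual (union over all globally
    consistent configurations): CIS means only cis-type states survive, TRANS
    only trans-type, UNINFORMATIVE both.
    """

    iid: str
    pair: tuple[str, str]
    call: PhaseType
    n_cis_configs: int = 0
    n_trans_configs: int = 0
    evidence: tuple[str, ...] = ()


@dataclass
class PhaseSolution:
    """Per-individual unions of globally consistent ordered diplotype states.

    ``consistent`` is False iff no global assignment satisfies all genotypes
    and transmissions, in which case every union is empty and
    ``conflicting_family`` names a minimal locally inconsistent nuclear family
    (father, mother, children) when one is determinable.
    """

    states: dict[str, frozenset[DiplotypeState]]
    consistent: bool = True
    conflicting_family: tuple[str | None, str | None, tuple[str, ...]] | None = None


def enumerate_individual_states(
    dosages: Sequence[int], n_loci: int | None = None
) -> frozenset[DiplotypeState]:
    """All ordered (paternal, maternal) haplotype pairs matching the dosages.

    MISSING loci are unconstrained; with h heterozygous and m missing loci the
    set has 2^h * 4^m ordered states.
    """
    if n_loci is not None and len(dosages) != n_loci:
        raise StructureError(f"expected {n_loci} dosages, got {len(dosages)}")
    if len(dosages) > MAX_PANEL:
        raise StructureError(f"panel size {len(dosages)} exceeds the {MAX_PANEL}-locus cap")
    states = set()
    for combo in itertools.product(*(_ALLELE_PAIRS[d] for d in dosages)):
        pat = tuple(p for p, _ in combo)
        mat = tuple(m for _, m in combo)
        states.add((pat, mat))
    return frozenset(states)


def _topological_order(pedigree: Pedigree, members: Iterable[str]) -> list[str]:
    """Members ordered parents-before-children, ties broken by sorted iid."""
    members = set(members)
    order: list[str] = []
    placed: set[str] = set()
    remaining = sorted(members)
    while remaining:
        progressed = False
        next_round = []
        for iid in remaining:
            ind = pedigree.individuals[iid]
            deps = [p for p in (ind.father, ind.mother) if p in members and p not in placed]
            if deps:
                next_round.append(iid)
            else:
                order.append(iid)
                placed.add(iid)
                progressed = True
        if not progressed:  # cannot happen: Pedigree forbids cycles
            raise StructureError(f"parentage cycle among {next_round}")
        remaining = next_round
    return order


def _components(pedigree: Pedigree) -> list[list[str]]:
    """Connected components of the parent-child constraint graph."""
    parent: dict[str, str] = {iid: iid for iid in pedigree.individuals}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for iid, ind in pedigree.individuals.items():
        for p in (ind.father, ind.mother):
            if p is not None:
                union(iid, p)
    groups: dict[str, list[str]] = {}
    for iid in sorted(pedigree.individuals):
        groups.setdefault(find(iid), []).append(iid)
    return sorted(groups.values())


def _arc_consistency(
    pedigree: Pedigree, domains: dict[str, set[DiplotypeState]]
) -> bool:
    """Prune domains to pairwise (child, parent) consistency; False if emptied."""
    arcs: list[tuple[str, str, int]] = []  # (child, parent, side 0=paternal 1=maternal)
    for iid in sorted(domains):
        ind = pedigree.individuals[iid]
        if ind.father in domains:
            arcs.append((iid, ind.father, 0))
        if ind.mother in domains:
            arcs.append((iid, ind.mother, 1))
    queue = list(arcs)
    while queue:
        child, par, side = queue.pop()
        dom_c, dom_p = domains[child], domains[par]
        keep_c = {s for s in dom_c if any(s[side] == p[0] or s[side] == p[1] for p in dom_p)}
        keep_p = {p for p in dom_p if any(s[side] == p[0] or s[side] == p[1] for s in dom_c)}
        changed = set()
        if len(keep_c) != len(dom_c):
            domains[child] = keep_c
            changed.add(child)
        if len(keep_p) != len(dom_p):
            domains[par] = keep_p
            changed.add(par)
        if any(not domains[x] for x in changed):
            return False
        if changed:
            for arc in arcs:
                if arc[0] in changed or arc[1] in changed:
                    queue.append(arc)
    return all(domains.values())


def _search(
    pedigree: Pedigree,
    order: Sequence[str],
    domains: Mapping[str, Iterable[DiplotypeState]],
    pin: tuple[str, DiplotypeState] | None = None,
) -> Iterator[dict[str, DiplotypeState]]:
    """Lazy depth-first enumeration of consistent assignments over ``order``.

    ``order`` must place parents before children so transmission is checked
    against already-assigned parents.  ``pin`` fixes one individual's state.
    Iteration order is deterministic (sorted states); callers wanting a single
    witness just stop after the first yield.
    """
    if pin is not None and pin[1] not in domains[pin[0]]:
        return
    sorted_domains = {
        iid: [pin[1]] if pin is not None and iid == pin[0] else sorted(domains[iid])
        for iid in order
    }
    assignment: dict[str, DiplotypeState] = {}

    def compatible(iid: str, state: DiplotypeState) -> bool:
        ind = pedigree.individuals[iid]
        if ind.father in assignment:
            f = assignment[ind.father]
            if state[0] != f[0] and state[0] != f[1]:
                return False
        if ind.mother in assignment:
            m = assignment[ind.mother]
            if state[1] != m[0] and state[1] != m[1]:
                return False
        return True

    def recurse(i: int) -> Iterator[dict[str, DiplotypeState]]:
        if i == len(order):
            yield dict(assignment)
            return
        iid = order[i]
        for state in sorted_domains[iid]:
            if compatible(iid, state):
                assignment[iid] = state
                yield from recurse(i + 1)
                del assignment[iid]

    yield from recurse(0)


def _first_solution(pedigree, order, domains, pin=None):
    return next(_search(pedigree, order, domains, pin=pin), None)


def _conflicting_family(
    pedigree: Pedigree, raw_domains: Mapping[str, frozenset[DiplotypeState]]
) -> tuple[str | None, str | None, tuple[str, ...]] | None:
    """First nuclear family with no locally consistent assignment, if any."""
    for father, mother, children in pedigree.nuclear_families():
        members = [p for p in (father, mother) if p is not None] + list(children)
        order = _topological_order(pedigree, members)
        local = {iid: raw_domains[iid] for iid in members}
        if _first_solution(pedigree, order, local) is None:
            return (father, mother, children)
    return None


def solve_pedigree_phase(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    panel: VariantPanel,
    max_exhaustive: int = 4096,
) -> PhaseSolution:
    """Per-individual unions of globally consistent diplotype states.

    Assumes single-locus Mendelian validation has been applied (see
    :func:`phase_variant_pair`, which applies it) and no recombination within
    the panel span, so a recombinant genotype pattern surfaces as an
    inconsistent pedigree rather than being silently explained.

    Strategy: enumerate per-individual candidate states from dosages, prune
    with arc consistency over transmission constraints, then, per connected
    component, either enumerate all consistent assignments directly (when the
    pruned state-space product is at most ``max_exhaustive``) or prove each
    surviving state reachable by backtracking search with that state pinned.
    """
    if len(panel) > MAX_PANEL:
        raise StructureError(f"panel size {len(panel)} exceeds the {MAX_PANEL}-locus cap")
    raw_domains = {
        iid: enumerate_individual_states(genotypes.dosages(iid, panel))
        for iid in sorted(pedigree.individuals)
    }
    domains = {iid: set(states) for iid, states in raw_domains.items()}
    empty = PhaseSolution(
        states={iid: frozenset() for iid in raw_domains}, consistent=False
    )
    if not all(domains.values()) or not _arc_consistency(pedigree, domains):
        empty.conflicting_family = _conflicting_family(pedigree, raw_domains)
        return empty

    unions: dict[str, set[DiplotypeState]] = {iid: set() for iid in domains}
    for component in _components(pedigree):
        order = _topological_order(pedigree, component)
        comp_domains = {iid: domains[iid] for iid in component}
        product = 1
        for iid in component:
            product *= len(comp_domains[iid])
            if product > max_exhaustive:
                break
        if product <= max_exhaustive:
            found_any = False
            for sol in _search(pedigree, order, comp_domains):
                found_any = True
                for iid, state in sol.items():
                    unions[iid].add(state)
            if not found_any:
                empty.conflicting_family = _conflicting_family(pedigree, raw_domains)
                return empty
        else:
            base = _first_solution(pedigree, order, comp_domains)
            if base is None:
                empty.conflicting_family = _conflicting_family(pedigree, raw_domains)
                return empty
            for iid, state in base.items():
                unions[iid].add(state)
            for iid in order:
                for state in sorted(comp_domains[iid]):
                    if state in unions[iid]:
                        continue
                    sol = _first_solution(pedigree, order, comp_domains, pin=(iid, state))
                    if sol is not None:
                        for jid, s in sol.items():
                            unions[jid].add(s)
    return PhaseSolution(states={iid: frozenset(s) for iid, s in unions.items()})


def exhaustive_phase_oracle(
    pedigree: Pedigree, genotypes: GenotypeMatrix, panel: VariantPanel
) -> PhaseSolution:
    """Brute-force reference with the same contract as :func:`solve_pedigree_phase`.

    Enumerates every joint assignment of dosage-compatible ordered diplotypes
    (no arc-consistency, no pinning) and collects per-individual unions.
    Refuses pedigrees above 10 members.
    """
    if len(pedigree) > ORACLE_MAX_MEMBERS:
        raise StructureError(
            f"exhaustive oracle refuses pedigrees above {ORACLE_MAX_MEMBERS} members "
            f"(got {len(pedigree)})"
        )
    domains = {
        iid: enumerate_individual_states(genotypes.dosages(iid, panel))
        for iid in sorted(pedigree.individuals)
    }
    unions: dict[str, set[DiplotypeState]] = {iid: set() for iid in domains}
    found_any = False
    order = _topological_order(pedigree, domains)
    for sol in _search(pedigree, order, domains):
        found_any = True
        for iid, state in sol.items():
            unions[iid].add(state)
    if not found_any:
        return PhaseSolution(
            states={iid: frozenset() for iid in domains},
            consistent=False,
            conflicting_family=_conflicting_family(pedigree, domains),
        )
    return PhaseSolution(states={iid: frozenset(s) for iid, s in unions.items()})


def _unordered(state: DiplotypeState) -> tuple[Haplotype, Haplotype]:
    a, b = state
    return (a, b) if a <= b else (b, a)


def _is_cis_type(state: DiplotypeState, ia: int, ib: int) -> bool:
    """True if some haplotype of the state carries the alt allele at both loci."""
    return any(h[ia] == 1 and h[ib] == 1 for h in state)


def phase_variant_pair(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    panel: VariantPanel,
    pair: tuple[str, str],
    mask_mendelian: bool = True,
    max_exhaustive: int = 4096,
) -> list[PhaseCall]:
    """CIS/TRANS calls for one variant pair across the pedigree.

    One call per member with non-missing dosages at both pair loci.  Members
    lacking the alt allele at either locus get NOT_DOUBLE_HET.  Carriers of
    both variants are called CIS when every surviving configuration places the
    two alt alleles on one haplotype (forced outright for hom-alt dosages),
    TRANS when every configuration separates them, UNINFORMATIVE when both
    kinds survive, and INCONSISTENT when the pedigree admits no configuration.

    When ``mask_mendelian`` is set (default), single-locus Mendelian
    violations are detected first and the offending child genotypes excluded
    (set MISSING) before phasing, since the inheritance argument assumes
    faithful transmission.
    """
    ia, ib = panel.index(pair[0]), panel.index(pair[1])
    if mask_mendelian:
        masked_keys = [
            (v.child, v.variant_id)
            for variant in panel
            for v in validate_mendelian_single_locus(pedigree, genotypes, variant)
        ]
        if masked_keys:
            genotypes = genotypes.masked(masked_keys)
    solution = solve_pedigree_phase(pedigree, genotypes, panel, max_exhaustive=max_exhaustive)

    def informative_relatives(iid: str) -> tuple[str, ...]:
        ind = pedigree.individuals[iid]
        relatives = [p for p in (ind.father, ind.mother) if p is not None]
        relatives += list(pedigree.children_of(iid))
        return tuple(
            r
            for r in relatives
            if genotypes.dosage(r, pair[0]) != MISSING or genotypes.dosage(r, pair[1]) != MISSING
        )

    calls: list[PhaseCall] = []
    for iid in sorted(pedigree.individuals):
        d_a = genotypes.dosage(iid, pair[0])
        d_b = genotypes.dosage(iid, pair[1])
        if d_a == MISSING or d_b == MISSING:
            continue
        evidence = informative_relatives(iid)
        if not solution.consistent:
            calls.append(PhaseCall(iid, pair, PhaseType.INCONSISTENT, 0, 0, evidence))
            continue
        if d_a == 0 or d_b == 0:
            calls.append(PhaseCall(iid, pair, PhaseType.NOT_DOUBLE_HET, 0, 0, evidence))
            continue
        states = {_unordered(s) for s in solution.states[iid]}
        n_cis = sum(1 for s in states if _is_cis_type(s, ia, ib))
        n_trans = len(states) - n_cis
        if n_cis and not n_trans:
            call = PhaseType.CIS
        elif n_trans and not n_cis:
            call = PhaseType.TRANS
        elif n_cis and n_trans:
            call = PhaseType.UNINFORMATIVE
        else:  # empty union for one member of a consistent pedigree: impossible
            call = PhaseType.INCONSISTENT
        calls.append(PhaseCall(iid, pair, call, n_cis, n_trans, evidence))
    return calls


def write_phase_calls(calls: Sequence[PhaseCall], path) -> None:
    """Write calls as a TSV: iid, pair, call, n_cis_configs, n_trans_configs, evidence."""
    from pathlib import Path

    lines = ["iid\tpair\tcall\tn_cis_configs\tn_trans_configs\tevidence"]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.iid,
                    f"{c.pair[0]},{c.pair[1]}",
                    c.call.value,
                    str(c.n_cis_configs),
                    str(c.n_trans_configs),
                    ";".join(c.evidence),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
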