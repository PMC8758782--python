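"""Phase engine: state enumeration, trio resolution, oracle equivalence."""

from __future__ import annotations

import pytest

from ocaphase import (
    MISSING,
    PhaseType,
    Population,
    SimulationConfig,
    StructureError,
    enumerate_individual_states,
    exhaustive_phase_oracle,
    phase_variant_pair,
    simulate_pedigrees,
    solve_pedigree_phase,
    truth_pair_phase,
)
from conftest import build_genotypes, build_pedigree

PAIR = ("S192Y", "R402Q")


def call_for(calls, iid):
    return next(c for c in calls if c.iid == iid)


class TestStateEnumeration:
    @pytest.mark.parametrize(
        "dosages,n_states",
        [
            ((2, 2), 1),  # homozygote: phase forced
            ((1, 1), 4),  # 2^2 ordered (cis x2, trans x2)
            ((1, MISSING), 8),  # 2 phases x 4 fillings of the missing locus
            ((0, 0), 1),
            ((1, 2), 2),
            ((MISSING, MISSING), 16),
        ],
    )
    def test_counts(self, dosages, n_states):
        assert len(enumerate_individual_states(dosages)) == n_states

    def test_states_match_dosages(self):
        for pat, mat in enumerate_individual_states((1, 2)):
            assert pat[0] + mat[0] == 1 and pat[1] + mat[1] == 2

    def test_refuses_beyond_four_loci(self):
        with pytest.raises(StructureError):
            enumerate_individual_states((1, 1, 1, 1, 1))


class TestTrioResolution:
    def test_homozygous_parent_forces_cis_in_child(self, trio_pedigree, two_locus_panel):
        """Father carries neither variant, mother is hom for both: the child's
        maternal haplotype carries both alts, so mother and child resolve CIS."""
        matrix = build_genotypes(
            {"dad": (0, 0), "mum": (1, 1), "kid": (1, 1)}, two_locus_panel
        )
        calls = phase_variant_pair(trio_pedigree, matrix, two_locus_panel, PAIR)
        assert call_for(calls, "mum").call is PhaseType.CIS
        assert call_for(calls, "kid").call is PhaseType.CIS
        assert call_for(calls, "dad").call is PhaseType.NOT_DOUBLE_HET

    def test_split_transmission_resolves_trans(self, trio_pedigree, two_locus_panel):
        """Child inherits S192Y without R402Q from the double-het mother, so
        the mother's variants must sit on opposite haplotypes."""
        matrix = build_genotypes(
            {"dad": (0, 0), "mum": (1, 1), "kid": (1, 0)}, two_locus_panel
        )
        calls = phase_variant_pair(trio_pedigree, matrix, two_locus_panel, PAIR)
        assert call_for(calls, "mum").call is PhaseType.TRANS

    def test_all_double_het_trio_is_uninformative(self, trio_pedigree, two_locus_panel):
        matrix = build_genotypes(
            {"dad": (1, 1), "mum": (1, 1), "kid": (1, 1)}, two_locus_panel
        )
        calls = phase_variant_pair(trio_pedigree, matrix, two_locus_panel, PAIR)
        for iid in ("dad", "mum", "kid"):
            call = call_for(calls, iid)
            assert call.call is PhaseType.UNINFORMATIVE
            assert call.n_cis_configs > 0 and call.n_trans_configs > 0

    def test_singleton_calls(self, two_locus_panel):
        ped = build_pedigree([("solo", None, None)])
        for dosages, expected in [
            ((2, 2), PhaseType.CIS),  # phase forced outright
            ((1, 2), PhaseType.CIS),  # the S192Y haplotype must carry R402Q
            ((1, 1), PhaseType.UNINFORMATIVE),  # no transmissions observed
            ((0, 1), PhaseType.NOT_DOUBLE_HET),
        ]:
            matrix = build_genotypes({"solo": dosages}, two_locus_panel)
            calls = phase_variant_pair(ped, matrix, two_locus_panel, PAIR)
            assert call_for(calls, "solo").call is expected, dosages

    def test_pair_order_symmetry(self, trio_pedigree, two_locus_panel):
        matrix = build_genotypes(
            {"dad": (0, 0), "mum": (1, 1), "kid": (1, 1)}, two_locus_panel
        )
        forward = phase_variant_pair(trio_pedigree, matrix, two_locus_panel, PAIR)
        backward = phase_variant_pair(
            trio_pedigree, matrix, two_locus_panel, (PAIR[1], PAIR[0])
        )
        assert [(c.iid, c.call) for c in forward] == [(c.iid, c.call) for c in backward]

    def test_jointly_inconsistent_pedigree_flagged(self, trio_pedigree, two_locus_panel):
        """Both parents lack S192Y but the child is het after masking is
        disabled: no global configuration exists."""
        matrix = build_genotypes(
            {"dad": (0, 0), "mum": (0, 0), "kid": (1, 0)}, two_locus_panel
        )
        solution = solve_pedigree_phase(trio_pedigree, matrix, two_locus_panel)
        assert not solution.consistent
        assert all(not states for states in solution.states.values())
        assert solution.conflicting_family == ("dad", "mum", ("kid",))
        calls = phase_variant_pair(
            trio_pedigree, matrix, two_locus_panel, PAIR, mask_mendelian=False
        )
        assert call_for(calls, "kid").call is PhaseType.INCONSISTENT

    def test_mendelian_masking_excludes_bad_genotype(self, trio_pedigree, two_locus_panel):
        """With masking on (default) the impossible child genotype is dropped
        and the remaining pedigree is phased normally."""
        matrix = build_genotypes(
            {"dad": (0, 0), "mum": (0, 0), "kid": (1, 0)}, two_locus_panel
        )
        calls = phase_variant_pair(trio_pedigree, matrix, two_locus_panel, PAIR)
        # kid's S192Y genotype was masked, so kid gets no call for this pair
        assert [c.iid for c in calls] == ["dad", "mum"]


class TestMonotoneInformativeness:
    def test_relatives_move_uninformative_to_resolved(self, two_locus_panel):
        solo = build_pedigree([("kid", None, None)])
        matrix = build_genotypes({"kid": (1, 1)}, two_locus_panel)
        assert (
            call_for(phase_variant_pair(solo, matrix, two_locus_panel, PAIR), "kid").call
            is PhaseType.UNINFORMATIVE
        )
        trio = build_pedigree([("dad", None, None), ("mum", None, None), ("kid", "dad", "mum")])
        matrix = build_genotypes(
            {"dad": (0, 0), "mum": (2, 2), "kid": (1, 1)}, two_locus_panel
        )
        assert (
            call_for(phase_variant_pair(trio, matrix, two_locus_panel, PAIR), "kid").call
            is PhaseType.CIS
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_masking_relatives_never_flips_resolved_calls(self, seed):
        """Hiding genotyped relatives can only lose information: an individual
        resolved CIS/TRANS in the restricted data keeps that call with the
        full data (adding relatives never flips CIS <-> TRANS)."""
        import numpy as np

        config = SimulationConfig(
            n_families=1, generations=2, sibship_mean=3,
            population=Population.EUROPEAN, seed=1000 + seed,
        )
        sim = simulate_pedigrees(config)
        panel = sim.panel
        full = phase_variant_pair(sim.pedigree, sim.genotypes, panel, PAIR)
        rng = np.random.default_rng(seed)
        iids = sorted(sim.pedigree.individuals)
        hidden = {iid for iid in iids if rng.random() < 0.4}
        masked = sim.genotypes.masked(
            (iid, vid) for iid in hidden for vid in panel.ids
        )
        restricted = phase_variant_pair(sim.pedigree, masked, panel, PAIR)
        full_by_iid = {c.iid: c.call for c in full}
        for c in restricted:
            if c.call in (PhaseType.CIS, PhaseType.TRANS):
                assert full_by_iid[c.iid] == c.call


def _simulate_small(seed, corrupt=False, max_members=10):
    """Small consistent family; optionally corrupt one dosage at random."""
    import numpy as np

    config = SimulationConfig(
        n_families=1, generations=2, sibship_mean=2,
        population=Population.EUROPEAN, seed=seed,
    )
    sim = simulate_pedigrees(config)
    if len(sim.pedigree) > max_members:
        return None
    genotypes = sim.genotypes
    if corrupt:
        rng = np.random.default_rng(seed + 10_000)
        iid = sorted(sim.pedigree.individuals)[int(rng.integers(len(sim.pedigree)))]
        vid = sim.panel.ids[int(rng.integers(len(sim.panel)))]
        genotypes = genotypes.masked([])
        genotypes.set(iid, vid, int(rng.integers(-1, 3)))
    return sim, genotypes


class TestOracleEquivalence:
    @pytest.mark.parametrize("corrupt", [False, True])
    def test_solver_matches_oracle_on_random_pedigrees(self, corrupt):
        """Arc-consistency + backtracking == brute-force enumeration, both on
        clean gene-dropped genotypes and after random corruption (which may
        make the pedigree inconsistent)."""
        n_checked = 0
        seed = 0
        while n_checked < 30:
            seed += 1
            out = _simulate_small(seed + (50_000 if corrupt else 0), corrupt=corrupt)
            if out is None:
                continue
            sim, genotypes = out
            fast = solve_pedigree_phase(sim.pedigree, genotypes, sim.panel)
            slow = exhaustive_phase_oracle(sim.pedigree, genotypes, sim.panel)
            assert fast.consistent == slow.consistent
            assert fast.states == slow.states
            n_checked += 1

    def test_oracle_refuses_large_pedigrees(self):
        sim = simulate_pedigrees(
            SimulationConfig(n_families=1, generations=3, sibship_mean=4, seed=7)
        )
        assert len(sim.pedigree) > 10
        with pytest.raises(StructureError, match="refuses"):
            exhaustive_phase_oracle(sim.pedigree, sim.genotypes, sim.panel)

    def test_planted_trans_founder_detected_by_both(self, two_locus_panel):
        """Gene-dropping a trans founder: the alt at one locus transmits
        without its partner, so both engines call the founder TRANS."""
        ped = build_pedigree(
            [("founder", None, None), ("spouse", None, None), ("kid", "founder", "spouse")]
        )
        matrix = build_genotypes(
            {"founder": (1, 1), "spouse": (0, 0), "kid": (1, 0)}, two_locus_panel
        )
        for solver in (solve_pedigree_phase, exhaustive_phase_oracle):
            solution = solver(ped, matrix, two_locus_panel)
            states = solution.states["founder"]
            assert states and all(
                not (h[0] == 1 and h[1] == 1) for s in states for h in s
            )
        calls = phase_variant_pair(ped, matrix, two_locus_panel, PAIR)
        assert call_for(calls, "founder").call is PhaseType.TRANS


class TestSoundnessOnSimulations:
    def test_calls_never_contradict_truth(self):
        """In the no-recombination, no-error regime every CIS/TRANS call must
        match the simulator's truth phase exactly."""
        panel_ids = None
        n_resolved = 0
        for seed in range(60):
            sim = simulate_pedigrees(
                SimulationConfig(
                    n_families=1, generations=3, sibship_mean=3,
                    population=Population.AMISH, seed=seed,
                )
            )
            if panel_ids is None:
                ia, ib = sim.panel.index(PAIR[0]), sim.panel.index(PAIR[1])
                panel_ids = True
            calls = phase_variant_pair(sim.pedigree, sim.genotypes, sim.panel, PAIR)
            for c in calls:
                assert c.call is not PhaseType.INCONSISTENT
                if c.call in (PhaseType.CIS, PhaseType.TRANS):
                    assert c.call.value == truth_pair_phase(sim.truth[c.iid], ia, ib)
                    n_resolved += 1
        assert n_resolved > 100  # the check must actually exercise resolved calls
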