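"""Search engine: pool enumeration, phase semantics, bookkeeping,
determinism, and oracle equivalence on toy surfaces."""

import numpy as np
import pytest

from _oracle import grid_minima, match_sets
from torsearch.fixtures import off_grid_pes, shared_basin_pes, single_well_pes, threefold_pes
from torsearch.molmodel import circular_distance, enantiomer
from torsearch.search import (
    PreconditionedAngles,
    SearchConfig,
    SearchEngine,
    SearchState,
    canonical_representative,
    expand_enantiomers,
    pairwise_min_distance,
    rereference_energies,
    systematic_pool,
)

SP3 = PreconditionedAngles.sp3_chain


class TestSystematicPool:
    @pytest.mark.parametrize("t,sym,expected", [
        (3, False, 27), (3, True, 14),
        (1, False, 3),
        (6, True, 365),
        (2, True, 5), (4, True, 41), (5, True, 122),
    ])
    def test_counts(self, t, sym, expected):
        assert len(systematic_pool(SP3(t), sym)) == expected

    def test_single_angle_single_point(self):
        assert len(systematic_pool(PreconditionedAngles([[180.0]]), False)) == 1

    def test_reduced_pool_is_enantiomer_free(self):
        pool = systematic_pool(SP3(3), True)
        keys = {tuple(p) for p in pool}
        n_self = sum(1 for p in pool if np.allclose(p, enantiomer(p)))
        assert n_self == 1  # only the all-anti point
        for p in pool:
            if tuple(p) not in keys:
                continue
            if not np.allclose(p, enantiomer(p)):
                assert tuple(enantiomer(p)) not in keys

    def test_asymmetric_list_with_sym_flag_is_an_error(self):
        with pytest.raises(ValueError, match="closed under"):
            systematic_pool(PreconditionedAngles([[60.0, 180.0]]), True)

    def test_duplicate_angles_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PreconditionedAngles([[60.0, 60.0]])


class TestCanonicalRepresentative:
    @pytest.mark.parametrize("phi,expected", [
        ((180, 300, 60), (180, 60, 300)),
        ((180, 180), (180, 180)),
        ((90, 10), (90, 10)),
    ])
    def test_examples(self, phi, expected):
        assert np.allclose(canonical_representative(phi), expected)

    def test_idempotent_and_orbit_stable(self, rng):
        for _ in range(20):
            phi = rng.uniform(0, 360, 4)
            c1 = canonical_representative(phi)
            assert np.allclose(c1, canonical_representative(c1))
            assert np.allclose(c1, canonical_representative(enantiomer(phi)))


class TestSystematicPhase:
    def test_single_well_single_point(self):
        pes = single_well_pes()
        eng = SearchEngine(pes.zm, pes, SearchConfig())
        state = eng.run_systematic(PreconditionedAngles([[180.0]]))
        assert (state.K1, state.K1_star, state.J) == (1, 1, 1)

    def test_two_guesses_share_a_basin(self):
        """Both gauche guesses slide into the single anti well: the second
        optimized structure is rejected as redundant, not re-counted."""
        pes = shared_basin_pes()
        eng = SearchEngine(pes.zm, pes, SearchConfig())
        state = eng.run_systematic(PreconditionedAngles([[60.0, 300.0]]))
        assert state.J == 1
        assert state.K1_star == 2

    def test_nine_wells_found_on_grid(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig())
        state = eng.run_systematic(SP3(2))
        assert state.J == 9
        oracle = grid_minima(pes_t2, 2)
        assert match_sets([c.phi_eq for c in state.equilibria], oracle, eps=3.0)

    def test_similarity_uses_equilibria_only(self, pes_t2):
        """A guess inside a stored *trial* hypercube but outside every
        equilibrium hypercube passes in the systematic phase and fails in
        the stochastic phase."""
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(d=30.0))
        state = SearchState()
        state.trials.append(np.array([100.0, 100.0]))
        state.K1_star += 1  # keep P consistent
        phi_g = np.array([110.0, 110.0])  # within 30 of the trial, no equilibria
        accepted_sys = eng._try_guess(state, phi_g, state.equilibrium_points, 30.0, "systematic")
        assert accepted_sys
        state2 = SearchState()
        state2.trials.append(np.array([100.0, 100.0]))
        state2.K1_star += 1
        accepted_sto = eng._try_guess(state2, phi_g, state2.stored_points, 30.0, "stochastic-0")
        assert not accepted_sto


class TestStochasticPhase:
    def test_sampler_reproducible_and_in_range(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(seed=7))
        a = [eng.sample_stochastic_point(np.random.default_rng(7)) for _ in range(5)]
        b = [eng.sample_stochastic_point(np.random.default_rng(7)) for _ in range(5)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        draws = np.array(a)
        assert np.all((draws >= 0) & (draws < 360))

    def test_uniform_mean(self):
        rng = np.random.default_rng(123)
        pes = single_well_pes()
        eng = SearchEngine(pes.zm, pes, SearchConfig())
        draws = np.array([eng.sample_stochastic_point(rng)[0] for _ in range(10_000)])
        se = 360.0 / np.sqrt(12.0) / np.sqrt(draws.size)
        assert abs(draws.mean() - 180.0) < 3 * se

    def test_no_new_minima_when_all_found(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2,
                           SearchConfig(seed=5, batches=[{"cycles": 60, "d": 30.0}]))
        state = eng.run_systematic(SP3(2))
        j_before = state.J
        eng.run_stochastic(state)
        assert state.J == j_before
        assert state.K2 == 60

    def test_huge_d_blocks_everything_after_first(self):
        pes = single_well_pes()
        eng = SearchEngine(pes.zm, pes,
                           SearchConfig(seed=2, batches=[{"cycles": 30, "d": 181.0}]))
        state = eng.run_stochastic()
        assert state.K2 == 30
        assert state.K2_star == 1  # only the very first point is ever accepted

    def test_off_grid_well_missed_systematically_found_stochastically(self):
        pes = off_grid_pes()
        eng = SearchEngine(pes.zm, pes,
                           SearchConfig(seed=11, batches=[{"cycles": 150, "d": 10.0}]))
        state = eng.run_systematic(SP3(1))
        assert state.J == 3  # 60 / 180 / 300 only: the 95-degree well is off-grid
        assert not any(circular_distance(c.phi_eq[0], 95.0) < 15.0 for c in state.equilibria)
        eng.run_stochastic(state)
        assert any(circular_distance(c.phi_eq[0], 95.0) < 15.0 for c in state.equilibria)
        oracle = grid_minima(pes, 1)
        assert match_sets([c.phi_eq for c in state.equilibria], oracle, eps=3.0)


class TestBookkeeping:
    def test_pool_identity_after_every_event(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2,
                           SearchConfig(seed=1, batches=[{"cycles": 40, "d": 20.0}]))
        state = eng.run(SP3(2))
        for ev in state.events:
            assert ev["P"] == ev["K1_star"] + ev["K2_star"] + ev["J"]

    def test_accepted_conformers_pairwise_distinct(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig())
        state = eng.run_systematic(SP3(2))
        assert pairwise_min_distance([c.phi_eq for c in state.equilibria]) > 3.0

    def test_determinism_bit_for_bit(self, pes_t2):
        def run():
            eng = SearchEngine(pes_t2.zm, pes_t2,
                               SearchConfig(seed=9, batches=[{"cycles": 30, "d": 25.0}]))
            return eng.run(SP3(2)).to_json()

        assert run() == run()

    def test_checkpoint_resume_equivalence(self, pes_t2):
        cfg = dict(seed=4, batches=[{"cycles": 25, "d": 20.0}])
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(**cfg))
        full = eng.run_systematic(SP3(2))
        eng.run_stochastic(full)
        rereference_energies(full)

        eng2 = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(**cfg))
        half = eng2.run_systematic(SP3(2))
        resumed = SearchState.from_json(half.to_json())
        eng3 = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(**cfg))
        eng3.run_stochastic(resumed)
        rereference_energies(resumed)
        assert resumed.to_json() == full.to_json()


class TestEnantiomerExpansion:
    def test_counts_with_one_self_enantiomer(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(has_sym_plane=True))
        state = eng.run_systematic(SP3(2))
        assert state.J == 5  # reduced pool for the 3x3 grid of wells
        n_self = sum(1 for c in state.equilibria if c.weight_w == 1)
        full = expand_enantiomers(state)
        assert len(full) == 2 * state.J - n_self
        assert n_self == 1
        assert len(full) == 9

    def test_all_self_enantiomeric_unchanged(self):
        pes = single_well_pes()
        eng = SearchEngine(pes.zm, pes, SearchConfig())
        state = eng.run_systematic(PreconditionedAngles([[180.0]]))
        assert len(expand_enantiomers(state)) == 1

    def test_mirror_members_have_identical_energy(self, pes_t2):
        eng = SearchEngine(pes_t2.zm, pes_t2, SearchConfig(has_sym_plane=True))
        state = eng.run_systematic(SP3(2))
        rereference_energies(state)
        for c in expand_enantiomers(state):
            if c.provenance.endswith("+mirror"):
                # the toy profile is mirror symmetric, so mirrored torsions
                # sit at a well of the same depth
                assert pes_t2.torsional_potential(c.phi_eq) == pytest.approx(
                    pes_t2.torsional_potential(enantiomer(c.phi_eq)), abs=1e-8)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_torsions", [1, 2])
    def test_threefold_surfaces(self, n_torsions):
        pes = threefold_pes(n_torsions)
        eng = SearchEngine(pes.zm, pes,
                           SearchConfig(seed=3, batches=[{"cycles": 40, "d": 20.0}]))
        state = eng.run(SP3(n_torsions))
        oracle = grid_minima(pes, n_torsions)
        assert match_sets([c.phi_eq for c in state.equilibria], oracle, eps=3.0)

    def test_three_torsions(self):
        pes = threefold_pes(3)
        eng = SearchEngine(pes.zm, pes, SearchConfig(seed=3))
        state = eng.run(SP3(3))
        assert state.J == 27
        oracle = grid_minima(pes, 3)
        assert match_sets([c.phi_eq for c in state.equilibria], oracle, eps=3.0)
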