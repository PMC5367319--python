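"""Three-island configuration dynamics: transition maps, increments, stepping."""

import math

import numpy as np
import pytest

from gcspec import (
    BondGraph,
    GCFractions,
    ModelParams,
    ThreeIslandState,
    increment_moments,
    migration_transition_map,
    migration_update,
    mutation_transition_map,
    mutation_update,
    simulate_three_island,
    step_three_island,
)
from gcspec.core import DIRECTED_BONDS
from gcspec.three_island import MIGRATION_TRANSITIONS, first_passage_three_island


def params(**kw):
    base = dict(l=100, u=1e-4, epsilon=0.01, z_c=0.9, m=0.005)
    base.update(kw)
    return ModelParams(**base)


class TestMutationTransitionMap:
    @pytest.mark.parametrize(
        "config, island, expected",
        [
            (1, "A", 2),  # (ABC) -> (A)(BC): A leaves the shared group
            (1, "B", 3),
            (1, "C", 4),
            (2, "B", 5),  # replacement on B or C splits (A)(BC) completely
            (2, "C", 5),
            (2, "A", 2),  # A already distinct: configuration preserved
            (3, "A", 5),
            (3, "B", 3),
            (4, "A", 5),
            (4, "C", 4),
            (5, "A", 5),  # all-distinct is absorbing under mutation
            (5, "C", 5),
        ],
    )
    def test_fixation_splits_sharing_groups(self, config, island, expected):
        assert mutation_transition_map(config, island) == expected

    def test_rejects_bad_labels(self):
        with pytest.raises(ValueError):
            mutation_transition_map(0, "A")
        with pytest.raises(ValueError):
            mutation_transition_map(1, "D")


class TestMigrationTransitionMap:
    @pytest.mark.parametrize(
        "config, bond, expected",
        [
            (2, "AB", 4),  # B adopts A's allele: (A)(BC) -> (C)(AB)
            (3, "AB", 1),  # (B)(CA) -> (ABC)
            (5, "AB", 4),
            (1, "AB", None),  # A and B already share: fixed point
            (4, "AB", None),
            (2, "BA", 1),
            (3, "BA", 4),
            (2, "AC", 3),
            (4, "AC", 1),
            (5, "AC", 3),
            (2, "CA", 1),
            (4, "CA", 3),
            (3, "BC", 2),
            (4, "BC", 1),
            (5, "BC", 2),
            (3, "CB", 1),
            (4, "CB", 2),
            (5, "CB", 2),
        ],
    )
    def test_destination_adopts_source_allele(self, config, bond, expected):
        assert migration_transition_map(config, bond) == expected

    def test_each_bond_has_three_transitions_and_two_fixed_points(self):
        for bond, trans in MIGRATION_TRANSITIONS.items():
            assert len(trans) == 3
            moved = {i for i, _ in trans}
            fixed = set(range(1, 6)) - moved
            # fixed points are exactly the configurations where the two
            # bonded islands already share an allele
            assert len(fixed) == 2
            for c in fixed:
                assert migration_transition_map(c, bond) is None

    def test_rejects_bad_bond(self):
        with pytest.raises(ValueError):
            migration_transition_map(2, "AA")


class TestMutationUpdate:
    def test_all_distinct_state_is_absorbing(self, rng):
        gc = GCFractions(0, 0, 0, 0, 1)
        dz = mutation_update(gc, params(), 1.0, rng)
        assert np.all(dz == 0)

    def test_increments_conserve_total_exactly(self, rng):
        gc = GCFractions(0.3, 0.2, 0.1, 0.25, 0.15)
        for _ in range(200):
            dz = mutation_update(gc, params(l=10, u=0.01), 1.0, rng)
            assert dz.sum() == pytest.approx(0.0, abs=1e-15)

    def test_mean_loss_from_shared_configuration(self, rng):
        """At an interior state the shared configuration decays at rate 3 u z1.

        Interior so the non-negativity caps never bind and bias the mean.
        """
        p = params(l=50, u=5e-4)
        gc = GCFractions(0.5, 0.125, 0.125, 0.125, 0.125)
        n = 20_000
        draws = np.array([mutation_update(gc, p, 1.0, rng)[0] for _ in range(n)])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - (-3 * p.u * 0.5)) < 3 * se

    def test_infinite_l_is_deterministic(self, rng):
        p = params(l=math.inf, u=1e-3)
        gc = GCFractions(0.5, 0.2, 0.1, 0.1, 0.1)
        dz1 = mutation_update(gc, p, 1.0, rng)
        dz2 = mutation_update(gc, p, 1.0, rng)
        assert np.array_equal(dz1, dz2)
        # mean accumulation terms: e.g. dz1 = -3 u z1
        assert dz1[0] == pytest.approx(-3 * p.u * 0.5)
        assert dz1[4] == pytest.approx(p.u * (2 * 0.2 + 2 * 0.1 + 2 * 0.1))


class TestMigrationUpdate:
    def test_fully_shared_state_has_no_outgoing_transition(self, rng):
        gc = GCFractions(1, 0, 0, 0, 0)
        dz = migration_update(gc, params(m=0.1), BondGraph(), 1.0, rng)
        assert np.all(dz == 0)

    def test_split_between_shared_and_distinct_leaves_zbc_invariant(self, rng):
        """Only bond A->B active on a (z1, z5) mix: every realisation moves
        mass 5 -> 4 only, which cancels inside z_BC = z3 + z4 + z5."""
        gc = GCFractions(1 / 3, 0, 0, 0, 2 / 3)
        p = params(m={"AB": 0.05}, u=0.0)
        for _ in range(300):
            dz = migration_update(gc, p, BondGraph(), 1.0, rng)
            assert dz[2] + dz[3] + dz[4] == pytest.approx(0.0, abs=1e-15)
            assert dz.sum() == pytest.approx(0.0, abs=1e-15)

    def test_closed_bond_contributes_nothing(self, rng):
        gc = GCFractions(0.2, 0.2, 0.2, 0.2, 0.2)
        p = params(m={"AB": 0.05}, u=0.0)
        closed_ab = BondGraph(closed=(True, False, False))
        for _ in range(50):
            dz = migration_update(gc, p, closed_ab, 1.0, rng)
            assert np.all(dz == 0)

    def test_outflow_capped_at_available_mass(self, rng):
        """Huge rates cannot drive a fraction negative within one step."""
        gc = GCFractions(0.0, 0.001, 0.0, 0.0, 0.999)
        p = ModelParams(l=10, u=0.0, epsilon=0.25, z_c=0.9, m=0.5)
        for _ in range(200):
            dz = migration_update(gc, p, BondGraph(), 1.0, rng)
            new = gc.as_array() + dz
            assert np.all(new >= -1e-12)


class TestIncrementMoments:
    def test_case2_variance_of_zbc_matches_compound_poisson(self):
        """With the three two-group configurations equally abundant, a lone
        A->B bond leaves Var(dz_BC) = m dt z eps(1-eps)/l with z = z_BC = 2/3:
        the two binomial sampling contributions z2 and z3 add, while the
        shared-timing parts cancel inside the z_BC projection."""
        p = ModelParams(l=99, u=0.0, epsilon=0.05, z_c=0.9, m={"AB": 0.02})
        gc = GCFractions(0, 1 / 3, 1 / 3, 1 / 3, 0)
        _, cov = increment_moments(gc, p, dt=1.0)
        v = np.array([0, 0, 1, 1, 1.0])
        expected = 0.02 * (2 / 3) * 0.05 * 0.95 / 99
        assert v @ cov @ v == pytest.approx(expected, rel=1e-12)

    def test_case1_variance_of_zbc_is_zero(self):
        p = ModelParams(l=99, u=0.0, epsilon=0.05, z_c=0.9, m={"AB": 0.02})
        gc = GCFractions(1 / 3, 0, 0, 0, 2 / 3)
        _, cov = increment_moments(gc, p, dt=1.0)
        v = np.array([0, 0, 1, 1, 1.0])
        assert v @ cov @ v == pytest.approx(0.0, abs=1e-18)

    def test_mean_of_z2_assembles_eight_flow_terms(self):
        """dz2 collects -outflows (AB, BA, AC, CA) and +inflows (BC, CB)."""
        m = {"AB": 0.01, "BA": 0.02, "AC": 0.03, "CA": 0.04, "BC": 0.05, "CB": 0.06}
        p = ModelParams(l=50, u=0.0, epsilon=0.1, z_c=0.9, m=m)
        z = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        mean, _ = increment_moments(GCFractions(*z), p, dt=1.0)
        eps = 0.1
        expected = eps * (
            -(m["AB"] + m["BA"] + m["AC"] + m["CA"]) * z[1]
            + m["BC"] * (z[2] + z[4])
            + m["CB"] * (z[4] + z[3])
        )
        assert mean[1] == pytest.approx(expected, rel=1e-12)

    def test_empirical_step_moments_match_analytic(self, rng):
        """The sampled increments reproduce their own analytic moments."""
        p = params(l=40, u=5e-4, epsilon=0.05, m=0.02)
        gc = GCFractions(0.25, 0.25, 0.2, 0.15, 0.15)
        n = 30_000
        draws = np.empty((n, 5))
        for i in range(n):
            draws[i] = mutation_update(gc, p, 1.0, rng) + migration_update(
                gc, p, BondGraph(), 1.0, rng
            )
        mean_a, cov_a = increment_moments(gc, p, dt=1.0)
        se_mean = draws.std(axis=0, ddof=1) / math.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - mean_a) < 4 * se_mean)
        # variances: wide relative tolerance absorbs fourth-moment noise
        assert np.allclose(draws.var(axis=0, ddof=1), np.diag(cov_a), rtol=0.1)


class TestStepping:
    def test_no_rates_leave_state_unchanged(self, rng):
        p = params(u=0.0, m=0.0)
        s0 = ThreeIslandState(0.0, GCFractions(0.3, 0.2, 0.2, 0.2, 0.1), BondGraph())
        s1, label = step_three_island(s0, p, 1.0, rng)
        assert s1.gc.as_array() == pytest.approx(s0.gc.as_array(), abs=1e-15)
        assert label == "one_species"

    def test_fractions_sum_to_one_after_every_step(self, rng):
        p = params(l=10, u=1e-3, m=0.02, epsilon=0.05)
        s = ThreeIslandState(0.0, GCFractions(1, 0, 0, 0, 0), BondGraph())
        for _ in range(500):
            s, _ = step_three_island(s, p, 1.0, rng)
            assert s.gc.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_migration_gives_symmetric_long_run_distances(self, rng):
        """Equal rates on all bonds: the three time-averaged distances agree."""
        p = params(l=100, u=1e-4, epsilon=0.01, m=0.005, z_c=1.0)
        traj, _ = simulate_three_island(
            p, t_max=40_000, record_stride=20, rng=rng
        )
        tail = traj[traj.t > 20_000]
        means = np.array([tail.zAB.mean(), tail.zBC.mean(), tail.zCA.mean()])
        # common quasi-equilibrium near u/(u + m*eps) = 2/3
        assert np.all(np.abs(means - means.mean()) < 0.08)
        assert abs(means.mean() - 2 / 3) < 0.1

    def test_isolated_island_dominates_its_configuration(self, rng):
        """Rare migration to/from A (Fig-2c-style rates) makes the
        A-differs configuration dominate and z_AB, z_CA exceed z_BC."""
        m = {"AB": 0.001, "BA": 0.001, "CA": 0.001, "AC": 0.001,
             "BC": 0.01, "CB": 0.01}
        p = params(l=100, u=1e-4, epsilon=0.01, m=m, z_c=1.0)
        traj, _ = simulate_three_island(p, t_max=40_000, record_stride=20, rng=rng)
        tail = traj[traj.t > 20_000]
        assert tail.z2.mean() > tail.z3.mean()
        assert tail.z2.mean() > tail.z4.mean()
        assert tail.zAB.mean() > tail.zBC.mean()
        assert tail.zCA.mean() > tail.zBC.mean()

    def test_zero_threshold_speciates_immediately(self, rng):
        p = params(l=20, u=1e-3, z_c=0.0, m=0.0)
        traj, rec = simulate_three_island(p, t_max=100, rng=rng, stop_at_tau3=True)
        assert rec.tau2 == rec.tau3 == traj.t.iloc[1]  # first step

    def test_waiting_times_ordered_and_recorded(self, rng):
        p = ModelParams(l=20, u=0.000075, epsilon=0.01, z_c=0.3, m=0.01)
        tau2, tau3 = first_passage_three_island(
            p, reps=10, t_max=100_000, rng=rng
        )
        assert not np.any(np.isnan(tau2)) and not np.any(np.isnan(tau3))
        assert np.all(tau3 >= tau2)

    def test_severed_bonds_stop_mixing_after_split(self, rng):
        """Once two species exist, distance across severed bonds keeps
        growing under mutation instead of reverting to the old balance."""
        p = ModelParams(l=50, u=5e-4, epsilon=0.02, z_c=0.4, m=0.01)
        traj, rec = simulate_three_island(p, t_max=30_000, rng=rng)
        assert rec.tau2 is not None
        after = traj[traj.t > rec.tau2 + 5_000]
        if len(after):  # distances keep climbing past the threshold
            assert after[["zAB", "zBC", "zCA"]].max(axis=1).mean() > 0.4
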