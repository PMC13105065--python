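"""Simulator unit and property tests against the mean-field oracle."""

import numpy as np
import pytest

from idletrace.population import (
    LineagePopulation,
    PhenotypeLandscape,
    PhenotypeState,
    mean_field_solution,
    run_treatment_protocol,
    simulate,
)


class TestTypes:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeState("bad", -0.1, 0.0)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeLandscape(
                (PhenotypeState("a", 0, 0), PhenotypeState("b", 0, 0)),
                np.array([[0.1, 0.0], [0.0, 0.0]]),
            )

    def test_transition_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeLandscape((PhenotypeState("a", 0, 0),),
                               np.zeros((2, 2)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LineagePopulation({"L": np.array([-1])})


class TestSimulate:
    def test_no_events_population_constant(self):
        ls = PhenotypeLandscape((PhenotypeState("s", 0.0, 0.0),),
                                np.zeros((1, 1)))
        init = LineagePopulation({"A": np.array([100])})
        traj = simulate(ls, init, 48.0, [0, 12, 24, 48], seed=0)
        assert np.array_equal(traj.totals(), [100, 100, 100, 100])

    def test_conservation_under_pure_transitions(self):
        # zero division/death: transitions shuffle states, never total count
        states = (PhenotypeState("a", 0, 0), PhenotypeState("b", 0, 0))
        k = np.array([[0.0, 0.5], [0.2, 0.0]])
        ls = PhenotypeLandscape(states, k)
        init = LineagePopulation({"A": np.array([40, 10]),
                                  "B": np.array([5, 25])})
        traj = simulate(ls, init, 30.0, [10, 20, 30], seed=3)
        assert all(s.total() == 80 for s in traj.snapshots)
        for snap in traj.snapshots:
            assert snap.counts["A"].sum() == 50
            assert snap.counts["B"].sum() == 30

    def test_seed_reproducibility_bit_identical(self, balanced_two_state,
                                                small_population):
        t1 = simulate(balanced_two_state, small_population, 24, [12, 24],
                      seed=7)
        t2 = simulate(balanced_two_state, small_population, 24, [12, 24],
                      seed=7)
        for a, b in zip(t1.snapshots, t2.snapshots):
            for lin in a.counts:
                assert np.array_equal(a.counts[lin], b.counts[lin])

    def test_different_seeds_differ(self, balanced_two_state,
                                    small_population):
        t1 = simulate(balanced_two_state, small_population, 48, [48], seed=1)
        t2 = simulate(balanced_two_state, small_population, 48, [48], seed=2)
        same = all(
            np.array_equal(t1.snapshots[0].counts[k],
                           t2.snapshots[0].counts[k])
            for k in t1.snapshots[0].counts
        )
        assert not same

    def test_empty_population_warns_and_stays_zero(self, one_state_growing):
        init = LineagePopulation({"A": np.array([0])})
        with pytest.warns(UserWarning):
            traj = simulate(one_state_growing, init, 10, [5, 10], seed=0)
        assert traj.empty_start
        assert np.array_equal(traj.totals(), [0, 0])

    def test_lineage_identity_heritable(self, one_state_growing):
        init = LineagePopulation({"only": np.array([500])})
        traj = simulate(one_state_growing, init, 24, [24], seed=5)
        assert set(traj.snapshots[-1].counts) == {"only"}

    def test_ensemble_mean_matches_branching_mean(self, one_state_growing):
        # E[N_t] = N0 * exp((b-d) t) for the linear birth-death process
        n_rep, n0, t = 500, 1000, 48.0
        totals = np.empty(n_rep)
        for r in range(n_rep):
            init = LineagePopulation({"A": np.array([n0])})
            totals[r] = simulate(one_state_growing, init, t, [t],
                                 seed=r).totals()[0]
        expected = n0 * np.exp(0.02 * t)
        sem = totals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(totals.mean() - expected) < 3 * sem

    def test_tau_leaping_tracks_mean_field(self, one_state_growing):
        init = LineagePopulation({"A": np.array([200_000])})
        traj = simulate(one_state_growing, init, 48, [48], seed=2,
                        method="tau", tau=0.25)
        expected = 200_000 * np.exp(0.96)
        assert abs(traj.totals()[0] - expected) / expected < 0.02

    def test_invalid_record_times_rejected(self, one_state_growing,
                                           small_population):
        with pytest.raises(ValueError):
            simulate(one_state_growing, small_population, 10, [5, 20],
                     seed=0)


class TestMeanField:
    def test_scalar_exponential(self):
        ls = PhenotypeLandscape((PhenotypeState("s", 0.03, 0.01),),
                                np.zeros((1, 1)))
        out = mean_field_solution(ls, [1000], [48.0])
        assert out[0, 0] == pytest.approx(1000 * np.exp(0.96), rel=1e-12)

    def test_all_rates_zero_identity(self):
        states = (PhenotypeState("a", 0, 0), PhenotypeState("b", 0, 0))
        ls = PhenotypeLandscape(states, np.zeros((2, 2)))
        out = mean_field_solution(ls, [7, 3], [0.0, 5.0, 50.0])
        assert np.allclose(out, [[7, 7, 7], [3, 3, 3]])

    def test_symmetric_transitions_converge_to_half(self):
        # equal net rates + symmetric switching: occupancy -> 50/50,
        # the dominant eigenvector of the generator
        states = (PhenotypeState("a", 0.03, 0.01),
                  PhenotypeState("b", 0.03, 0.01))
        k = np.array([[0.0, 0.1], [0.1, 0.0]])
        ls = PhenotypeLandscape(states, k)
        out = mean_field_solution(ls, [100, 0], [200.0])
        frac = out[:, 0] / out[:, 0].sum()
        assert np.allclose(frac, [0.5, 0.5], atol=1e-6)
        evals, evecs = np.linalg.eig(ls.rate_matrix())
        lead = evecs[:, np.argmax(evals.real)].real
        lead = np.abs(lead) / np.abs(lead).sum()
        assert np.allclose(frac, lead, atol=1e-9)

    def test_oracle_equivalence_small_ensemble(self, balanced_two_state):
        # stochastic per-state means track exp(tA) n0 within 3 SEM
        n_rep, t = 400, 20.0
        n0 = np.array([60, 40])
        ens = np.empty((n_rep, 2))
        for r in range(n_rep):
            init = LineagePopulation({"L": n0.copy()})
            traj = simulate(balanced_two_state, init, t, [t], seed=10_000 + r)
            ens[r] = traj.snapshots[0].counts["L"]
        expected = mean_field_solution(balanced_two_state, n0, [t])[:, 0]
        sem = ens.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(ens.mean(axis=0) - expected) < 3 * sem)


class TestTreatmentProtocol:
    def _landscapes(self):
        unt = PhenotypeLandscape(
            (PhenotypeState("u1", 0.04, 0.04), PhenotypeState("u2", 0.04, 0.04)),
            np.array([[0.0, 0.01], [0.01, 0.0]]), label="untreated")
        drg = PhenotypeLandscape(
            (PhenotypeState("d1", 0.02, 0.02), PhenotypeState("d2", 0.05, 0.05)),
            np.array([[0.0, 0.002], [0.002, 0.0]]), label="drugged")
        return unt, drg

    def test_bad_state_map_rejected(self, small_population):
        unt, drg = self._landscapes()
        with pytest.raises(ValueError):
            run_treatment_protocol(unt, drg, np.array([[0.5, 0.4],
                                                       [0.5, 0.5]]),
                                   small_population, 24, 24, [48], seed=0)

    def test_lineages_preserved_across_switch(self, small_population):
        unt, drg = self._landscapes()
        sm = np.array([[0.8, 0.2], [0.8, 0.2]])
        traj = run_treatment_protocol(unt, drg, sm, small_population,
                                      24, 24, [0, 24, 48], seed=9)
        assert set(traj.snapshots[-1].counts) == {"L1", "L2", "L3"}
        assert len(traj.landscape_schedule) == 2
        assert traj.landscape_schedule[1][1] == "drugged"

    def test_idling_map_gives_flat_mean(self):
        # all cells to a division=death state: expected total is constant
        unt, _ = self._landscapes()
        drg = PhenotypeLandscape((PhenotypeState("idle", 0.03, 0.03),),
                                 np.zeros((1, 1)), label="idle")
        sm = np.array([[1.0], [1.0]])
        n_rep = 200
        finals = np.empty(n_rep)
        for r in range(n_rep):
            init = LineagePopulation.uniform(["L"], 2, 250)
            traj = run_treatment_protocol(unt, drg, sm, init, 12, 48,
                                          [60], seed=r)
            finals[r] = traj.totals()[-1]
        sem = finals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(finals.mean() - 250) < 3 * sem
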