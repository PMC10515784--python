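"""Metropolis engine: proposals, acceptance rule, determinism, bookkeeping."""

import math

import numpy as np
import pytest

import epbdsim as E
from epbdsim.mcmc import _metropolis_chunk


def _sched(**kw):
    base = dict(preheat_steps=100, measure_steps=400, record_interval=10,
                n_runs=2, base_seed=0)
    base.update(kw)
    return E.MCMCSchedule(**base)


class TestProposal:
    def test_zero_sigma_returns_current(self):
        rng = np.random.default_rng(0)
        y = np.array([0.3, 0.1])
        assert E.propose_move(y, 0, None, 0.0, rng) == 0.3

    def test_strand_accounting_scales_width(self):
        draws_y, draws_strand = [], []
        for i in range(20_000):
            rng = np.random.default_rng(i)
            draws_y.append(E.propose_move(np.zeros(1), 0, None, 1.0, rng))
            rng = np.random.default_rng(i)
            draws_strand.append(E.propose_move(np.zeros(1), 0, "left", 1.0, rng))
        assert np.allclose(np.array(draws_strand) * np.sqrt(2), draws_y)

    def test_proposals_centred_on_current(self):
        rng = np.random.default_rng(3)
        current = 1.7
        n = 100_000
        draws = current + rng.standard_normal(n) * 0.4
        assert abs(draws.mean() - current) < 4 * 0.4 / math.sqrt(n)


class TestAcceptanceRule:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(E.metropolis_accept(-0.1, 310.0, E.KB_EV_PER_K, rng) for _ in range(100))

    def test_half_acceptance_at_kT_ln2(self):
        rng = np.random.default_rng(1)
        kB, T = E.KB_EV_PER_K, 310.0
        de = kB * T * math.log(2.0)
        n = 40_000
        hits = sum(E.metropolis_accept(de, T, kB, rng) for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 4 * se


class TestStep:
    def test_zero_sigma_sweep_keeps_state(self, params):
        sp = E.resolve_site_parameters(E.DNASequence("ACGTA"), params)
        rng = np.random.default_rng(9)
        y = np.array([0.2, 0.0, 1.0, 0.5, 0.1])
        before = y.copy()
        accepted, de = E.mcmc_step(y, sp, 310.0, np.zeros(5), rng, convention="sweep")
        assert accepted == 5  # dE = 0 -> P = 1
        assert de == 0.0
        assert np.array_equal(y, before)

    def test_step_is_deterministic_in_seed(self, params):
        sp = E.resolve_site_parameters(E.DNASequence("ACGTA"), params)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(1234)
            y = np.full(5, 0.1)
            for _ in range(50):
                E.mcmc_step(y, sp, 310.0, np.full(5, 0.3), rng, convention="sweep")
            outs.append(y.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_kernel_matches_python_reference(self, params):
        """The compiled chunk kernel reproduces an explicit Metropolis loop."""
        seq = E.generate_fixture("promoter_like", 12, seed=7)
        sp = E.resolve_site_parameters(seq, params)
        rng = np.random.default_rng(2024)
        n_prop = 3000
        sites = rng.integers(0, 12, size=n_prop)
        gauss = rng.standard_normal(n_prop)
        unif = rng.random(n_prop)
        sigma = np.full(12, 0.3)
        beta = 1.0 / (sp.kB * 310.0)

        y_ref = np.zeros(12)
        acc_ref = 0
        for p in range(n_prop):
            i = int(sites[p])
            new = y_ref[i] + gauss[p] * sigma[i]
            if sp.y_min <= new <= sp.y_max:
                de = E.delta_energy(y_ref, i, new, sp)
                if de <= 0 or unif[p] < math.exp(-beta * de):
                    y_ref[i] = new
                    acc_ref += 1

        y_k = np.zeros(12)
        snaps = np.empty((0, 12))
        acc_k, _, _ = _metropolis_chunk(
            y_k, sp.D, sp.a, sp.k, sp.rho, sp.b, beta, sp.y_min, sp.y_max,
            sp.periodic, sites, gauss, unif, sigma, 0, snaps, 0,
        )
        assert acc_k == acc_ref
        assert np.allclose(y_k, y_ref, atol=1e-12)


class TestRunSimulation:
    def test_snapshot_count_formula(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        traj = E.run_simulation(seq, params, _sched(measure_steps=100, record_interval=10), 0)
        assert traj.n_snapshots == 10

    def test_zero_snapshot_schedule_rejected(self):
        with pytest.raises(E.ScheduleError):
            E.MCMCSchedule(measure_steps=5, record_interval=10)

    def test_same_seed_reproduces_snapshots(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        t1 = E.run_simulation(seq, params, _sched(), 3)
        t2 = E.run_simulation(seq, params, _sched(), 3)
        assert np.array_equal(t1.snapshots, t2.snapshots)
        assert t1.acceptance_count == t2.acceptance_count

    def test_low_temperature_freezes_chain(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        sched = _sched(temperature=1.0, preheat_steps=500, measure_steps=1000)
        traj = E.run_simulation(seq, params, sched, 1)
        assert np.abs(traj.snapshots).mean() < 0.05

    def test_snapshots_respect_bounds(self, small_ensemble, params):
        stacked = small_ensemble.stacked()
        assert stacked.min() >= params.y_min_bound
        assert stacked.max() <= params.y_max_bound

    def test_running_energy_matches_recompute(self, params):
        """The energy maintained from per-move deltas agrees with a
        from-scratch total after a thousand steps."""
        seq = E.generate_fixture("promoter_like", 25, seed=4)
        sched = _sched(preheat_steps=0, measure_steps=1000, record_interval=1000,
                       step_convention="single")
        sp = E.resolve_site_parameters(seq, params)
        traj = E.run_simulation(seq, params, sched, 0)
        assert traj.final_energy == pytest.approx(
            E.total_energy(traj.final_state, sp), abs=1e-8
        )

    def test_single_convention_counts_one_proposal_per_step(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        sched = _sched(step_convention="single")
        traj = E.run_simulation(seq, params, sched, 0)
        assert traj.proposal_count == sched.preheat_steps + sched.n_snapshots * sched.record_interval
        sweep = E.run_simulation(seq, params, _sched(), 0)
        assert sweep.proposal_count == traj.proposal_count * 10


class TestEnsemble:
    def test_single_run_reduces_to_run_simulation(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        ens = E.run_ensemble(seq, params, _sched(n_runs=1))
        traj = E.run_simulation(seq, params, _sched(n_runs=1), 0)
        assert np.array_equal(ens.trajectories[0].snapshots, traj.snapshots)

    def test_runs_are_order_independent(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        ens = E.run_ensemble(seq, params, _sched(n_runs=4))
        # recomputing any single run in isolation gives the same trajectory
        for i in (3, 0, 2):
            solo = E.run_simulation(seq, params, _sched(n_runs=4), i)
            assert np.array_equal(solo.snapshots, ens.trajectories[i].snapshots)

    def test_runs_differ_between_seeds(self, params):
        seq = E.DNASequence("ACGTACGTAC")
        ens = E.run_ensemble(seq, params, _sched(n_runs=3))
        assert not np.array_equal(ens.trajectories[0].snapshots, ens.trajectories[1].snapshots)

    def test_ensemble_mean_self_consistent_across_run_lengths(self, params):
        """Ensembles of short and of 4x-longer runs estimate the same mean
        displacement: both are unbiased, so they agree within combined
        run-to-run errors."""
        seq = E.generate_fixture("promoter_like", 10, seed=6)
        short = E.run_ensemble(seq, params, _sched(
            preheat_steps=2000, measure_steps=2000, record_interval=10, n_runs=20, base_seed=5))
        longer = E.run_ensemble(seq, params, _sched(
            preheat_steps=2000, measure_steps=8000, record_interval=10, n_runs=20, base_seed=99))
        a = short.per_run_means().mean(axis=1)
        b = longer.per_run_means().mean(axis=1)
        se = np.hypot(a.std(ddof=1) / np.sqrt(20), b.std(ddof=1) / np.sqrt(20))
        assert abs(a.mean() - b.mean()) < 4 * se

    def test_auto_sigma_acceptance_in_sane_band(self, params):
        seq = E.generate_fixture("promoter_like", 30, seed=3)
        sched = _sched(preheat_steps=1000, measure_steps=3000, n_runs=3, base_seed=1)
        ens = E.run_ensemble(seq, params, sched)
        rate = np.mean([t.acceptance_rate for t in ens.trajectories])
        assert 0.2 <= rate <= 0.7
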