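import numpy as np
import pytest

from altdyn.core_state import HostStrain, Params, SystemState, ViralStrain
from altdyn.ssa import (apply_adsorption, channel_rates, default_initial_state,
                        run)

from oracles import logistic_quasi_stationary_mean


def _host_only(K=500, H0=100, t_max=100.0, seed=0):
    p = Params(r=1.0, d=0.1, phi=0.0, q=0.0, mu=0.0, beta=50, g=3, K=K,
               t_max=t_max, sample_dt=1.0, seed=seed)
    return p, SystemState(0.0, [HostStrain(1, frozenset(), H0)], [], p)


def _virus_only(V0=1000, d=0.1, t_max=10.0, seed=0):
    p = Params(r=1.0, d=d, phi=0.0, q=0.0, mu=0.0, beta=50, g=3, K=500,
               t_max=t_max, sample_dt=1.0, seed=seed)
    return p, SystemState(0.0, [], [ViralStrain(1, (1, 2, 3), V0)], p)


class TestChannelRates:
    def test_host_only_channels(self):
        p, init = _host_only(K=1000, H0=100)
        chans = channel_rates(init)
        by_kind = {c.kind: c.rate for c in chans}
        assert by_kind == {"host_replication": 100.0,
                          "host_competition_death": 10.0}

    def test_empty_state(self):
        p = Params()
        assert channel_rates(SystemState(0.0, [], [], p)) == []

    def test_adsorption_rate(self):
        p = Params(phi=1e-7, w=0.0)
        s = SystemState(0.0, [HostStrain(1, frozenset(), 5)],
                        [ViralStrain(2, tuple(range(1, p.g + 1)), 10)], p)
        ads = [c for c in channel_rates(s) if c.kind == "adsorption"]
        assert len(ads) == 1
        assert ads[0].rate == pytest.approx(5e-6)

    def test_washout_channel_present_when_positive(self):
        p, init = _host_only()
        pw = Params(**{**p.__dict__, "w": 0.05})
        s = SystemState(0.0, init.hosts, [], pw)
        kinds = {c.kind for c in channel_rates(s)}
        assert "host_washout" in kinds


class TestApplyAdsorption:
    def setup_method(self):
        self.p = Params(r=1, d=0.1, phi=1e-6, q=0.0, mu=0.0, beta=10, g=3,
                        K=1000)

    def _state(self, spacers, q=0.0, mu=0.0):
        p = Params(**{**self.p.__dict__, "q": q, "mu": mu})
        h = HostStrain(1, frozenset(spacers), 20)
        v = ViralStrain(2, (1, 2, 3), 30)
        return SystemState(0.0, [h], [v], p), h, v

    def test_protected_host_only_loses_virion(self):
        s, h, v = self._state({1})
        rng = np.random.default_rng(0)
        out = apply_adsorption(s, v, h, rng)
        assert out.V == 29 and out.N == 20
        assert len(out.hosts) == 1 and len(out.viruses) == 1

    def test_susceptible_lysis_no_mutation(self):
        s, h, v = self._state(set())
        out = apply_adsorption(s, v, h, np.random.default_rng(0))
        assert out.V == 30 - 1 + 10  # burst of beta replaces the adsorbed virion
        assert out.N == 19
        assert len(out.viruses) == 1  # no new strains at mu=0

    def test_acquisition_moves_cell_to_new_strain(self):
        s, h, v = self._state(set(), q=1.0)
        out = apply_adsorption(s, v, h, np.random.default_rng(0))
        assert out.V == 29
        assert out.N == 20  # cell moved, not lost
        assert len(out.hosts) == 2
        new = [x for x in out.hosts if x.id != 1][0]
        assert len(new.spacers) == 1
        assert next(iter(new.spacers)) in v.repertoire

    def test_expected_mutant_offspring_matches_binomial_oracle(self):
        # E[mutant offspring per lysis] = beta*(1-(1-mu)^g)
        mu, g, beta = 0.01, 15, 50
        p = Params(r=1, d=0.1, phi=1e-6, q=0.0, mu=mu, beta=beta, g=g, K=1000)
        h = HostStrain(1, frozenset(), 10**6)
        v = ViralStrain(2, tuple(range(1, g + 1)), 10**6)
        s = SystemState(0.0, [h], [v], p)
        rng = np.random.default_rng(42)
        n = 20_000
        mutants = 0
        for _ in range(n):
            out = apply_adsorption(s, v, h, rng)
            mutants += len(out.viruses) - 1
        expected = beta * (1 - (1 - mu) ** g)
        se = np.sqrt(expected / n)  # Poisson-scale bound on the SE
        assert abs(mutants / n - expected) < 3 * max(se, 0.03)

    def test_zero_abundance_rejected(self):
        s, h, v = self._state(set())
        dead = ViralStrain(9, (4, 5, 6), 0)
        with pytest.raises(ValueError):
            apply_adsorption(s, dead, h, np.random.default_rng(0))


class TestRun:
    def test_empty_initial_returns_flat_series(self):
        p = Params(t_max=5.0, sample_dt=1.0)
        res = run(p, SystemState(0.0, [], [], p))
        assert res.series.N.tolist() == [0] * 6
        assert res.series.V.tolist() == [0] * 6
        assert res.n_events == 0

    def test_pure_decay_mean_matches_linear_death_process(self):
        # E[V(10)] = 1000*exp(-0.1*10) ~ 367.9
        vals = []
        for seed in range(200):
            p, init = _virus_only(seed=seed)
            vals.append(run(p, init).series.V[-1])
        vals = np.asarray(vals, dtype=float)
        expect = 1000 * np.exp(-1.0)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) < 3 * se

    def test_logistic_quasi_stationary_mean(self):
        # time-average of N over [20,100] vs enumerated quasi-stationary mean
        means = []
        for seed in range(200):
            p, init = _host_only(seed=seed)
            s = run(p, init).series
            means.append(s.N[20:].mean())
        means = np.asarray(means)
        expect = logistic_quasi_stationary_mean(r=1.0, K=500)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expect) < 3 * max(se, 1e-3)

    def test_bit_identical_reproducibility(self):
        from altdyn.experiments import reduced_params
        p = reduced_params(seed=7, t_max=60.0)
        a = run(p)
        b = run(p)
        assert np.array_equal(a.series.N, b.series.N)
        assert np.array_equal(a.series.V, b.series.V)
        assert a.series.host_samples == b.series.host_samples
        assert a.series.viral_samples == b.series.viral_samples
        assert a.n_events == b.n_events

    def test_event_guard_signals_runaway(self):
        p, init = _host_only(t_max=100.0)
        with pytest.raises(RuntimeError, match="guard"):
            run(p, init, max_events=50)


class TestRunStructure:
    def test_infinite_alleles_every_mutation_is_novel(self, small_run):
        res = small_run
        first_seen: dict[int, float] = {}
        for v in sorted(res.viruses.values(), key=lambda s: s.t_birth):
            parent = res.viruses.get(v.parent_id)
            inherited = set(parent.repertoire) if parent else set()
            for a in v.repertoire:
                if a in inherited:
                    continue
                assert a not in first_seen, \
                    f"allele {a} reused at t={v.t_birth}"
                first_seen[a] = v.t_birth
        assert len(first_seen) > len(res.viruses[2].repertoire) - 1

    def test_host_acquisition_adds_exactly_one_spacer(self, small_run):
        res = small_run
        for h in res.hosts.values():
            if h.parent_id is None:
                continue
            parent = res.hosts[h.parent_id]
            assert parent.spacers < h.spacers
            assert len(h.spacers) == len(parent.spacers) + 1

    def test_extinction_times_consistent_with_series(self, small_run):
        res = small_run
        s = res.series
        if res.t_virus_extinct is not None:
            i = np.searchsorted(s.times, res.t_virus_extinct)
            assert (s.V[i:] == 0).all()
            assert (s.V[:i] > 0).all()

    def test_sample_grid(self, small_run):
        s = small_run.series
        p = small_run.params
        assert s.times[0] == 0.0
        assert s.times[-1] == p.t_max
        assert np.allclose(np.diff(s.times), p.sample_dt)
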