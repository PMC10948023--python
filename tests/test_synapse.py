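import itertools
import math

import numpy as np
import pytest

from retstim.errors import ConfigError
from retstim.fixtures import tiny_release_params
from retstim.synapse import (ReleaseParams, SynapsePopulation,
                             clamp_release_metrics, release_rate_constants,
                             run_release)


class TestGeometry:
    def test_slot_bookkeeping(self):
        p = ReleaseParams()
        assert p.n_synapses == 80
        assert p.vesicles_per_synapse == 30
        pop = SynapsePopulation(p, seed=0)
        assert pop.occ.size == 2400
        assert pop.occ.shape == (1, 80, 6, 5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            ReleaseParams(advance="teleport")
        with pytest.raises(ConfigError):
            ReleaseParams(refill_tau_ms=0.0)


class TestRateConstants:
    def test_negligible_at_rest(self):
        kf, ks = release_rate_constants(0.1)
        assert kf < 1e-4 and ks < 1e-4

    def test_monotone_in_calcium(self):
        ca = np.logspace(-1, 2, 40)
        kf, ks = release_rate_constants(ca)
        assert np.all(np.diff(kf) >= 0)
        assert np.all(np.diff(ks) >= 0)

    def test_shared_sensor_fixed_ratio(self):
        p = ReleaseParams(slow_sensor="shared")
        ca = np.logspace(-1, 2.5, 25)
        kf, ks = release_rate_constants(ca, p)
        assert kf / ks == pytest.approx(40.0, rel=1e-12)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ConfigError):
            release_rate_constants(-1.0)


class TestDynamics:
    def test_resting_calcium_keeps_pool_full(self):
        pop = SynapsePopulation(ReleaseParams(), seed=4, n_reps=2)
        for _ in range(1000):  # 10 s at a coarse step
            pop.step(0.1, 10.0)
        assert np.all(pop.occupancy_fraction > 0.99)

    def test_saturating_hazard_releases_all_docked_in_one_step(self):
        p = ReleaseParams(a_fast_per_ms=500.0, kd_um=1.0, hill_n=2.0,
                          slow_sensor="shared")
        pop = SynapsePopulation(p, seed=5)
        nf, ns = pop.step(1000.0, 1.0)  # k·dt huge for both pools
        assert pop.occupancy_fraction[0] < 0.01
        assert nf[0] + ns[0] > 0.99 * 2400

    def test_empty_population_refills_within_five_tau(self):
        pop = SynapsePopulation(ReleaseParams(), seed=1, n_reps=2,
                                start_empty=True)
        for _ in range(4000):
            pop.step(0.0, 1.25)  # 5 s = 5 refill time constants
        assert np.all(pop.occupancy_fraction > 0.97)

    @pytest.mark.parametrize("mode", ["refill", "instant"])
    def test_vesicle_conservation_exact(self, mode):
        p = ReleaseParams(advance=mode)
        pop = SynapsePopulation(p, seed=3, n_reps=2)
        ca = np.abs(300 * np.sin(np.arange(4000) * 0.01))
        for c in ca:
            pop.step(c, 0.025)
        lhs = pop.released + pop.occ.sum(axis=(2, 3))
        rhs = p.vesicles_per_synapse + pop.refilled
        assert np.array_equal(lhs, rhs)

    def test_occupancy_counters_match_state(self):
        pop = SynapsePopulation(ReleaseParams(), seed=6, n_reps=2)
        for c in np.abs(200 * np.sin(np.arange(2000) * 0.02)):
            pop.step(c, 0.05)
        assert np.array_equal(pop._n_occ, pop.occ.sum(axis=(1, 2, 3)))
        assert np.array_equal(pop._n_fast, pop.occ[..., 0].sum(axis=(1, 2)))

    def test_bit_reproducible_for_fixed_seed(self):
        def run():
            rec = run_release(np.full(2000, 40.0), 0.025, ReleaseParams(),
                              n_reps=3, seed=7)
            return rec.counts, rec.occupancy
        c1, o1 = run()
        c2, o2 = run()
        assert np.array_equal(c1, c2) and np.array_equal(o1, o2)

    def test_event_log_matches_counts(self):
        rec = run_release(np.full(2000, 100.0), 0.025, ReleaseParams(),
                          n_reps=1, seed=8, record_events=True)
        assert len(rec.events) == rec.counts.sum()
        pools = {pool for _, _, pool in rec.events}
        assert pools <= {"fast", "slow"}

    def test_doubling_fast_amplitude_speeds_depletion(self, clamp_ca_trace):
        _, ca, _ = clamp_ca_trace
        ca = ca[1:40001]  # first second is enough
        times = []
        for scale in (1.0, 2.0):
            p = ReleaseParams()
            p = ReleaseParams(a_fast_per_ms=p.a_fast_per_ms * scale)
            rec = run_release(ca, 0.025, p, n_reps=8, seed=9)
            focc = rec.fast_occupancy.mean(axis=0)
            times.append(rec.t_ms[np.flatnonzero(focc < 0.10)[0]])
        assert times[1] < times[0]
        assert times[1] == pytest.approx(times[0] / 2, rel=0.5)


# ----------------------------------------------------------------------
# exact Markov-chain oracle for one release site (5 slots)
# ----------------------------------------------------------------------

def _site_chain_expected_releases(ca_steps, dt_ms, params):
    """Exact expected release count for one 5-slot site over the given
    calcium steps, by full enumeration of the 32-state chain (release,
    reserve refill, and row advance exactly as specified: docked slot
    releases at k_fast, upper rows at k_slow, vacant slots refill at
    1/τ, a refilling docked slot takes the nearest occupied upper row)."""
    rows = params.rows
    pr = 1.0 - math.exp(-dt_ms / params.refill_tau_ms)
    dist = {frozenset(range(rows)): 1.0}
    expected = 0.0
    for ca in ca_steps:
        kf, ks = release_rate_constants(float(ca), params)
        pf = 1.0 - math.exp(-kf * dt_ms)
        psl = 1.0 - math.exp(-ks * dt_ms)
        new = {}
        for state, p_state in dist.items():
            occ = sorted(state)
            vac = [i for i in range(rows) if i not in state]
            expected += p_state * sum(pf if i == 0 else psl for i in occ)
            for n_rel in range(len(occ) + 1):
                for rel in itertools.combinations(occ, n_rel):
                    p_rel = 1.0
                    for i in occ:
                        pi = pf if i == 0 else psl
                        p_rel *= pi if i in rel else (1.0 - pi)
                    occ1 = state - frozenset(rel)
                    for n_due in range(len(vac) + 1):
                        for due in itertools.combinations(vac, n_due):
                            p_due = (pr ** n_due
                                     * (1 - pr) ** (len(vac) - n_due))
                            occ2 = set(occ1)
                            due_set = set(due)
                            if 0 in due_set:
                                upper = sorted(i for i in occ2 if i >= 1)
                                if upper:
                                    occ2.discard(upper[0])
                                occ2.add(0)
                                due_set.discard(0)
                            occ2 |= due_set
                            key = frozenset(occ2)
                            prob = p_state * p_rel * p_due
                            new[key] = new.get(key, 0.0) + prob
        dist = new
    return expected


class TestMarkovOracle:
    def test_monte_carlo_matches_enumerated_expectation(self):
        """Mean release count over 1000 repetitions of a 3-step calcium
        trajectory agrees with the exact per-site chain within 3 SE."""
        params = tiny_release_params(refill_tau_ms=20.0)
        ca_steps = np.array([200.0, 400.0, 100.0])
        dt = 5.0
        n_sites = params.n_synapses * params.release_sites
        exact = n_sites * _site_chain_expected_releases(ca_steps, dt, params)
        rec = run_release(ca_steps, dt, params, n_reps=1000, seed=12)
        totals = rec.counts.sum(axis=1)
        se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - exact) < 3.0 * se


class TestClampMetrics:
    def test_transient_to_sustained_ratio_order_of_magnitude(
            self, clamp_ca_trace):
        _, ca, _ = clamp_ca_trace
        m = clamp_release_metrics(ReleaseParams(), n_seeds=10, seed=0,
                                  ca_trace=ca)
        assert 25.0 <= m["peak_to_sustained_ratio"] <= 100.0
        assert m["depletion_ms"] <= 20.0

    def test_sustained_rate_is_refill_capped(self, clamp_ca_trace):
        """Steady-state release cannot exceed the reserve feed of
        30 vesicles per synapse per refill time constant
        (0.3 vesicles/ms/terminal)."""
        _, ca, _ = clamp_ca_trace
        m = clamp_release_metrics(ReleaseParams(), n_seeds=6, seed=1,
                                  ca_trace=ca)
        assert m["sustained_per_ms_per_terminal"] <= 0.3
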