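"""Event semantics, invariants and oracle agreement of the traffic simulator."""

import numpy as np
import pytest
from dataclasses import replace

from ribojam.engine import (
    SimState,
    apply_event,
    draw_event,
    exact_stationary,
    simulate,
    total_event_rate,
)
from ribojam.io import SimConfig

from conftest import make_transcript


class TestTotalEventRate:
    def test_empty_lattice_is_initiation_only(self):
        t = make_transcript([2.0, 3.0, 1.0])
        assert total_event_rate(SimState(), t, 0.1) == pytest.approx(0.1)

    def test_sums_rates_of_occupied_sites(self):
        t = make_transcript([2.0, 3.0, 1.0], termination_rate=4.0)
        state = SimState(positions=[1], queued=[False])
        assert total_event_rate(state, t, 0.1) == pytest.approx(2.1)

    def test_blocked_ribosomes_keep_contributing(self):
        # two ribosomes, the upstream one blocked: both rates still count
        t = make_transcript([2.0, 3.0] + [1.0] * 10, termination_rate=5.0)
        state = SimState(positions=[1, 3], queued=[True, False])
        assert total_event_rate(state, t, 0.1) == pytest.approx(0.1 + 2.0 + 1.0)


class TestDrawEvent:
    def test_empty_lattice_always_initiates(self):
        t = make_transcript([1.0, 1.0])
        rng = np.random.default_rng(0)
        events = {draw_event(SimState(), t, 0.5, rng)[0] for _ in range(50)}
        assert events == {("init",)}

    def test_event_frequencies_match_rate_law(self):
        """Empirical frequencies over 1e5 draws match λ/μ and n_i λ_i/μ
        within 3 binomial SDs."""
        t = make_transcript([2.0, 3.0, 1.0, 1.0], termination_rate=4.0)
        lam = 1.0
        state = SimState(positions=[1, 3], queued=[False, False])
        mu = total_event_rate(state, t, lam)
        rng = np.random.default_rng(42)
        n = 100_000
        counts = {}
        for _ in range(n):
            ev, _dt = draw_event(state, t, lam, rng)
            counts[ev] = counts.get(ev, 0) + 1
        expected = {("init",): lam / mu, ("jump", 0): 2.0 / mu, ("jump", 1): 1.0 / mu}
        for ev, p in expected.items():
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[ev] - n * p) < 3 * sd, ev

    def test_waiting_time_is_exponential_with_rate_mu(self):
        t = make_transcript([2.0, 3.0])
        state = SimState(positions=[1], queued=[False])
        mu = total_event_rate(state, t, 1.0)
        rng = np.random.default_rng(3)
        dts = np.array([draw_event(state, t, 1.0, rng)[1] for _ in range(20_000)])
        assert dts.mean() == pytest.approx(1 / mu, rel=0.03)


class TestApplyEvent:
    L = 10

    def transcript(self, n=30):
        return make_transcript([1.0] * n, termination_rate=2.0)

    def test_free_jump_succeeds_and_clears_flag(self):
        state = SimState(positions=[5], queued=[True])
        state, term = apply_event(state, ("jump", 0), self.transcript(), self.L)
        assert state.positions == [6] and state.queued == [False] and not term

    def test_blocked_jump_fails_and_sets_queued(self):
        state = SimState(positions=[5, 15], queued=[False, False])
        state, _ = apply_event(state, ("jump", 0), self.transcript(), self.L)
        assert state.positions == [5, 15]
        assert state.queued == [True, False]

    def test_gap_one_jump_lands_adjacent(self):
        state = SimState(positions=[5, 16], queued=[False, False])
        state, _ = apply_event(state, ("jump", 0), self.transcript(), self.L)
        assert state.positions == [6, 16]
        state.check(self.L)

    def test_initiation_blocked_while_early_sites_covered(self):
        state = SimState(positions=[self.L], queued=[False])
        state, _ = apply_event(state, ("init",), self.transcript(), self.L)
        assert state.positions == [self.L]  # rejected
        state = SimState(positions=[self.L + 1], queued=[False])
        state, _ = apply_event(state, ("init",), self.transcript(), self.L)
        assert state.positions == [1, self.L + 1]
        state.check(self.L)

    def test_termination_removes_downstream_ribosome(self):
        t = self.transcript(n=30)
        state = SimState(positions=[10, 30], queued=[False, True])
        state, term = apply_event(state, ("jump", 1), t, self.L)
        assert term and state.positions == [10]

    def test_random_event_sequences_preserve_exclusion(self):
        """Exclusion invariant holds after every event of a long trace."""
        t = make_transcript([1.0] * 25, termination_rate=1.0)
        rng = np.random.default_rng(11)
        state = SimState()
        for _ in range(5000):
            ev, _ = draw_event(state, t, 2.0, rng)
            state, _ = apply_event(state, ev, t, 4)
            state.check(4)
            for j, q in enumerate(state.queued):
                assert not q or state.positions[j] <= 25


@pytest.mark.parametrize("L", [2, 4])
@pytest.mark.parametrize("lam", [0.1, 2.0])
def test_simulation_matches_exact_oracle(L, lam):
    """Density, current and queue probability agree with the exact CTMC
    solution on small heterogeneous lattices (3 SEs over replicates)."""
    rng = np.random.default_rng(L * 10 + int(lam * 10))
    rates = rng.uniform(0.5, 3.0, 10)
    t = make_transcript(rates, termination_rate=2.0)
    exact_density, exact_rate, exact_qp = exact_stationary(t, L, lam)

    reps = []
    for r in range(8):
        cfg = SimConfig(
            ribosome_size=L, initiation_rate=lam, seed=100 + r,
            warmup_terminations=100, monitored_terminations=15_000,
        )
        res = simulate(t, cfg, track_profiles=False)
        reps.append((res.mean_ribosomes, res.translation_rate, res.queue_probability))
    arr = np.array(reps)
    for i, exact in enumerate([exact_density.sum(), exact_rate, exact_qp]):
        mean, se = arr[:, i].mean(), arr[:, i].std(ddof=1) / np.sqrt(len(arr))
        assert abs(mean - exact) < 3 * max(se, 1e-4), (i, mean, exact, se)


def test_exact_stationary_guards():
    t = make_transcript([1.0])
    with pytest.raises(ValueError):
        exact_stationary(t, 2, 1.0)  # N=1 fails N > L/2
    with pytest.raises(ValueError):
        exact_stationary(make_transcript([1.0] * 12), 2, 1.0, max_states=10)


def test_saturated_initiation_reaches_max_packing():
    """With λ → ∞ and homogeneous rates the lattice front stays packed."""
    t = make_transcript([1.0] * 6, termination_rate=1.0)
    density, rate, _ = exact_stationary(t, 2, 1e4)
    # entry region saturates: one of the first two sites is always occupied
    assert density[0] + density[1] > 0.99
    assert rate < 1.0  # exclusion caps the current below the free rate
    # current is already saturated: pushing λ higher changes nothing
    _, rate_lo, _ = exact_stationary(t, 2, 1e2)
    assert rate == pytest.approx(rate_lo, rel=0.01)


class TestSimulate:
    def test_low_initiation_limit_is_empty_and_unqueued(self):
        t = make_transcript([1.0] * 20, termination_rate=1.0)
        cfg = SimConfig(initiation_rate=1e-3, warmup_terminations=20,
                        monitored_terminations=500, seed=5)
        res = simulate(t, cfg)
        assert res.mean_ribosomes < 0.05
        assert res.qfr == pytest.approx(0.0, abs=1e-3)
        assert res.queue_probability == pytest.approx(0.0, abs=1e-3)
        # initiation-limited: translation rate ≈ λ
        assert res.translation_rate == pytest.approx(1e-3, rel=0.1)

    def test_density_sum_equals_mean_ribosomes(self, fast_config):
        t = make_transcript(np.linspace(0.5, 2.0, 40), termination_rate=2.0)
        res = simulate(t, replace(fast_config, initiation_rate=0.5))
        assert res.density_profile.sum() == pytest.approx(res.mean_ribosomes, rel=1e-9)
        assert np.all(res.queued_profile <= res.density_profile + 1e-12)
        assert 0.0 <= res.qfr <= 1.0
        assert 0.0 <= res.queue_probability <= 1.0

    def test_queueing_increases_with_initiation_rate(self):
        t = make_transcript([1.0] * 40, termination_rate=1.0)
        qfr, qp = [], []
        for lam in [0.05, 0.3, 1.5]:
            vals = [
                simulate(t, SimConfig(initiation_rate=lam, seed=s,
                                      warmup_terminations=50,
                                      monitored_terminations=4000),
                         track_profiles=False)
                for s in (1, 2, 3)
            ]
            qfr.append(np.mean([v.qfr for v in vals]))
            qp.append(np.mean([v.queue_probability for v in vals]))
        assert qfr[0] < qfr[1] < qfr[2]
        assert qp[0] < qp[1] < qp[2]

    def test_backends_agree(self):
        t = make_transcript(np.linspace(0.8, 1.6, 15), termination_rate=2.0)
        results = {}
        for backend in ("numba", "python"):
            vals = [
                simulate(
                    t,
                    SimConfig(ribosome_size=4, initiation_rate=0.6, seed=s,
                              warmup_terminations=50, monitored_terminations=3000,
                              spacing=1),
                    backend=backend,
                )
                for s in (1, 2, 3, 4)
            ]
            results[backend] = np.array(
                [[v.mean_ribosomes, v.translation_rate, v.queue_probability,
                  v.qfr] for v in vals]
            )
        a, b = results["numba"], results["python"]
        se = np.sqrt(a.var(axis=0, ddof=1) / 4 + b.var(axis=0, ddof=1) / 4)
        assert np.all(np.abs(a.mean(0) - b.mean(0)) < 4 * np.maximum(se, 1e-3))

    def test_infeasible_parameters_raise(self):
        # near-zero termination rate: events burn on failed jumps upstream of
        # the stuck ribosome and terminations never accumulate
        t = make_transcript([1.0] * 20, termination_rate=1e-9)
        cfg = SimConfig(initiation_rate=1.0, warmup_terminations=100,
                        monitored_terminations=100, seed=1, max_events=50_000)
        with pytest.raises(RuntimeError, match="infeasible"):
            simulate(t, cfg, track_profiles=False)

    def test_same_seed_reproduces_bitwise(self, fast_config):
        t = make_transcript(np.linspace(0.5, 2.0, 30), termination_rate=2.0)
        cfg = replace(fast_config, initiation_rate=0.4)
        a = simulate(t, cfg)
        b = simulate(t, cfg)
        assert a.translation_rate == b.translation_rate
        assert np.array_equal(a.density_profile, b.density_profile)
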