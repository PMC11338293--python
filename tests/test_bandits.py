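import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matesearch import (
    NoiseSpec,
    SearchParams,
    SearchState,
    calibrate_noise,
    choose_mate,
    endstate_accuracy,
    mv_matrix,
    observe,
    reciprocity_weight,
    run_allocation,
    run_search,
    ts_update,
    ucb_score,
)


class TestNoiseCalibration:
    def test_zero_noise(self, small_mv):
        assert calibrate_noise(small_mv, 0.0).sd == 0.0

    def test_half_noise_equals_pooled_sd(self, small_mv):
        spec = calibrate_noise(small_mv, 0.5)
        v = np.var(small_mv.pooled_values())
        assert spec.sd == pytest.approx(np.sqrt(v), rel=1e-12)

    def test_three_quarters(self, small_mv):
        spec = calibrate_noise(small_mv, 0.75)
        v = np.var(small_mv.pooled_values())
        assert spec.sd**2 == pytest.approx(3 * v, rel=1e-12)

    def test_variance_fraction_identity(self, small_mv):
        for p in (0.1, 0.25, 0.5, 0.9):
            spec = calibrate_noise(small_mv, p)
            v = np.var(small_mv.pooled_values())
            assert spec.sd**2 / (spec.sd**2 + v) == pytest.approx(p, abs=1e-9)

    def test_full_noise_rejected(self, small_mv):
        with pytest.raises(ValueError, match="noise fraction"):
            calibrate_noise(small_mv, 1.0)


class TestObserve:
    def test_zero_sd_exact(self):
        rng = np.random.default_rng(0)
        assert observe(7.3, NoiseSpec(0.0, 0.0), rng) == 7.3

    def test_unbiased(self):
        rng = np.random.default_rng(1)
        draws = observe(np.full(100_000, 7.0), NoiseSpec(0.5, 1.0), rng)
        assert np.mean(draws) == pytest.approx(7.0, abs=0.02)

    def test_seeded_reproducibility(self):
        a = observe(np.ones(10), NoiseSpec(0.5, 1.0), np.random.default_rng(2))
        b = observe(np.ones(10), NoiseSpec(0.5, 1.0), np.random.default_rng(2))
        assert np.array_equal(a, b)


class TestUcbScore:
    def test_zero_c_is_greedy(self):
        assert ucb_score(8.0, 12, 10, 0.0) == pytest.approx(8.0, abs=1e-12)

    def test_hand_computed(self):
        expected = 8.0 + 1.5 * np.sqrt(np.log(12) / 10)
        assert ucb_score(8.0, 12, 10, 1.5) == pytest.approx(expected, abs=1e-9)

    def test_unvisited_is_infinite(self):
        scores = ucb_score(np.array([8.0, 9.0]), 5, np.array([0, 3]), 1.5)
        assert scores[0] == np.inf and np.isfinite(scores[1])

    def test_invalid_t_rejected(self):
        with pytest.raises(ValueError, match="t must be"):
            ucb_score(8.0, 0, 1, 1.5)


class TestTsUpdate:
    def test_hand_computed(self):
        mu, sigma = ts_update(10.0, 0.25, 6.0, 1.0)
        assert mu == pytest.approx(166 / 17, abs=1e-9)
        assert sigma == pytest.approx(np.sqrt(1 / 17), abs=1e-9)

    def test_mean_fixed_point(self):
        mu, sigma = ts_update(5.0, 0.5, 5.0, 1.0)
        assert mu == pytest.approx(5.0, abs=1e-12)
        assert sigma < 0.5

    def test_posterior_consistency(self):
        rng = np.random.default_rng(3)
        mu, sigma = 10.0, 1.0
        for x in rng.normal(4.0, 1.0, 1000):
            mu, sigma = ts_update(mu, sigma, x, 1.0)
        assert mu == pytest.approx(4.0, abs=0.1)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            ts_update(5.0, 0.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            ts_update(5.0, 1.0, 5.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu=st.floats(0, 10),
        sigma=st.floats(0.01, 5),
        x=st.floats(-5, 15),
        obs_sd=st.floats(0.01, 5),
    )
    def test_posterior_sd_shrinks_and_mean_between(self, mu, sigma, x, obs_sd):
        mu2, sigma2 = ts_update(mu, sigma, x, obs_sd)
        assert sigma2 < sigma
        assert min(mu, x) - 1e-9 <= mu2 <= max(mu, x) + 1e-9


class TestReciprocityWeight:
    def test_neutral_start(self):
        assert reciprocity_weight(1, 1) == 1.0

    def test_printed_ratio(self):
        assert reciprocity_weight(5, 3) == pytest.approx(5 / 3, abs=1e-12)

    def test_never_reciprocated_limit(self):
        # agent pursued n times, mate never reciprocates: weight 1/(n+1) -> 0
        weights = [reciprocity_weight(1, n + 1) for n in range(1, 200)]
        assert weights == sorted(weights, reverse=True)
        assert weights[-1] == pytest.approx(1 / 200, abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reciprocity_weight(1, 0)


def one_agent_state(estimates, pulls=None, received=None, mu=None, sigma=None, t=0):
    m = len(estimates)
    params = SearchParams(model="eg")
    state = SearchState.initial(1, m, params.resolved())
    state.estimate[0] = estimates
    if pulls is not None:
        state.pulls[0] = pulls
    if received is not None:
        state.received = np.array([received], dtype=np.int64)
    if mu is not None:
        state.mu[0] = mu
    if sigma is not None:
        state.sigma[0] = sigma
    state.t = t
    return state


class TestChooseMate:
    def test_pure_greedy(self):
        state = one_agent_state([3.0, 9.0, 5.0], t=3)
        params = SearchParams(model="eg", epsilon=0.0).resolved()
        rng = np.random.default_rng(0)
        assert choose_mate("eg", state, params, rng)[0] == 1

    def test_full_exploration_uniform(self):
        state = one_agent_state([3.0, 9.0, 5.0], t=3)
        params = SearchParams(model="eg", epsilon=1.0).resolved()
        rng = np.random.default_rng(1)
        counts = np.zeros(3)
        n = 10_000
        for _ in range(n):
            counts[choose_mate("eg", state, params, rng)[0]] += 1
        expected = n / 3
        sd = np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - expected) < 3 * sd)

    def test_reciprocity_flips_greedy_choice(self):
        # estimates (9, 8) but weights (0.5, 1.5): 4.5 < 12 -> mate 2
        state = one_agent_state([9.0, 8.0], pulls=[1, 1], received=[0, 2], t=2)
        params = SearchParams(model="rweg", epsilon=0.0).resolved()
        rng = np.random.default_rng(2)
        assert choose_mate("rweg", state, params, rng)[0] == 1

    def test_ucb_prefers_unvisited(self):
        state = one_agent_state([9.0, 9.5], pulls=[0, 5], t=5)
        params = SearchParams(model="ucb").resolved()
        rng = np.random.default_rng(3)
        assert choose_mate("ucb", state, params, rng)[0] == 0

    def test_ties_broken_randomly(self):
        state = one_agent_state([5.0, 5.0], t=2)
        params = SearchParams(model="eg", epsilon=0.0).resolved()
        rng = np.random.default_rng(4)
        picks = {int(choose_mate("eg", state, params, rng)[0]) for _ in range(100)}
        assert picks == {0, 1}

    def test_unknown_model_rejected(self):
        state = one_agent_state([5.0])
        with pytest.raises(ValueError, match="unknown"):
            choose_mate("qlearn", state, SearchParams(model="eg").resolved(),
                        np.random.default_rng(0))


class TestRunSearch:
    def test_nonlearning_zero_noise_matches_full_information(self, small_pop, small_mv):
        reference = run_allocation(small_mv, seed=7)
        params = SearchParams(model="nonlearning", budget=900, block_size=300)
        traj, _ = run_search(small_pop, small_mv, params, NoiseSpec(0.0, 0.0), seed=8)
        assert endstate_accuracy(traj.final_pairing, reference).accuracy == 100.0

    @pytest.mark.parametrize("model", ["eg", "ucb", "ts", "rweg", "rwucb", "rwts"])
    def test_two_agent_market_pairs_from_first_block(self, model):
        from conftest import make_agent_table

        v = np.full(16, 5.0)
        pop = make_agent_table([v], [v], [v], [v])
        mv = mv_matrix(pop)
        noise = calibrate_noise(mv, 0.0)
        noise = NoiseSpec(0.5, 0.5)  # nonzero noise; only one option anyway
        params = SearchParams(model=model, budget=40, block_size=10)
        traj, _ = run_search(pop, mv, params, noise, seed=9)
        for _, pairing in traj:
            assert pairing.partners[0] == 1 and pairing.partners[1] == 0

    @pytest.mark.parametrize("model", ["eg", "ucb", "ts", "rweg", "rwucb", "rwts"])
    def test_pull_count_conservation(self, small_pop, small_mv, model):
        params = SearchParams(model=model, budget=200, block_size=100)
        noise = calibrate_noise(small_mv, 0.5)
        _, states = run_search(small_pop, small_mv, params, noise, seed=10)
        for state in states.values():
            assert np.all(state.pulls.sum(axis=1) == state.t)
        # every pursuit sent by one sex is received by the other
        assert np.array_equal(states["female"].received, states["male"].pulls.T)
        assert np.array_equal(states["male"].received, states["female"].pulls.T)

    def test_thompson_posterior_converges_single_mate(self):
        from conftest import make_agent_table

        v = np.full(16, 5.0)
        t = np.full(16, 7.0)
        pop = make_agent_table([v], [v], [v], [t])  # male trait differs
        mv = mv_matrix(pop)
        true_mv = mv.f_to_m[0, 0]
        noise = NoiseSpec(0.5, 1.0)
        params = SearchParams(model="ts", prior_sd=2.0, budget=400, block_size=400)
        _, states = run_search(pop, mv, params, noise, seed=11)
        n = states["female"].pulls[0, 0]
        assert abs(states["female"].mu[0, 0] - true_mv) < 3 * 1.0 / np.sqrt(n)
        assert states["female"].sigma[0, 0] < 2.0

    def test_sigma_never_increases(self, small_pop, small_mv):
        params = SearchParams(model="rwts", budget=100, block_size=100)
        noise = calibrate_noise(small_mv, 0.5)
        _, states = run_search(small_pop, small_mv, params, noise, seed=12)
        prior_sd = SearchParams(model="rwts").resolved().prior_sd
        for state in states.values():
            assert np.all(state.sigma <= prior_sd + 1e-12)
            assert np.all(state.sigma > 0)

    def test_deterministic_given_seed(self, small_pop, small_mv):
        params = SearchParams(model="rwts", budget=200, block_size=100)
        noise = calibrate_noise(small_mv, 0.5)
        a, _ = run_search(small_pop, small_mv, params, noise, seed=13)
        b, _ = run_search(small_pop, small_mv, params, noise, seed=13)
        assert [p.partners for _, p in a] == [p.partners for _, p in b]

    def test_trajectory_export(self, small_pop, small_mv, tmp_path):
        params = SearchParams(model="rweg", budget=200, block_size=100)
        noise = calibrate_noise(small_mv, 0.5)
        traj, _ = run_search(small_pop, small_mv, params, noise, seed=15)
        path = tmp_path / "trajectory.csv"
        traj.to_csv(path)
        frame = traj.to_frame()
        assert len(frame) == 2 * len(small_pop)
        assert set(frame["block"]) == {100, 200}

    def test_indivisible_budget_rejected(self, small_pop, small_mv):
        params = SearchParams(model="eg", budget=250, block_size=100)
        with pytest.raises(ValueError, match="divisible"):
            run_search(small_pop, small_mv, params, NoiseSpec(0.0, 0.0), seed=0)

    def test_nonlearning_degrades_with_noise(self, small_pop, small_mv):
        """Endstate accuracy of the non-learning model is non-increasing in p."""
        reference = run_allocation(small_mv, seed=14)
        mean_accs = []
        for p in (0.0, 0.25, 0.5, 0.75):
            noise = calibrate_noise(small_mv, p)
            accs = []
            for rep in range(3):
                params = SearchParams(model="nonlearning", budget=100, block_size=100)
                traj, _ = run_search(small_pop, small_mv, params, noise, seed=20 + rep)
                accs.append(endstate_accuracy(traj.final_pairing, reference).accuracy)
            mean_accs.append(np.mean(accs))
        assert all(a >= b for a, b in zip(mean_accs, mean_accs[1:]))
        assert mean_accs[0] == 100.0
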