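import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carlsim.agents import (
    AgentState,
    BiasSpec,
    carl_update,
    choose_actions,
    classify_feedback,
    resolve_bias,
    softmax_policy,
)


def make_state(q=(0.0, 0.0), ap=0.15, am=0.05, beta=4.0):
    return AgentState(q=np.array(q, dtype=float), alpha_plus=ap,
                      alpha_minus=am, beta=beta)


class TestSoftmaxPolicy:
    def test_zero_beta_is_random(self):
        assert softmax_policy(np.array([0.9, -0.7]), 0.0, 0) == 0.5

    def test_equal_q_is_tie(self):
        assert softmax_policy(np.array([0.3, 0.3]), 17.0, 1) == 0.5

    def test_hand_evaluated_logistic(self):
        # beta=4, gap 0.4 -> 1/(1+e^-1.6), oracle = direct arithmetic
        p = softmax_policy(np.array([0.4, 0.0]), 4.0, 0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.6)))

    def test_probabilities_sum_to_one(self):
        q = np.array([0.25, -0.6])
        assert softmax_policy(q, 3.0, 0) + softmax_policy(q, 3.0, 1) == pytest.approx(1.0)

    def test_extreme_beta_no_overflow(self):
        p = softmax_policy(np.array([1.0, -1.0]), 1e6, 0)
        assert p == pytest.approx(1.0)
        assert softmax_policy(np.array([1.0, -1.0]), 1e6, 1) == pytest.approx(0.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            softmax_policy(np.zeros(2), -1.0, 0)


class TestChooseActions:
    def test_greedy_limit_all_pick_best(self, rng):
        states = [make_state(q=(0.5, -0.5), beta=1e4) for _ in range(10)]
        for _ in range(20):
            assert (choose_actions(states, rng) == 0).all()

    def test_zero_beta_choice_frequency(self, rng):
        states = [make_state(q=(0.9, -0.9), beta=0.0)]
        draws = np.array([choose_actions(states, rng)[0] for _ in range(20_000)])
        freq = draws.mean()
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_choices_independent_across_agents(self, rng):
        # n=3 identical states: pairwise chi-square independence
        from scipy.stats import chi2_contingency

        states = [make_state(q=(0.2, 0.0), beta=2.0) for _ in range(3)]
        draws = np.array([choose_actions(states, rng) for _ in range(20_000)])
        for i, j in ((0, 1), (0, 2), (1, 2)):
            table = np.histogram2d(draws[:, i], draws[:, j], bins=2)[0]
            _, p, _, _ = chi2_contingency(table)
            assert p > 1e-3


class TestClassifyFeedback:
    def test_solo_rewarded(self):
        part = classify_feedback(0, np.array([0]), np.array([1]))
        assert part.r_c == frozenset({0})
        assert part.p_c == part.r_u == part.p_u == frozenset()
        assert part.chosen_arm == 0

    def test_two_agents_same_arm_mixed_outcomes(self):
        part = classify_feedback(0, np.array([0, 0]), np.array([1, -1]))
        assert part.r_c == frozenset({0})
        assert part.p_c == frozenset({1})

    def test_other_arm_reward_is_disconfirmatory(self):
        part = classify_feedback(0, np.array([0, 1]), np.array([1, 1]))
        assert part.r_c == frozenset({0})
        assert part.r_u == frozenset({1})
        assert part.p_c == part.p_u == frozenset()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            classify_feedback(0, np.array([0, 1]), np.array([1]))

    @given(
        n=st.integers(1, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_invariant(self, n, seed):
        rng = np.random.default_rng(seed)
        actions = rng.integers(0, 2, size=n)
        payoffs = rng.choice([-1, 1], size=n)
        focal = int(rng.integers(0, n))
        part = classify_feedback(focal, actions, payoffs)
        sets = (part.r_c, part.p_c, part.r_u, part.p_u)
        assert sum(len(s) for s in sets) == n
        union = frozenset().union(*sets)
        assert union == frozenset(range(n))
        # focal agent sits in one of the chosen-arm sets
        assert focal in part.r_c | part.p_c


class TestCarlUpdate:
    def test_solo_reward_moves_chosen_q_by_alpha_plus(self):
        state = make_state(ap=0.15, am=0.05)
        part = classify_feedback(0, np.array([0]), np.array([1]))
        q = carl_update(state, part, n=1)
        assert q[0] == pytest.approx(0.15)
        assert q[1] == 0.0

    def test_two_rewards_same_arm(self):
        state = make_state(ap=0.15, am=0.05)
        part = classify_feedback(0, np.array([0, 0]), np.array([1, 1]))
        q = carl_update(state, part, n=2)
        assert q[0] == pytest.approx(0.5 * (0.15 + 0.15))

    def test_fixed_point_at_bound(self):
        state = make_state(q=(1.0, 0.0))
        part = classify_feedback(0, np.array([0, 0]), np.array([1, 1]))
        q = carl_update(state, part, n=2)
        assert q[0] == pytest.approx(1.0)

    def test_partition_size_must_match_n(self):
        state = make_state()
        part = classify_feedback(0, np.array([0, 0]), np.array([1, 1]))
        with pytest.raises(ValueError):
            carl_update(state, part, n=3)

    @given(
        n=st.integers(1, 6),
        steps=st.integers(1, 60),
        seed=st.integers(0, 10_000),
        ap=st.floats(0.01, 1.0),
        am=st.floats(0.01, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_q_values_bounded_under_random_streams(self, n, steps, seed, ap, am):
        rng = np.random.default_rng(seed)
        state = make_state(q=rng.uniform(-1, 1, 2), ap=ap, am=am)
        for _ in range(steps):
            actions = rng.integers(0, 2, size=n)
            payoffs = rng.choice([-1, 1], size=n)
            part = classify_feedback(0, actions, payoffs)
            state = make_state(q=carl_update(state, part, n), ap=ap, am=am)
        assert (np.abs(state.q) <= 1.0 + 1e-12).all()

    @given(n=st.integers(1, 6), seed=st.integers(0, 10_000),
           alpha=st.floats(0.01, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_unbiased_equals_single_rate_collective_rw(self, n, seed, alpha):
        # oracle: per arm, sum each chooser's plain prediction error, rate alpha/n
        rng = np.random.default_rng(seed)
        q0 = rng.uniform(-1, 1, 2)
        actions = rng.integers(0, 2, size=n)
        payoffs = rng.choice([-1, 1], size=n)
        state = make_state(q=q0.copy(), ap=alpha, am=alpha)
        part = classify_feedback(0, actions, payoffs)
        got = carl_update(state, part, n)
        expected = q0.copy()
        for arm in (0, 1):
            pe_sum = sum(payoffs[j] - q0[arm] for j in range(n) if actions[j] == arm)
            expected[arm] += alpha * pe_sum / n
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_single_agent_reduces_to_two_rate_rw_learner(self, rng):
        # standalone asymmetric learner: only factual feedback, alpha+ for
        # positive PEs, alpha- for negative ones
        ap, am = 0.3, 0.1
        q_solo = np.zeros(2)
        state = make_state(q=(0, 0), ap=ap, am=am)
        for _ in range(200):
            arm = int(rng.integers(0, 2))
            payoff = int(rng.choice([-1, 1]))
            pe = payoff - q_solo[arm]
            q_solo[arm] += (ap if pe > 0 else am) * pe
            part = classify_feedback(0, np.array([arm]), np.array([payoff]))
            state = make_state(q=carl_update(state, part, n=1), ap=ap, am=am)
        np.testing.assert_allclose(state.q, q_solo, atol=1e-12)


class TestResolveBias:
    @pytest.mark.parametrize(
        "b, expected",
        [
            (3.0, (0.15, 0.05)),
            (1.0, (0.1, 0.1)),
            (9.0, (0.18, 0.02)),
            (17.0 / 3.0, (0.17, 0.03)),
        ],
    )
    def test_fixed_sum_reproduces_printed_pairs(self, b, expected):
        ap, am = resolve_bias(BiasSpec(scheme="fixed_sum", b=b))
        assert ap == pytest.approx(expected[0])
        assert am == pytest.approx(expected[1])
        assert ap + am == pytest.approx(0.2)

    def test_fixed_minus(self):
        assert resolve_bias(BiasSpec(scheme="fixed_minus", b=5.0)) == (0.5, 0.1)

    def test_explicit_passthrough(self):
        spec = BiasSpec(scheme="explicit", alpha_plus=0.18, alpha_minus=0.02)
        assert resolve_bias(spec) == (0.18, 0.02)

    def test_derived_strength_equals_ratio(self):
        for scheme in ("fixed_sum", "fixed_minus"):
            spec = BiasSpec(scheme=scheme, b=2.5)
            ap, am = spec.resolve()
            assert spec.strength == pytest.approx(ap / am) == pytest.approx(2.5)

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            resolve_bias(BiasSpec(scheme="fixed_sum", b=0.0))
        with pytest.raises(ValueError):
            resolve_bias(BiasSpec(scheme="fixed_minus", b=-1.0))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            resolve_bias(BiasSpec(scheme="fixed_plus", b=2.0))


class TestAgentState:
    def test_q_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_state(q=(1.5, 0.0))

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            make_state(ap=0.0)
        with pytest.raises(ValueError):
            make_state(am=1.5)
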