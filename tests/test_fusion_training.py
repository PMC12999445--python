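"""VDN fusion algebra, action selection, TD machinery and the training loop."""

import numpy as np
import pytest

from dermagents.environment import PatchGrid
from dermagents.errors import ConfigurationError, ContractError, DomainError
from dermagents.fusion import (
    class_probabilities,
    fuse_class_values,
    make_fusion,
    select_joint_action,
    team_values,
)
from dermagents.training import (
    ReplayBuffer,
    TrainConfig,
    TrainingSample,
    Transition,
    predict,
    td_target,
    train,
    vdn_loss,
)

VDN = make_fusion("vdn-sum", 2)
AVG = make_fusion("fixed-average", 2)


class TestFusionAlgebra:
    def test_vdn_sum_example(self):
        q1 = np.array([0.0, 0.0, 0.0, 0.0, 0.3, -0.1])
        q2 = np.array([0.5, 0.2])
        assert np.allclose(fuse_class_values(q1, q2, VDN), [0.8, 0.1])

    def test_vdn_additivity_on_random_pairs(self, rng):
        q1 = rng.normal(size=(1000, 6))
        q2 = rng.normal(size=(1000, 2))
        fused = fuse_class_values(q1, q2, VDN)
        assert np.array_equal(fused, q1[:, 4:] + q2)

    def test_zero_vectors_fuse_to_zero(self, rng):
        q1 = np.zeros(6)
        q2 = np.zeros(2)
        for kind in ("vdn-sum", "fixed-average", "attention", "concat-head"):
            rule = make_fusion(kind, 2, np.random.default_rng(0))
            summaries = (np.ones((1, 4)), np.ones((1, 3))) if kind == "attention" else None
            if kind == "attention":
                rule = make_fusion(kind, 2, np.random.default_rng(0), d_spatial=4, d_temporal=3)
            fused = fuse_class_values(q1, q2, rule, summaries=summaries)
            assert np.allclose(fused, 0.0)

    def test_fixed_average_is_half_vdn_sum(self, rng):
        q1 = rng.normal(size=(50, 6))
        q2 = rng.normal(size=(50, 2))
        assert np.allclose(
            fuse_class_values(q1, q2, AVG), 0.5 * fuse_class_values(q1, q2, VDN)
        )

    def test_attention_weights_are_convex(self, rng):
        rule = make_fusion("attention", 2, rng, d_spatial=4, d_temporal=3)
        alphas = rule.alphas((rng.normal(size=(10, 4)), rng.normal(size=(10, 3))))
        assert np.all(alphas >= 0)
        assert np.allclose(alphas.sum(axis=1), 1.0)

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ContractError):
            fuse_class_values(np.zeros(5), np.zeros(2), VDN)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ConfigurationError):
            make_fusion("majority-vote", 2)

    def test_navigation_values_come_from_agent_one_alone(self, rng):
        q1 = rng.normal(size=6)
        q2 = rng.normal(size=2)
        tv = team_values(q1, q2, VDN)
        assert np.array_equal(tv[:4], q1[:4])


class TestActionSelection:
    def test_greedy_argmax(self):
        rng = np.random.default_rng(0)
        q1 = np.array([0.0, 0.0, 0.0, 0.0, 0.9, 0.0])
        q2 = np.array([0.0, 0.1])
        # fused class values (0.9, 0.1): classify class 0 -> action index 4
        assert select_joint_action(q1, q2, VDN, 0.0, rng) == 4

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert select_joint_action(np.zeros(6), np.zeros(2), VDN, 0.0, rng) == 0

    def test_uniform_exploration_frequencies(self):
        rng = np.random.default_rng(7)
        n = 10_000
        counts = np.zeros(6)
        for _ in range(n):
            counts[select_joint_action(np.zeros(6), np.zeros(2), VDN, 1.0, rng)] += 1
        p = 1 / 6
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(counts / n - p) <= 3 * se)

    def test_allowed_mask_restricts_choice(self):
        rng = np.random.default_rng(0)
        allowed = np.array([False, False, False, False, True, True])
        q1 = np.array([9.0, 9.0, 9.0, 9.0, 0.1, 0.5])
        a = select_joint_action(q1, np.zeros(2), VDN, 0.0, rng, allowed=allowed)
        assert a == 5

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(DomainError):
            select_joint_action(np.zeros(6), np.zeros(2), VDN, 1.5, np.random.default_rng(0))


class TestClassProbabilities:
    def test_uniform_under_equal_values(self):
        assert np.allclose(class_probabilities(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_closed_form_softmax(self):
        p = class_probabilities(np.array([np.log(2.0), 0.0]), tau=1.0)
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_shift_invariance(self, rng):
        v = rng.normal(size=4)
        assert np.allclose(class_probabilities(v), class_probabilities(v + 10.0))

    @pytest.mark.parametrize("tau", [0.1, 1.0, 10.0])
    def test_normalization(self, rng, tau):
        for _ in range(100):
            v = rng.normal(size=5) * 10
            p = class_probabilities(v, tau=tau)
            assert np.all(p > 0)
            assert abs(p.sum() - 1.0) < 1e-12

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(DomainError):
            class_probabilities(np.zeros(2), tau=0.0)


class _StubSpatial:
    """Deterministic stand-in exposing the SpatialQNet interface."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)
        self.last_features = np.zeros((1, 4))

    def q_values(self, patches, pos):
        n = np.atleast_3d(patches).shape[0] if patches.ndim == 4 else 1
        return np.tile(self.values, (n, 1))


class _StubTemporal:
    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)
        self.n_classes = len(values)

    def encode(self, token_lists):
        return np.zeros((len(token_lists), 4))

    def head_values(self, h):
        return np.tile(self.values, (h.shape[0], 1))


def _dummy_sample():
    return TrainingSample(np.zeros((224, 224, 3)), 1, (1, 2))


class TestTDTarget:
    def test_terminal_reduces_to_reward(self):
        tr = Transition(_dummy_sample(), (2, 2), 4, 1.0, None, True)
        y = td_target(tr, (None, None), VDN, gamma=0.99)
        assert y == 1.0

    def test_nonterminal_bootstrap(self):
        # next team values: nav all 0, classes (1.0, 0.0) -> max 1.0
        spatial = _StubSpatial([0.0, 0.0, 0.0, 0.0, 0.5, 0.0])
        temporal = _StubTemporal([0.5, 0.0])
        tr = Transition(_dummy_sample(), (2, 2), 0, -0.01, (1, 2), False)
        y = td_target(tr, (spatial, temporal), VDN, gamma=0.99)
        assert y == pytest.approx(-0.01 + 0.99 * 1.0)

    def test_zero_gamma_is_myopic(self):
        spatial = _StubSpatial(np.ones(6))
        temporal = _StubTemporal(np.ones(2))
        tr = Transition(_dummy_sample(), (2, 2), 0, -0.01, (1, 2), False)
        assert td_target(tr, (spatial, temporal), VDN, gamma=0.0) == -0.01

    def test_forced_next_state_maxes_over_classes_only(self):
        spatial = _StubSpatial([5.0, 5.0, 5.0, 5.0, 0.2, 0.0])
        temporal = _StubTemporal([0.0, 0.0])
        tr = Transition(_dummy_sample(), (2, 2), 0, -0.01, (1, 2), False, next_forced=True)
        y = td_target(tr, (spatial, temporal), VDN, gamma=1.0)
        assert y == pytest.approx(-0.01 + 0.2)


class TestReplayBuffer:
    def test_capacity_bound_and_fifo(self):
        buf = ReplayBuffer(5, np.random.default_rng(0))
        for i in range(8):
            tr = Transition(_dummy_sample(), (0, 0), 4, float(i), None, True)
            buf.add(tr)
        assert len(buf) == 5

    def test_uniform_sampling(self):
        buf = ReplayBuffer(100, np.random.default_rng(3))
        for i in range(100):
            buf.add(Transition(_dummy_sample(), (0, 0), 4, float(i), None, True))
        counts = np.zeros(100)
        draws = 10_000
        for _ in range(draws // 10):
            for tr in buf.sample(10):
                counts[int(tr.reward)] += 1
        p = 1 / 100
        se = np.sqrt(p * (1 - p) / draws)
        assert np.all(np.abs(counts / draws - p) <= 3 * se)

    def test_batch_larger_than_buffer_rejected(self):
        buf = ReplayBuffer(10, np.random.default_rng(0))
        buf.add(Transition(_dummy_sample(), (0, 0), 4, 0.0, None, True))
        with pytest.raises(ContractError):
            buf.sample(2)


class TestBellmanFixedPoint:
    def test_tabular_vdn_converges_to_analytic_q(self):
        """Two-state, two-action deterministic MDP: TD updates with the
        package's target rule drive the team values to Q* computed by value
        iteration."""
        # transitions[s][a] = (next_state, reward)
        transitions = {0: {0: (0, 0.0), 1: (1, 0.0)}, 1: {0: (0, 1.0), 1: (1, 0.0)}}
        gamma = 0.9

        # independent oracle: value iteration
        q_star = np.zeros((2, 2))
        for _ in range(500):
            q_new = np.zeros_like(q_star)
            for s in (0, 1):
                for a in (0, 1):
                    s2, r = transitions[s][a]
                    q_new[s, a] = r + gamma * q_star[s2].max()
            q_star = q_new

        # two tabular "agents" whose team value is the sum (VDN)
        q1 = np.zeros((2, 2))
        q2 = np.zeros((2, 2))
        lr = 0.25
        target1, target2 = q1.copy(), q2.copy()
        for sweep in range(1000):
            for s in (0, 1):
                for a in (0, 1):
                    s2, r = transitions[s][a]
                    y = r + gamma * (target1[s2] + target2[s2]).max()
                    residual = (q1[s, a] + q2[s, a]) - y
                    q1[s, a] -= lr * residual
                    q2[s, a] -= lr * residual
            if sweep % 10 == 0:
                target1, target2 = q1.copy(), q2.copy()
        assert np.max(np.abs((q1 + q2) - q_star)) < 1e-2


class TestVDNLoss:
    def _team(self, seed=0):
        from dermagents.agents import SpatialQNet, TemporalQNet

        rng = np.random.default_rng(seed)
        spatial = SpatialQNet(2, pos_dim=10, rng=rng)
        temporal = TemporalQNet(11, 2, rng)
        return spatial, temporal

    def _batch(self, samples, n=6):
        rng = np.random.default_rng(5)
        grid = PatchGrid()
        batch = []
        for i in range(n):
            s = samples[i % len(samples)]
            terminal = i % 2 == 0
            batch.append(
                Transition(
                    sample=s,
                    pos=(int(rng.integers(6)), int(rng.integers(6))),
                    action=int(rng.integers(6)) if not terminal else 4 + s.label,
                    reward=1.0 if terminal else -0.01,
                    next_pos=None if terminal else (2, 3),
                    terminal=terminal,
                )
            )
        return batch

    def test_single_transition_squared_residual(self, small_samples):
        spatial, temporal = self._team()
        s = small_samples[0]
        tr = Transition(s, (2, 2), 4 + s.label, 1.0, None, True)
        q1 = spatial.q_values(s.pixels[32:96, 64:128][None], np.zeros((1, 10)))
        loss = vdn_loss([tr], (spatial, temporal), (spatial, temporal), VDN)
        # recompute by hand
        grid = PatchGrid()
        from dermagents.environment import positional_embedding

        q1 = spatial.q_values(
            grid.crop(s.pixels, (2, 2))[None], positional_embedding((2, 2), grid)[None]
        )
        q2 = temporal.q_values([s.tokens])
        qtot = q1[0, 4 + s.label] + q2[0, s.label]
        assert loss == pytest.approx((qtot - 1.0) ** 2)

    def test_zero_loss_at_fixed_point(self, small_samples):
        """If the team value of the taken action already equals y, loss is 0."""
        spatial = _StubSpatial([0.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        temporal = _StubTemporal([0.0, 0.0])
        s = small_samples[0]
        tr = Transition(s, (2, 2), 4, 1.0, None, True)
        loss = vdn_loss([tr], (spatial, temporal), (spatial, temporal), VDN)
        assert loss == pytest.approx(0.0)

    def test_permutation_invariance(self, small_samples):
        spatial, temporal = self._team()
        batch = self._batch(small_samples)
        loss_a = vdn_loss(batch, (spatial, temporal), (spatial, temporal), VDN)
        loss_b = vdn_loss(batch[::-1], (spatial, temporal), (spatial, temporal), VDN)
        assert loss_a == pytest.approx(loss_b)

    def test_empty_batch_rejected(self):
        spatial, temporal = self._team()
        with pytest.raises(ContractError):
            vdn_loss([], (spatial, temporal), (spatial, temporal), VDN)

    def test_loss_nonnegative(self, small_samples):
        spatial, temporal = self._team()
        batch = self._batch(small_samples)
        assert vdn_loss(batch, (spatial, temporal), (spatial, temporal), VDN) >= 0.0


class TestTrainLoop:
    def test_single_class_rejected(self, small_samples):
        ones = [s for s in small_samples if s.label == 1]
        with pytest.raises(ConfigurationError):
            train(ones, TrainConfig(episodes=2), vocab_size=11)

    def test_seeded_determinism(self, small_samples):
        cfg = TrainConfig(episodes=12, warmup_transitions=16, batch_size=8, seed=4)
        r1 = train(small_samples, cfg, vocab_size=11)
        r2 = train(small_samples, cfg, vocab_size=11)
        assert r1.log.equals(r2.log)

    def test_noop_configuration_leaves_weights_unchanged(self, small_samples):
        cfg = TrainConfig(
            episodes=6,
            warmup_transitions=8,
            batch_size=4,
            learning_rate=0.0,
            epsilon_start=0.0,
            epsilon_end=0.0,
            seed=2,
        )
        result = train(small_samples, cfg, vocab_size=11)
        fresh = train(
            small_samples,
            TrainConfig(episodes=0, seed=2),
            vocab_size=11,
        )
        for (na, pa, _), (nb, pb, _) in zip(
            result.spatial.named_parameters(), fresh.spatial.named_parameters()
        ):
            assert na == nb
            assert np.array_equal(pa, pb)

    def test_log_columns_and_length(self, small_samples):
        cfg = TrainConfig(episodes=5, warmup_transitions=8, batch_size=4, seed=0)
        result = train(small_samples, cfg, vocab_size=11)
        assert list(result.log.columns) == ["episode", "return", "loss", "epsilon", "steps"]
        assert len(result.log) == 5

    @pytest.mark.parametrize("kind", ["fixed-average", "attention", "concat-head"])
    def test_fusion_variants_train(self, small_samples, kind):
        cfg = TrainConfig(episodes=4, warmup_transitions=8, batch_size=4, seed=0)
        result = train(small_samples, cfg, vocab_size=11, fusion_kind=kind)
        assert len(result.log) == 4
        assert np.isfinite(result.log["return"]).all()


class TestPredict:
    def test_rigged_dominant_class_terminates_immediately(self, small_samples):
        spatial = _StubSpatial([0.0, 0.0, 0.0, 0.0, 0.0, 5.0])
        temporal = _StubTemporal([0.0, 0.0])
        p = predict(small_samples[0], spatial, temporal, VDN)
        assert p.predicted_class == 1
        assert len(p.trajectory) == 1

    def test_horizon_forces_class_argmax(self, small_samples):
        # navigation always dominates -> rollout must stop at t_max and pick
        # the larger fused class value
        spatial = _StubSpatial([1.0, 0.9, 0.9, 0.9, 0.1, 0.2])
        temporal = _StubTemporal([0.05, 0.0])
        p = predict(small_samples[0], spatial, temporal, VDN, t_max=6)
        assert len(p.actions) == 7  # 6 navigation moves + forced classification
        assert p.predicted_class == 1  # 0.2 + 0.0 > 0.1 + 0.05

    def test_repeated_calls_identical(self, small_samples):
        spatial = _StubSpatial([0.0, 0.1, 0.0, 0.0, 0.3, 0.2])
        temporal = _StubTemporal([0.1, 0.0])
        p1 = predict(small_samples[0], spatial, temporal, VDN)
        p2 = predict(small_samples[0], spatial, temporal, VDN)
        assert p1.predicted_class == p2.predicted_class
        assert p1.trajectory == p2.trajectory
        assert np.array_equal(p1.probabilities, p2.probabilities)
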