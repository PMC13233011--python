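"""Q-learning machinery: targets, exploration, replay, training loops."""

import numpy as np
import pytest

import dosewise as dw
from dosewise.dqn import (
    Adam,
    Policy,
    QNetwork,
    QNetworkSpec,
    ReplayBuffer,
    TrainConfig,
    Transition,
    replay_step,
)


class ToyMDP:
    """Two states, two actions: action 1 toggles; being in state 1 pays 1."""

    n_actions = 2

    def __init__(self, episode_len: int = 30):
        self.episode_len = episode_len

    def reset(self, seed=None):
        self.s, self.t = 0, 0
        return np.array([float(self.s)])

    def step(self, a):
        if a == 1:
            self.s ^= 1
        self.t += 1
        r = 1.0 if self.s == 1 else 0.0
        return np.array([float(self.s)]), r, self.t >= self.episode_len, {}


def toy_factory(seed=0, reward_cfg=None):
    return ToyMDP()


class OneStepBandit:
    """Single-step episodes; action means differ; gamma=0 must find the best."""

    n_actions = 3
    MEANS = (0.2, 0.9, 0.5)

    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)

    def reset(self, seed=None):
        return np.array([1.0])

    def step(self, a):
        r = self.MEANS[a] + self.rng.normal(0, 0.05)
        return np.array([1.0]), r, True, {}


class TestUpdateRules:
    @pytest.mark.parametrize("r,gamma,max_q,done,expected", [
        (5.0, 0.0, 7.0, False, 5.0),
        (1.0, 0.9, 10.0, False, 10.0),
        (3.0, 0.99, 100.0, True, 3.0),
    ])
    def test_bellman_target(self, r, gamma, max_q, done, expected):
        assert dw.bellman_target(r, gamma, max_q, done) == expected

    def test_td_update_examples(self):
        assert dw.td_update(0.0, 10.0, 0.5) == 5.0
        assert dw.td_update(2.0, 10.0, 1.0) == 10.0

    def test_td_update_geometric_convergence(self):
        q, target, alpha = 0.0, 10.0, 0.3
        for k in range(1, 20):
            q = dw.td_update(q, target, alpha)
            assert abs(q - target) == pytest.approx((1 - alpha) ** k * 10.0)


class TestSelectAction:
    def test_pure_exploitation(self):
        rng = np.random.default_rng(0)
        assert dw.select_action(np.array([1.0, 3.0, 2.0]), 0.0, rng) == 1

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert dw.select_action(np.array([5.0, 5.0]), 0.0, rng) == 0

    def test_uniform_at_epsilon_one(self):
        rng = np.random.default_rng(42)
        q = np.zeros(4)
        counts = np.zeros(4)
        n = 100_000
        for _ in range(n):
            counts[dw.select_action(q, 1.0, rng)] += 1
        freqs = counts / n
        assert ((freqs >= 0.24) & (freqs <= 0.26)).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dw.select_action(np.array([]), 0.5, np.random.default_rng(0))


class TestEpsilonSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig(episodes=10)
        assert dw.epsilon_at(0, cfg) == 1.0
        assert dw.epsilon_at(9, cfg) == pytest.approx(0.1)
        cfg11 = TrainConfig(episodes=11)
        assert dw.epsilon_at(5, cfg11) == pytest.approx(0.55)

    def test_out_of_range_episode_rejected(self):
        with pytest.raises(ValueError):
            dw.epsilon_at(10, TrainConfig(episodes=10))


class TestReplay:
    def test_buffer_fifo_eviction(self):
        buf = ReplayBuffer(capacity=3)
        for i in range(5):
            buf.push(Transition(np.array([float(i)]), 0, 0.0, np.array([0.0]), False))
        assert len(buf) == 3
        stored = [t.state[0] for t in buf._store]
        assert stored == [2.0, 3.0, 4.0]  # oldest evicted first

    def test_underfilled_buffer_skips(self):
        rng = np.random.default_rng(0)
        qnet = QNetwork(QNetworkSpec(2, 2, (8,)), rng)
        cfg = TrainConfig()
        adam = Adam(qnet.get_params(), cfg.learning_rate)
        buf = ReplayBuffer(10)
        assert replay_step(buf, qnet, cfg, rng, adam) is None

    def test_sampling_reproducible_under_seed(self):
        buf = ReplayBuffer(100)
        for i in range(50):
            buf.push(Transition(np.array([float(i)]), 0, 0.0, np.array([0.0]), False))
        a = [t.state[0] for t in buf.sample(8, np.random.default_rng(7))]
        b = [t.state[0] for t in buf.sample(8, np.random.default_rng(7))]
        assert a == b

    def test_converges_on_degenerate_buffer(self):
        rng = np.random.default_rng(0)
        qnet = QNetwork(QNetworkSpec(4, 2, (64, 64, 32)), rng)
        cfg = TrainConfig()
        adam = Adam(qnet.get_params(), cfg.learning_rate)
        buf = ReplayBuffer(64)
        tr = Transition(np.array([0.1, 0.2, 0.3, 0.4]), 1, 5.0,
                        np.zeros(4), True)
        for _ in range(cfg.batch_size):
            buf.push(tr)
        err = None
        for _ in range(500):
            err = replay_step(buf, qnet, cfg, rng, adam)
        assert err < 0.01

    def test_zero_tau_leaves_target_untouched(self):
        rng = np.random.default_rng(0)
        qnet = QNetwork(QNetworkSpec(2, 2, (8,)), rng)
        target = qnet.clone()
        before = [p.copy() for p in target.get_params()]
        cfg = TrainConfig(soft_target_tau=0.0)
        adam = Adam(qnet.get_params(), cfg.learning_rate)
        buf = ReplayBuffer(64)
        for _ in range(cfg.batch_size):
            buf.push(Transition(np.array([0.5, 0.5]), 0, 1.0, np.zeros(2), True))
        replay_step(buf, qnet, cfg, rng, adam, target_net=target)
        for b, a in zip(before, target.get_params()):
            assert np.array_equal(b, a)


class TestTraining:
    def test_toy_mdp_matches_value_iteration(self):
        cfg = TrainConfig(episodes=10, seed=3, gamma=0.9, hidden=(16, 16, 8),
                          learning_rate=0.01)
        policy, _ = dw.train(toy_factory, cfg)

        # independent oracle: value iteration on the known MDP
        trans = {0: {0: 0, 1: 1}, 1: {0: 1, 1: 0}}
        reward = lambda s2: 1.0 if s2 == 1 else 0.0  # noqa: E731
        V = {0: 0.0, 1: 0.0}
        for _ in range(500):
            V = {s: max(reward(trans[s][a]) + 0.9 * V[trans[s][a]] for a in (0, 1))
                 for s in (0, 1)}
        oracle = {s: max((0, 1), key=lambda a: reward(trans[s][a]) + 0.9 * V[trans[s][a]])
                  for s in (0, 1)}
        assert policy(np.array([0.0])) == oracle[0]
        assert policy(np.array([1.0])) == oracle[1]

    def test_myopic_bandit_recovers_best_mean(self):
        cfg = TrainConfig(episodes=10, seed=2, gamma=0.0, hidden=(8, 8, 4),
                          learning_rate=0.01)
        policy, _ = dw.train(lambda seed, reward_cfg=None: OneStepBandit(seed), cfg)
        assert policy(np.array([1.0])) == int(np.argmax(OneStepBandit.MEANS))

    def test_same_seed_same_learning_curve(self):
        cfg = TrainConfig(episodes=4, seed=6, hidden=(8, 8, 4))
        _, curve_a = dw.train(toy_factory, cfg)
        _, curve_b = dw.train(toy_factory, cfg)
        assert curve_a.equals(curve_b)

    def test_checkpoints_written(self, tmp_path):
        cfg = TrainConfig(episodes=2, seed=1, hidden=(8, 8, 4),
                          checkpoint_dir=str(tmp_path))
        dw.train(toy_factory, cfg)
        assert sorted(p.name for p in tmp_path.iterdir()) == [
            "policy_ep000.json", "policy_ep001.json"]


class TestPolicy:
    def test_save_load_round_trip_greedy_actions(self, tmp_path, trained_policy):
        path = tmp_path / "policy.json"
        trained_policy.save(path)
        loaded = Policy.load(path)
        rng = np.random.default_rng(0)
        states = rng.uniform(0, 1, (1000, trained_policy.input_dim))
        for s in states:
            assert loaded(s) == trained_policy(s)

    def test_dimension_mismatch_names_expected(self, trained_policy):
        with pytest.raises(ValueError, match=str(trained_policy.input_dim)):
            trained_policy(np.zeros(7))


class TestEvaluate:
    def test_deterministic_under_seeds(self, short_env_factory, trained_policy):
        a = dw.evaluate(trained_policy, short_env_factory, n_episodes=1, seeds=[1, 2])
        b = dw.evaluate(trained_policy, short_env_factory, n_episodes=1, seeds=[1, 2])
        assert a[0] == b[0]
        assert a[1].equals(b[1])

    def test_zero_dose_policy_sees_hyperglycemia(self, short_env_factory):
        pooled, _ = dw.evaluate(lambda obs: 0, short_env_factory,
                                n_episodes=1, seeds=[1, 2])
        assert pooled.tar > 0  # unopposed meals push glucose above range
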