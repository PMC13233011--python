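"""Deep Q-network agent for discrete insulin dosing.

Value-based control: a small fully connected network approximates
Q(s, a), the expected discounted return of dose ``a`` in state ``s``,
trained toward the Bellman target ``r + gamma * max_a' Q(s', a')`` from
uniformly sampled replay-buffer batches, with epsilon-greedy exploration
decaying linearly from 1.0 to 0.1 over episodes. Defaults follow the
reference training regime: three hidden ReLU layers, Adam at learning
rate 0.001, replay capacity 5000, 10 episodes of ~1000-2000 transitions.

The network, optimizer and training loop are implemented directly on
numpy: the model is tiny (hundreds of KFLOPs per step) and this keeps the
agent dependency-light and bit-reproducible under a single seed.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import Metrics, evaluate_series
from .rewards import RewardConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QNetworkSpec:
    input_dim: int
    output_dim: int
    hidden: tuple[int, ...] = (64, 64, 32)

    def __post_init__(self) -> None:
        if self.output_dim < 2:
            raise ValueError("need at least 2 actions")
        if len(self.hidden) < 1:
            raise ValueError("need at least one hidden layer")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    gamma: float = 0.99
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    buffer_capacity: int = 5000
    batch_size: int = 32
    episodes: int = 10
    updates_per_step: int = 8  # replay ratio; compensates for the small episode budget
    soft_target_tau: float = 0.0   # 0 disables the target network
    hidden: tuple[int, ...] = (64, 64, 32)
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.epsilon_end > self.epsilon_start:
            raise ValueError("epsilon_end must be <= epsilon_start")


@dataclass(frozen=True)
class Transition:
    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    done: bool


class ReplayBuffer:
    """FIFO transition store with strict oldest-first eviction."""

    def __init__(self, capacity: int = 5000) -> None:
        self.capacity = capacity
        self._store: deque[Transition] = deque(maxlen=capacity)

    def push(self, tr: Transition) -> None:
        self._store.append(tr)

    def __len__(self) -> int:
        return len(self._store)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(0, len(self._store), batch_size)
        return [self._store[i] for i in idx]


# ---------------------------------------------------------------------------
# Network and optimizer
# ---------------------------------------------------------------------------

class QNetwork:
    """Fully connected ReLU network with a linear Q-value head."""

    def __init__(self, spec: QNetworkSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden, spec.output_dim]
        self.weights = [rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
                        for i in range(len(dims) - 1)]
        self.biases = [np.zeros(d) for d in dims[1:]]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [np.atleast_2d(x)]
        h = acts[0]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h, acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        q, _ = self.forward(x)
        return q[0] if np.ndim(x) == 1 else q

    def gradients(self, acts: list[np.ndarray], dq: np.ndarray):
        """Backprop of dLoss/dQ through the cached activations."""
        grads_w, grads_b = [None] * len(self.weights), [None] * len(self.biases)
        delta = dq
        for i in reversed(range(len(self.weights))):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        return grads_w, grads_b

    def get_params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.array(p) for p in params[:n]]
        self.biases = [np.array(p) for p in params[n:]]

    def clone(self) -> "QNetwork":
        other = QNetwork(self.spec, np.random.default_rng(0))
        other.set_params([p.copy() for p in self.get_params()])
        return other


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Core update rules
# ---------------------------------------------------------------------------

def bellman_target(r: float, gamma: float, max_q_next: float, done: bool) -> float:
    """One-step Bellman backup: r, plus the discounted best next Q if not terminal."""
    return r if done else r + gamma * max_q_next


def td_update(q: float, target: float, alpha: float) -> float:
    """Tabular temporal-difference step toward the target."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return q + alpha * (target - q)


def select_action(q_values: np.ndarray, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy: random with probability epsilon, else argmax (ties -> lowest index)."""
    q_values = np.asarray(q_values)
    if q_values.size == 0:
        raise ValueError("empty q_values")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(0, q_values.size))
    return int(np.argmax(q_values))


def epsilon_at(episode: int, cfg: TrainConfig) -> float:
    """Linear epsilon decay from start (episode 0) to end (last episode)."""
    if not 0 <= episode < cfg.episodes:
        raise ValueError(f"episode {episode} outside [0, {cfg.episodes})")
    if cfg.episodes == 1:
        return cfg.epsilon_end
    frac = episode / (cfg.episodes - 1)
    return cfg.epsilon_start + frac * (cfg.epsilon_end - cfg.epsilon_start)


def replay_step(buffer: ReplayBuffer, qnet: QNetwork, cfg: TrainConfig,
                rng: np.random.Generator, adam: Adam,
                target_net: QNetwork | None = None) -> float | None:
    """One uniform-batch regression step toward the Bellman targets.

    Returns the batch mean squared TD error, or None if the buffer is not
    yet filled to one batch.
    """
    if len(buffer) < cfg.batch_size:
        logger.debug("replay skipped: buffer %d < batch %d", len(buffer), cfg.batch_size)
        return None
    batch = buffer.sample(cfg.batch_size, rng)
    states = np.stack([t.state for t in batch])
    next_states = np.stack([t.next_state for t in batch])
    actions = np.array([t.action for t in batch])
    rewards = np.array([t.reward for t in batch])
    dones = np.array([t.done for t in batch])

    bootstrap = target_net if target_net is not None else qnet
    max_q_next = bootstrap.predict(next_states).max(axis=1)
    targets = np.where(dones, rewards, rewards + cfg.gamma * max_q_next)

    q_all, acts = qnet.forward(states)
    rows = np.arange(len(batch))
    td_err = q_all[rows, actions] - targets
    dq = np.zeros_like(q_all)
    dq[rows, actions] = 2.0 * td_err / len(batch)
    grads_w, grads_b = qnet.gradients(acts, dq)
    adam.step(qnet.get_params(), grads_w + grads_b)

    if target_net is not None and cfg.soft_target_tau > 0:
        tau = cfg.soft_target_tau
        for tp, p in zip(target_net.get_params(), qnet.get_params()):
            tp *= (1 - tau)
            tp += tau * p
    return float(np.mean(td_err ** 2))


# ---------------------------------------------------------------------------
# Policy
# ---------------------------------------------------------------------------

@dataclass
class Policy:
    """A trained Q-network plus its action-dose mapping; callable on states."""

    qnet: QNetwork
    action_doses: tuple[float, ...]

    @property
    def input_dim(self) -> int:
        return self.qnet.spec.input_dim

    def q_values(self, state_vec: np.ndarray) -> np.ndarray:
        v = np.asarray(state_vec, dtype=float)
        if v.shape[-1] != self.input_dim:
            raise ValueError(
                f"state vector of length {v.shape[-1]} does not match the "
                f"policy's expected input_dim {self.input_dim}")
        return self.qnet.predict(v)

    def greedy_action(self, state_vec: np.ndarray) -> int:
        return int(np.argmax(self.q_values(state_vec)))

    __call__ = greedy_action

    def save(self, path: str | Path) -> None:
        payload = {
            "input_dim": self.qnet.spec.input_dim,
            "output_dim": self.qnet.spec.output_dim,
            "hidden": list(self.qnet.spec.hidden),
            "action_doses": list(self.action_doses),
            "weights": [w.tolist() for w in self.qnet.weights],
            "biases": [b.tolist() for b in self.qnet.biases],
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path) -> "Policy":
        payload = json.loads(Path(path).read_text())
        spec = QNetworkSpec(payload["input_dim"], payload["output_dim"],
                            tuple(payload["hidden"]))
        qnet = QNetwork(spec, np.random.default_rng(0))
        qnet.weights = [np.array(w) for w in payload["weights"]]
        qnet.biases = [np.array(b) for b in payload["biases"]]
        return Policy(qnet=qnet, action_doses=tuple(payload["action_doses"]))


def random_policy(n_actions: int, seed: int = 0) -> Callable[[np.ndarray], int]:
    """Uniform-random dosing policy (the comparison floor for training)."""
    rng = np.random.default_rng(seed)

    def act(_state: np.ndarray) -> int:
        return int(rng.integers(0, n_actions))

    return act


# ---------------------------------------------------------------------------
# Training and evaluation loops
# ---------------------------------------------------------------------------

def train(env_factory: Callable[..., object], cfg: TrainConfig | None = None,
          reward_cfg: RewardConfig | None = None) -> tuple[Policy, pd.DataFrame]:
    """Train a DQN policy; returns the policy and its learning curve.

    ``env_factory(seed, reward_cfg=None)`` must return a fresh environment
    following the reset/step contract with ``n_actions`` and
    ``config.action_doses`` (falling back to action indices when absent).
    The learning curve holds one row per episode: cumulative reward, TIR
    of the visited glucose trace, mean TD loss, and epsilon.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)

    probe = env_factory(seed=cfg.seed, reward_cfg=reward_cfg)
    obs = probe.reset()
    input_dim = int(np.asarray(obs).size)
    n_actions = int(probe.n_actions)
    doses = tuple(getattr(getattr(probe, "config", None), "action_doses",
                          tuple(range(n_actions))))

    qnet = QNetwork(QNetworkSpec(input_dim, n_actions, cfg.hidden), rng)
    target_net = qnet.clone() if cfg.soft_target_tau > 0 else None
    adam = Adam(qnet.get_params(), cfg.learning_rate)
    buffer = ReplayBuffer(cfg.buffer_capacity)

    curve_rows = []
    for ep in range(cfg.episodes):
        eps = epsilon_at(ep, cfg)
        env = env_factory(seed=cfg.seed * 1000 + ep + 1, reward_cfg=reward_cfg)
        obs = np.asarray(env.reset(), dtype=float)
        ep_reward, losses, glucose = 0.0, [], []
        done = False
        while not done:
            action = select_action(qnet.predict(obs), eps, rng)
            next_obs, reward, done, info = env.step(action)
            next_obs = np.asarray(next_obs, dtype=float)
            buffer.push(Transition(obs, action, float(reward), next_obs, bool(done)))
            for _ in range(cfg.updates_per_step):
                loss = replay_step(buffer, qnet, cfg, rng, adam, target_net)
                if loss is None:
                    break
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"divergent TD loss {loss} at episode {ep}; "
                        "reduce the learning rate or reward scale")
                losses.append(loss)
            ep_reward += float(reward)
            if "glucose" in info:
                glucose.append(info["glucose"])
            obs = next_obs
        row = {
            "episode": ep,
            "cumulative_reward": ep_reward,
            "mean_td_loss": float(np.mean(losses)) if losses else float("nan"),
            "epsilon": eps,
            "steps": env.t if hasattr(env, "t") else len(glucose),
        }
        if glucose:
            g = np.asarray(glucose)
            row["tir"] = 100.0 * np.mean((g >= 70) & (g <= 180))
        curve_rows.append(row)
        logger.info("episode %d: reward %.1f eps %.2f", ep, ep_reward, eps)
        if cfg.checkpoint_dir is not None:
            ckpt = Path(cfg.checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            Policy(qnet, doses).save(ckpt / f"policy_ep{ep:03d}.json")

    return Policy(qnet, doses), pd.DataFrame(curve_rows)


def rollout(env, policy: Callable[[np.ndarray], int]) -> pd.DataFrame:
    """Greedy rollout of one episode; one row per step."""
    obs = np.asarray(env.reset(), dtype=float)
    rows = []
    done = False
    prev_g = None
    while not done:
        action = policy(obs)
        obs_next, reward, done, info = env.step(action)
        rows.append({
            "glucose": info.get("glucose", np.nan),
            "prev_glucose": prev_g if prev_g is not None else info.get("glucose", np.nan),
            "iob": info.get("iob", np.nan),
            "reward": reward,
            "action": action,
        })
        prev_g = info.get("glucose", np.nan)
        obs = np.asarray(obs_next, dtype=float)
    return pd.DataFrame(rows)


def evaluate(policy: Callable[[np.ndarray], int], env_factory: Callable[..., object],
             n_episodes: int = 5, seeds: Sequence[int] = (1, 2, 3, 4, 5),
             reward_cfg: RewardConfig | None = None,
             low: float = 70.0, high: float = 180.0) -> tuple[Metrics, pd.DataFrame]:
    """Greedy evaluation over paired seeds.

    MAE/RMSE are one-step-ahead errors of the trajectory (each reading
    against the previous one), a smoothness measure of the glucose the
    policy produces; TIR/TBR/TAR and mean per-episode cumulative reward
    summarize control quality. Returns pooled metrics plus a per-seed
    breakdown.
    """
    per_seed = []
    all_g, all_prev, all_rewards, returns = [], [], [], []
    for seed in seeds:
        g_seed, ret_seed = [], []
        for ep in range(n_episodes):
            env = env_factory(seed=int(seed) * 10_000 + ep, reward_cfg=reward_cfg)
            tr = rollout(env, policy)
            g_seed.append(tr["glucose"].to_numpy())
            ret_seed.append(float(tr["reward"].sum()))
            all_rewards.extend(tr["reward"].tolist())
        g = np.concatenate(g_seed)
        all_g.append(g)
        all_prev.append(g)  # paired below via shift
        m = evaluate_series(g[:-1], g[1:], rewards=None, low=low, high=high)
        per_seed.append({
            "seed": seed, "mae": m.mae, "rmse": m.rmse, "tir": m.tir,
            "tbr": m.tbr, "tar": m.tar,
            "mean_cumulative_reward": float(np.mean(ret_seed)),
        })
        returns.extend(ret_seed)
    g = np.concatenate(all_g)
    pooled = evaluate_series(g[:-1], g[1:], rewards=None, low=low, high=high)
    pooled = Metrics(mae=pooled.mae, rmse=pooled.rmse, tir=pooled.tir,
                     tbr=pooled.tbr, tar=pooled.tar,
                     mean_reward=float(np.mean(returns)), n=pooled.n)
    return pooled, pd.DataFrame(per_seed)
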