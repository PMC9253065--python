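"""Goal-directed maze navigation with a small DQN-style agent.

The agent observes the one-hot current cell and outputs one value per action
through the same three-layer architecture as the supervised learner (ReLU
hidden, linear action outputs trained as Q-values). The action space is
fixed: the 8 compass moves plus "stay", mirroring the self-inclusive
8-neighborhood of the random walk. Choosing a wall (or leaving the grid)
terminates the episode with a penalty and a new random start — invalid
actions are thereby punished rather than masked. Episodes also end on
reaching a reward (food tray) cell or on the per-episode step limit.

After training, softmax over the action values of a cell gives a next-action
probability row, which is scattered onto the grid cells those actions reach
to form a full state-transition row; concatenating rows yields a policy
transition matrix usable by :func:`cogmap.sr.successor_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environments import GridEnvironment, NeighborhoodSpec, environment_transition_matrix
from .sr import SuccessorRepresentation, TransitionModel, successor_matrix
from .supervised import AdamState, PredictorNetwork, init_network, softmax

__all__ = [
    "ACTION_OFFSETS",
    "AgentConfig",
    "RewardHistory",
    "train_agent",
    "action_distribution",
    "extend_action_probs_to_states",
    "policy_tp_matrix",
    "maze_ground_truth_sr",
    "reward_trend_slope",
]

# stay first, then the 8 compass moves in row-major order
ACTION_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 0), (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)
N_ACTIONS = len(ACTION_OFFSETS)


@dataclass
class AgentConfig:
    """Hyperparameters of the navigation agent.

    ``total_steps`` counts environment steps; the first ``warmup_steps`` use
    uniformly random actions and fill the replay buffer before any update.
    The default policy is purely greedy (no epsilon schedule): exploration
    comes from random episode starts, the warmup phase, and the penalty
    feedback on wall choices. ``epsilon > 0`` enables epsilon-greedy.
    ``q_discount`` is the Q-learning discount (distinct from the SR gamma).
    """

    total_steps: int = 10_000
    warmup_steps: int = 300
    learning_rate: float = 0.001
    max_episode_steps: int = 30
    policy: str = "greedy"
    epsilon: float = 0.0
    wall_penalty: float = -1.0
    q_discount: float = 0.9
    hidden_fraction: float = 1.0
    replay_capacity: int = 2000
    batch_size: int = 32
    target_update_interval: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.total_steps <= self.warmup_steps or self.warmup_steps < 0:
            raise ValueError("need total_steps > warmup_steps >= 0")
        if self.max_episode_steps < 1:
            raise ValueError("max_episode_steps must be >= 1")
        if self.policy not in ("greedy", "epsilon-greedy"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass
class RewardHistory:
    """Accumulated reward and length of each completed episode."""

    rewards: list[float] = field(default_factory=list)
    lengths: list[int] = field(default_factory=list)

    @property
    def n_episodes(self) -> int:
        return len(self.rewards)


def _step(env: GridEnvironment, s: int, action: int) -> tuple[int, float, bool]:
    """Apply an action; returns (next state, reward, episode done)."""
    r, c = env.to_rc(s)
    dr, dc = ACTION_OFFSETS[action]
    nr, nc = r + dr, c + dc
    if not env.in_bounds(nr, nc) or not env.allowed[nr, nc]:
        return s, float("nan"), True  # wall choice; caller applies the penalty
    ns = env.to_flat(nr, nc)
    rew = float(env.rewards[nr, nc])
    return ns, rew, rew != 0.0


def train_agent(
    env: GridEnvironment, config: AgentConfig = AgentConfig()
) -> tuple[PredictorNetwork, RewardHistory]:
    """Q-learning with experience replay on the rewarded grid environment.

    Episodes start at uniformly random allowed non-reward cells and end on a
    reward cell, on a wall choice (with ``wall_penalty``), or after
    ``max_episode_steps``. Fully deterministic given ``config.seed``.
    """
    if env.reward_states.size == 0:
        raise ValueError("environment has no reward cells; nothing to navigate to")
    rng = np.random.default_rng(config.seed)
    net = init_network(
        env.n_cells, hidden_fraction=config.hidden_fraction,
        seed=None if config.seed is None else config.seed + 1,
        n_outputs=N_ACTIONS,
    )
    target = PredictorNetwork(*(p.copy() for p in net.parameters()))
    opt = AdamState(net.parameters(), config.learning_rate)
    starts = np.setdiff1d(env.allowed_states, env.reward_states)
    replay: list[tuple[int, int, float, int, bool]] = []
    hist = RewardHistory()

    eps = config.epsilon if config.policy == "epsilon-greedy" else 0.0
    s = int(rng.choice(starts))
    ep_reward, ep_len = 0.0, 0
    for step in range(config.total_steps):
        if step < config.warmup_steps or rng.random() < eps:
            a = int(rng.integers(N_ACTIONS))
        else:
            a = int(np.argmax(net.logits(np.array([s]))[0]))
        ns, rew, done = _step(env, s, a)
        if np.isnan(rew):
            rew = config.wall_penalty
        ep_reward += rew
        ep_len += 1
        if ep_len >= config.max_episode_steps:
            done = True
        replay.append((s, a, rew, ns, done))
        if len(replay) > config.replay_capacity:
            replay.pop(0)

        if step >= config.warmup_steps:
            idx = rng.integers(len(replay), size=min(config.batch_size, len(replay)))
            bs, ba, br, bn, bd = map(np.array, zip(*(replay[i] for i in idx)))
            q_next = target.logits(bn).max(axis=1)
            y = br + config.q_discount * q_next * ~bd
            h = net.hidden(bs)
            q = h @ net.W2 + net.b2
            dq = np.zeros_like(q)
            rows = np.arange(len(bs))
            dq[rows, ba] = 2.0 * (q[rows, ba] - y) / len(bs)
            gW2 = h.T @ dq
            gb2 = dq.sum(axis=0)
            dh = (dq @ net.W2.T) * (h > 0)
            gW1 = np.zeros_like(net.W1)
            np.add.at(gW1, bs, dh)
            opt.step(net.parameters(), [gW1, dh.sum(axis=0), gW2, gb2])
            if (step + 1) % config.target_update_interval == 0:
                target = PredictorNetwork(*(p.copy() for p in net.parameters()))

        if done:
            hist.rewards.append(ep_reward)
            hist.lengths.append(ep_len)
            s = int(rng.choice(starts))
            ep_reward, ep_len = 0.0, 0
        else:
            s = ns
    return net, hist


def action_distribution(net: PredictorNetwork, s: int, env: GridEnvironment) -> np.ndarray:
    """Softmax (temperature 1) over the agent's action values at cell ``s``."""
    if not env.is_allowed(s):
        raise ValueError(f"state {s} is a wall cell")
    return softmax(net.logits(np.array([s])))[0]


def extend_action_probs_to_states(
    probs: np.ndarray,
    s: int,
    env: GridEnvironment,
    mask_walls: bool = True,
) -> np.ndarray:
    """Scatter a 9-action probability row onto the full state space.

    Each action's probability lands on the grid cell the action reaches from
    ``s`` ("stay" lands on ``s`` itself). With ``mask_walls`` (default) the
    mass of actions leading into walls or off the grid is dropped and the row
    renormalized, keeping it stochastic; otherwise wall cells inside the grid
    keep that mass (off-grid mass is dropped) and the row may sum to < 1.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_ACTIONS,):
        raise ValueError(f"expected {N_ACTIONS} action probabilities")
    row = np.zeros(env.n_cells)
    r, c = env.to_rc(s)
    for a, (dr, dc) in enumerate(ACTION_OFFSETS):
        nr, nc = r + dr, c + dc
        if not env.in_bounds(nr, nc):
            continue
        if mask_walls and not env.allowed[nr, nc]:
            continue
        row[env.to_flat(nr, nc)] += probs[a]
    if mask_walls:
        total = row.sum()
        if total > 0:
            row /= total
    return row


def policy_tp_matrix(
    net: PredictorNetwork, env: GridEnvironment, mask_walls: bool = True
) -> TransitionModel:
    """Transition matrix induced by the agent's softmax action preferences."""
    n = env.n_cells
    T = np.zeros((n, n))
    for s in env.allowed_states:
        T[s] = extend_action_probs_to_states(
            action_distribution(net, int(s), env), int(s), env, mask_walls
        )
    return TransitionModel(T)


def maze_ground_truth_sr(
    env: GridEnvironment,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    gamma: float = 1.0,
    horizon: float = 10,
) -> SuccessorRepresentation:
    """SR of the uniform random walk restricted to the maze's allowed cells."""
    return successor_matrix(environment_transition_matrix(env, spec), gamma, horizon)


def reward_trend_slope(history: RewardHistory, n_episodes: int = 600) -> float:
    """Least-squares slope of episode reward over the first ``n_episodes``."""
    y = np.asarray(history.rewards[:n_episodes], dtype=float)
    if y.size < 2:
        raise ValueError("need at least two completed episodes for a trend")
    x = np.arange(y.size)
    return float(np.polyfit(x, y, 1)[0])
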