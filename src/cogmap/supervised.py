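"""Supervised successor prediction with a three-layer softmax network.

The network maps a one-hot state to a probability distribution over all
states (one hidden ReLU layer, softmax output) and is trained with
cross-entropy and Adam on sampled (state, successor) pairs. Because the
targets are stochastic labels drawn from the environment's transition row,
the cross-entropy optimum for input ``s`` is exactly row ``s`` of the true
transition matrix: concatenating converged predictions recovers T, and the
top-1 accuracy plateaus near the Bayes ceiling ``mean_s 1/k_s`` where
``k_s`` is the successor count of state ``s``.

Implemented in NumPy: the one-hot input layer means a forward pass over all
N states is a single matrix of hidden activations, and a full-batch epoch
over the sampled pairs reduces exactly to a weighted pass over the N unique
inputs with their empirical label distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sr import TransitionModel

__all__ = [
    "PredictorNetwork",
    "TrainingConfig",
    "TrainingHistory",
    "AdamState",
    "init_network",
    "train",
    "predict_distribution",
    "predicted_tp_matrix",
    "evaluate",
    "rmse",
    "bayes_accuracy_ceiling",
    "architecture_sweep",
]


@dataclass
class PredictorNetwork:
    """Three-layer net: one-hot input (N) -> ReLU hidden (H) -> softmax (out).

    ``W1`` is stored (N, H) so a one-hot input selects a row; ``W2`` is
    (H, n_out). For successor prediction n_out == N; the same container holds
    the Q-network of the navigation agent, where n_out is the action count.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.W1.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[1]

    def hidden(self, states: np.ndarray) -> np.ndarray:
        """ReLU hidden activations for a batch of state indices."""
        return np.maximum(self.W1[states] + self.b1, 0.0)

    def logits(self, states: np.ndarray) -> np.ndarray:
        return self.hidden(states) @ self.W2 + self.b2

    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_network(
    n_states: int,
    hidden_fraction: float = 1.0,
    seed: int | None = None,
    n_outputs: int | None = None,
) -> PredictorNetwork:
    """Initialize a network with ``H = round(hidden_fraction * n_states)``.

    Weights use He initialization (fan-in scaled normal, suited to the ReLU
    hidden layer); biases start at zero. Deterministic given ``seed``.
    """
    if n_states < 2:
        raise ValueError(f"need at least 2 states, got {n_states}")
    if not 0.0 < hidden_fraction <= 2.0:
        raise ValueError(f"hidden_fraction must lie in (0, 2], got {hidden_fraction}")
    H = max(1, round(hidden_fraction * n_states))
    n_out = n_states if n_outputs is None else n_outputs
    rng = np.random.default_rng(seed)
    return PredictorNetwork(
        W1=rng.normal(0.0, np.sqrt(2.0 / n_states), (n_states, H)),
        b1=np.zeros(H),
        W2=rng.normal(0.0, np.sqrt(2.0 / H), (H, n_out)),
        b2=np.zeros(n_out),
    )


@dataclass
class TrainingConfig:
    """Training hyperparameters for the successor-prediction task.

    ``batch_size=None`` runs exact full-batch gradient descent over all
    sampled pairs per epoch (computed via the unique-input reduction);
    an integer gives shuffled mini-batches. ``plateau_tol``/``plateau_window``
    stop training early once the epoch loss changes by less than
    ``plateau_tol`` over ``plateau_window`` consecutive epochs (set
    ``plateau_tol=0`` to disable). ``validation_split`` carves off the stated
    fraction of pairs for the per-epoch validation accuracy.
    """

    epochs: int = 5000
    learning_rate: float = 0.01
    batch_size: int | None = None
    seed: int | None = None
    validation_split: float = 0.2
    plateau_tol: float = 1e-4
    plateau_window: int = 50

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.validation_split < 1.0:
            raise ValueError("validation_split must lie in [0, 1)")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    acc_train: list[float] = field(default_factory=list)
    acc_val: list[float] = field(default_factory=list)
    stopped_at_plateau: bool = False

    @property
    def epochs_run(self) -> int:
        return len(self.loss)


class AdamState:
    """Adaptive-moment-estimation optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _aggregate(pairs: np.ndarray, n_states: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique input states, their pair counts, and empirical label rows."""
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (pairs[:, 0], pairs[:, 1]), 1.0)
    totals = counts.sum(axis=1)
    states = np.flatnonzero(totals)
    return states, totals[states], counts[states] / totals[states, None]


def _grads(net: PredictorNetwork, states: np.ndarray, weights: np.ndarray,
           targets: np.ndarray) -> tuple[list[np.ndarray], float]:
    """Weighted cross-entropy gradient over unique one-hot inputs.

    Equivalent to the mean pairwise gradient with per-state weights
    ``count_s / n``; exact for full-batch training.
    """
    h = net.hidden(states)
    p = softmax(h @ net.W2 + net.b2)
    w = weights / weights.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(targets > 0, np.log(np.clip(p, 1e-300, None)), 0.0)
    loss = float(-(w[:, None] * targets * logp).sum())
    dlogits = w[:, None] * (p - targets)
    gW2 = h.T @ dlogits
    gb2 = dlogits.sum(axis=0)
    dh = (dlogits @ net.W2.T) * (h > 0)
    gW1 = np.zeros_like(net.W1)
    np.add.at(gW1, states, dh)
    gb1 = dh.sum(axis=0)
    return [gW1, gb1, gW2, gb2], loss


def _accuracy_against_pairs(net: PredictorNetwork, states, weights, targets) -> float:
    """Expected top-1 accuracy: P(argmax prediction == sampled label)."""
    pred = np.argmax(net.logits(states), axis=1)
    w = weights / weights.sum()
    return float((w * targets[np.arange(len(states)), pred]).sum())


def train(
    net: PredictorNetwork,
    pairs: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[PredictorNetwork, TrainingHistory]:
    """Train on (state, successor) pairs; returns the net and its history.

    The per-epoch training accuracy is the probability that the argmax
    prediction matches a pair drawn from the training set; validation
    accuracy is the same on the held-out split.
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        raise ValueError("cannot train on an empty pair set")
    if pairs.max() >= net.n_outputs or pairs.min() < 0:
        raise ValueError("pair indices outside the network's state range")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_split * len(pairs)))
    perm = rng.permutation(len(pairs))
    val, tr = pairs[perm[:n_val]], pairs[perm[n_val:]]
    if tr.size == 0:
        raise ValueError("validation split left no training pairs")

    states, weights, targets = _aggregate(tr, net.n_inputs)
    vstates = vweights = vtargets = None
    if len(val):
        vstates, vweights, vtargets = _aggregate(val, net.n_inputs)

    opt = AdamState(net.parameters(), config.learning_rate)
    hist = TrainingHistory()
    for _ in range(config.epochs):
        if config.batch_size is None:
            grads, loss = _grads(net, states, weights, targets)
            opt.step(net.parameters(), grads)
        else:
            order = rng.permutation(len(tr))
            losses = []
            for start in range(0, len(tr), config.batch_size):
                batch = tr[order[start:start + config.batch_size]]
                bs, bw, bt = _aggregate(batch, net.n_inputs)
                grads, loss = _grads(net, bs, bw, bt)
                opt.step(net.parameters(), grads)
                losses.append(loss * len(batch))
            loss = float(np.sum(losses) / len(tr))
        hist.loss.append(loss)
        hist.acc_train.append(_accuracy_against_pairs(net, states, weights, targets))
        hist.acc_val.append(
            _accuracy_against_pairs(net, vstates, vweights, vtargets)
            if vstates is not None else float("nan")
        )
        w = config.plateau_window
        if (config.plateau_tol > 0 and len(hist.loss) > w
                and abs(hist.loss[-1 - w] - hist.loss[-1]) < config.plateau_tol):
            hist.stopped_at_plateau = True
            break
    return net, hist


def predict_distribution(net: PredictorNetwork, s: int) -> np.ndarray:
    """Softmax successor distribution for state ``s`` (sums to 1)."""
    if not 0 <= s < net.n_inputs:
        raise IndexError(f"state {s} out of range for {net.n_inputs} inputs")
    return softmax(net.logits(np.array([s])))[0]


def predicted_tp_matrix(net: PredictorNetwork, n_states: int | None = None) -> TransitionModel:
    """Concatenate all per-state predictions into a row-stochastic matrix."""
    n = net.n_inputs if n_states is None else n_states
    return TransitionModel(softmax(net.logits(np.arange(n))))


def evaluate(net: PredictorNetwork, pairs: np.ndarray) -> float:
    """Top-1 accuracy of argmax predictions against the sampled labels."""
    pairs = np.asarray(pairs, dtype=int)
    pred = np.argmax(net.logits(pairs[:, 0]), axis=1)
    return float(np.mean(pred == pairs[:, 1]))


def rmse(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square difference over all entries of two equal-shape arrays."""
    A, B = np.asarray(A, float), np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean((A - B) ** 2)))


def bayes_accuracy_ceiling(model: TransitionModel, inputs: np.ndarray | None = None) -> float:
    """Maximal expected top-1 accuracy against stochastically sampled labels.

    For labels drawn from row ``s`` of ``T`` the best any predictor can do is
    ``max_s' T[s, s']``; the ceiling is its mean over the input distribution
    (uniform over ``inputs``, default all non-terminal rows).
    """
    T = model.T
    if inputs is None:
        inputs = np.flatnonzero(T.sum(axis=1) > 0)
    return float(T[inputs].max(axis=1).mean())


def architecture_sweep(
    pairs: np.ndarray,
    truth: TransitionModel,
    hidden_fractions: list[float],
    config: TrainingConfig = TrainingConfig(),
    n_states: int | None = None,
) -> list[dict]:
    """Train once per hidden-layer fraction; tabulate RMSE and accuracy.

    All runs share the sampled pairs and the seed protocol (the init seed is
    offset by the sweep position so runs differ only by architecture and
    draw).
    """
    if not hidden_fractions:
        raise ValueError("hidden_fractions must be nonempty")
    n = truth.n_states if n_states is None else n_states
    rows = []
    for i, frac in enumerate(hidden_fractions):
        seed = None if config.seed is None else config.seed + i
        net = init_network(n, hidden_fraction=frac, seed=seed)
        net, hist = train(net, pairs, config)
        rows.append({
            "hidden_fraction": frac,
            "hidden_size": net.hidden_size,
            "rmse": rmse(predicted_tp_matrix(net).T, truth.T),
            "final_accuracy": hist.acc_train[-1],
            "epochs_run": hist.epochs_run,
        })
    return rows
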