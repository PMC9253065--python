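"""End-to-end runs: exploration, navigation and language tasks.

Each run writes a self-contained artifact bundle to an output directory:
ground-truth and predicted transition/SR matrices as delimited text,
training histories as CSV, figure panels as PNG, and a JSON manifest echoing
the configuration, seed and headline metrics so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import analysis, grammar, io, rl, supervised
from .environments import (
    GridEnvironment,
    NeighborhoodSpec,
    build_alvernhe_maze,
    build_square_room,
    environment_transition_matrix,
    load_environment,
    sample_state_pairs,
)
from .sr import successor_matrix

__all__ = ["RunConfig", "run_explore", "run_navigate", "run_language"]

log = logging.getLogger("cogmap")


@dataclass
class RunConfig:
    """Configuration shared by the pipeline entry points.

    ``gamma``/``horizon`` parameterize the SR computed from learned and true
    transition matrices (defaults: undiscounted, 10 steps ahead for the
    spatial tasks; the language SR uses ``language_horizon=2``).
    """

    task: str = "explore"
    side: int = 10
    environment_file: str | None = None
    connectivity: int = 8
    include_self: bool = True
    gamma: float = 1.0
    horizon: float = 10
    language_horizon: int = 2
    n_pairs: int = 10_000
    epochs: int = 5000
    learning_rate: float = 0.01
    batch_size: int | None = None
    hidden_fraction: float = 1.0
    agent: rl.AgentConfig = field(default_factory=rl.AgentConfig)
    edge_threshold: float = 1e-4
    sample_states: tuple[int, ...] = ()
    n_eigenmaps: int = 30
    make_figures: bool = True
    seed: int = 0
    out: str = "runs/out"

    @property
    def neighborhood(self) -> NeighborhoodSpec:
        return NeighborhoodSpec(self.connectivity, self.include_self)

    def training(self, epochs: int | None = None) -> supervised.TrainingConfig:
        return supervised.TrainingConfig(
            epochs=self.epochs if epochs is None else epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
        )


def _environment(config: RunConfig) -> GridEnvironment:
    if config.environment_file:
        return load_environment(config.environment_file)
    if config.task == "navigate":
        return build_alvernhe_maze()
    return build_square_room(config.side)


def _heatmap_grid(fields, titles, path: Path, env: GridEnvironment | None = None,
                  ncols: int = 6) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(fields)
    ncols = min(ncols, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for ax, f, t in zip(axes.ravel(), fields, titles):
        shown = np.array(f, dtype=float)
        if env is not None:
            shown = np.where(env.allowed, shown, np.nan)
        ax.imshow(shown, cmap="viridis")
        ax.set_title(t, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _scatter(embedding: analysis.Embedding2D, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(embedding.labels):
        pts = embedding.coords[embedding.labels == lab]
        ax.scatter(pts[:, 0], pts[:, 1], label=str(lab), s=18)
    ax.legend(fontsize=7)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_explore(config: RunConfig) -> dict[str, Any]:
    """Supervised exploration of a room: learn T, build SR, render panels."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    env = _environment(config)
    spec = config.neighborhood
    T_true = environment_transition_matrix(env, spec)
    pairs = sample_state_pairs(env, spec, config.n_pairs, rng=config.seed)
    net = supervised.init_network(env.n_cells, config.hidden_fraction, seed=config.seed)
    net, hist = supervised.train(net, pairs, config.training())
    T_pred = supervised.predicted_tp_matrix(net)
    sr_true = successor_matrix(T_true, config.gamma, config.horizon)
    sr_pred = successor_matrix(T_pred, config.gamma, config.horizon)

    io.write_matrix(T_true.T, out / "tp_true.csv")
    io.write_matrix(T_pred.T, out / "tp_pred.csv")
    io.write_matrix(sr_true.M, out / "sr_true.csv")
    io.write_matrix(sr_pred.M, out / "sr_pred.csv")
    io.write_history(hist, out / "history.csv")

    samples = config.sample_states or tuple(
        int(s) for s in env.allowed_states[[len(env.allowed_states) // 3,
                                            2 * len(env.allowed_states) // 3]]
    )
    metrics = {
        "final_accuracy": hist.acc_val[-1],
        "final_train_accuracy": hist.acc_train[-1],
        "tp_rmse": supervised.rmse(T_pred.T, T_true.T),
        "epochs_run": hist.epochs_run,
        "stopped_at_plateau": hist.stopped_at_plateau,
        "bayes_ceiling": supervised.bayes_accuracy_ceiling(T_true),
    }
    if config.make_figures:
        H, W = env.height, env.width
        _heatmap_grid(
            [sr_true.M[s].reshape(H, W) for s in samples]
            + [sr_pred.M[s].reshape(H, W) for s in samples],
            [f"true SR from {s}" for s in samples]
            + [f"learned SR from {s}" for s in samples],
            out / "sr_panels.png", env, ncols=len(samples),
        )
        maps = analysis.eigenmaps_of_sr(sr_pred, env, k=min(config.n_eigenmaps, env.n_cells))
        _heatmap_grid(maps.maps, [f"ev {v:.2f}" for v in maps.eigenvalues],
                      out / "eigenmaps.png", env)
    manifest = {"task": "explore", "seed": config.seed, "metrics": metrics,
                "config": {k: v for k, v in vars(config).items() if k != "agent"},
                "runtime_s": round(time.time() - t0, 2)}
    io.write_manifest(manifest, out / "manifest.json")
    log.info("explore: acc=%.4f rmse=%.4f (%.1fs)", metrics["final_accuracy"],
             metrics["tp_rmse"], manifest["runtime_s"])
    return manifest


def run_navigate(config: RunConfig) -> dict[str, Any]:
    """Train the maze agent; extract its TP/SR next to the random-walk truth."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    env = _environment(config)
    agent_cfg = config.agent
    if agent_cfg.seed is None:
        agent_cfg = rl.AgentConfig(**{**vars(config.agent), "seed": config.seed})
    net, hist = rl.train_agent(env, agent_cfg)
    T_policy = rl.policy_tp_matrix(net, env)
    sr_policy = successor_matrix(T_policy, config.gamma, config.horizon)
    sr_truth = rl.maze_ground_truth_sr(env, config.neighborhood,
                                       config.gamma, config.horizon)
    io.write_matrix(T_policy.T, out / "tp_policy.csv")
    io.write_matrix(sr_policy.M, out / "sr_policy.csv")
    io.write_matrix(sr_truth.M, out / "sr_true.csv")
    io.write_history(hist, out / "rewards.csv")

    n_ep = hist.n_episodes
    first = float(np.mean(hist.rewards[:100])) if n_ep >= 100 else float(np.mean(hist.rewards))
    last = float(np.mean(hist.rewards[-100:])) if n_ep >= 100 else first
    metrics = {
        "n_episodes": n_ep,
        "reward_slope_600": rl.reward_trend_slope(hist),
        "mean_reward_first100": first,
        "mean_reward_last100": last,
    }
    samples = config.sample_states or tuple(
        int(s) for s in (env.allowed_states[4],
                         env.to_flat(7, 7),
                         env.allowed_states[-5])
    )
    if config.make_figures:
        H, W = env.height, env.width
        _heatmap_grid(
            [sr_truth.M[s].reshape(H, W) for s in samples]
            + [sr_policy.M[s].reshape(H, W) for s in samples],
            [f"true SR from {s}" for s in samples]
            + [f"agent SR from {s}" for s in samples],
            out / "sr_panels.png", env, ncols=len(samples),
        )
    manifest = {"task": "navigate", "seed": agent_cfg.seed, "metrics": metrics,
                "agent": vars(agent_cfg), "runtime_s": round(time.time() - t0, 2)}
    io.write_manifest(manifest, out / "manifest.json")
    log.info("navigate: episodes=%d slope=%.4f (%.1fs)", n_ep,
             metrics["reward_slope_600"], manifest["runtime_s"])
    return manifest


def run_language(config: RunConfig) -> dict[str, Any]:
    """Learn the artificial grammar; embed TP and SR rows; score purity."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    vocab, rules = grammar.build_grammar()
    T_true = grammar.word_transition_matrix(vocab, rules)
    pairs = grammar.sample_word_pairs(vocab, rules, config.n_pairs, rng=config.seed)
    net = supervised.init_network(len(vocab.words), config.hidden_fraction,
                                  seed=config.seed)
    net, hist = supervised.train(net, pairs, config.training())
    T_pred = supervised.predicted_tp_matrix(net)
    h = config.language_horizon
    sr_true = successor_matrix(T_true, 1.0, h)
    sr_pred = successor_matrix(T_pred, 1.0, h)

    io.write_matrix(T_true.T, out / "tp_true.csv")
    io.write_matrix(T_pred.T, out / "tp_pred.csv")
    io.write_matrix(sr_true.M, out / "sr_true.csv")
    io.write_matrix(sr_pred.M, out / "sr_pred.csv")
    io.write_history(hist, out / "history.csv")

    G = grammar.export_language_graph(vocab, T_true, config.edge_threshold)
    with open(out / "language_graph.edgelist", "w") as fh:
        for u, v, d in G.edges(data=True):
            fh.write(f"{u}\t{v}\t{d['weight']:.6g}\n")

    # classical coordinates are written for reference; cluster diagnostics run
    # on the stress refinement, which keeps all five TP classes distinct
    # (exact 2D classical scaling collapses the noun and question-word
    # clusters onto the origin for this grammar's symmetric geometry)
    labels = vocab.labels
    emb = {}
    for name, rowsrc in [("tp_true", T_true.T), ("tp_pred", T_pred.T),
                         ("sr_true", sr_true.M), ("sr_pred", sr_pred.M)]:
        e = analysis.mds_embed(rowsrc, labels, seed=config.seed)
        emb[name] = analysis.mds_embed(rowsrc, labels, method="stress",
                                       seed=config.seed)
        np.savetxt(out / f"mds_{name}.csv",
                   np.column_stack([labels, e.coords[:, 0], e.coords[:, 1]]),
                   fmt="%s", delimiter=",", header="label,x,y", comments="")
        if config.make_figures:
            _scatter(emb[name], out / f"mds_{name}.png", name)
    metrics = {
        "final_accuracy": hist.acc_val[-1],
        "final_train_accuracy": hist.acc_train[-1],
        "tp_rmse": supervised.rmse(T_pred.T, T_true.T),
        "epochs_run": hist.epochs_run,
        "n_graph_edges": G.number_of_edges(),
        "purity_tp_true": analysis.cluster_purity(emb["tp_true"], 5, seed=config.seed),
        "purity_sr_true": analysis.cluster_purity(emb["sr_true"], 5, seed=config.seed),
        "purity_tp_pred": analysis.cluster_purity(emb["tp_pred"], 5, seed=config.seed),
        "purity_sr_pred": analysis.cluster_purity(emb["sr_pred"], 5, seed=config.seed),
        "spread_tp_true": analysis.within_class_spread(emb["tp_true"]),
        "spread_sr_true": analysis.within_class_spread(emb["sr_true"]),
    }
    manifest = {"task": "language", "seed": config.seed, "metrics": metrics,
                "config": {k: v for k, v in vars(config).items() if k != "agent"},
                "runtime_s": round(time.time() - t0, 2)}
    io.write_manifest(manifest, out / "manifest.json")
    log.info("language: acc=%.4f purity(sr)=%.2f (%.1fs)",
             metrics["final_accuracy"], metrics["purity_sr_pred"],
             manifest["runtime_s"])
    return manifest
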