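"""Discrete grid environments: open rooms and a maze with reward trays.

States live on a full ``height x width`` lattice in row-major order; wall
cells keep their flat index so that matrices over the state space reshape
directly onto the room. Walls never act as input states and their transition
rows are identically zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sr import TransitionModel

__all__ = [
    "GridEnvironment",
    "NeighborhoodSpec",
    "build_square_room",
    "build_alvernhe_maze",
    "load_environment",
    "save_environment",
    "successors",
    "environment_transition_matrix",
    "sample_state_pairs",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Which cells count as direct successors of a cell.

    ``connectivity`` is 4 (von Neumann) or 8 (Moore, the default: diagonal
    moves allowed); ``include_self`` adds the cell itself, so an interior cell
    of an open room has 9 potential successor states by default.
    """

    connectivity: int = 8
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self.connectivity == 4:
            off = [(-1, 0), (0, -1), (0, 1), (1, 0)]
        else:
            off = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
        if self.include_self:
            off = [(0, 0)] + off
        return tuple(off)


@dataclass(frozen=True)
class GridEnvironment:
    """A rectangular lattice with a traversability mask and per-cell rewards.

    ``allowed`` and ``rewards`` are ``(height, width)`` arrays; flat state
    index of cell ``(r, c)`` is ``r * width + c``.
    """

    width: int
    height: int
    allowed: np.ndarray = field(repr=False)
    rewards: np.ndarray = field(repr=False)
    name: str = "grid"

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError(
                f"environment must be at least 2x2, got {self.height}x{self.width}"
            )
        allowed = np.asarray(self.allowed, dtype=bool)
        rewards = np.asarray(self.rewards, dtype=float)
        if allowed.shape != (self.height, self.width):
            raise ValueError("allowed mask shape does not match width/height")
        if rewards.shape != allowed.shape:
            raise ValueError("rewards shape does not match allowed mask")
        if not allowed.any():
            raise ValueError("environment must contain at least one allowed cell")
        if np.any((rewards != 0) & ~allowed):
            raise ValueError("rewards must be zero on wall cells")
        object.__setattr__(self, "allowed", allowed)
        object.__setattr__(self, "rewards", rewards)

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def allowed_states(self) -> np.ndarray:
        """Flat indices of traversable cells, ascending."""
        return np.flatnonzero(self.allowed.ravel())

    @property
    def reward_states(self) -> np.ndarray:
        return np.flatnonzero(self.rewards.ravel() != 0)

    @property
    def reward_vector(self) -> np.ndarray:
        return self.rewards.ravel().copy()

    def to_rc(self, s: int) -> tuple[int, int]:
        return divmod(int(s), self.width)

    def to_flat(self, r: int, c: int) -> int:
        return r * self.width + c

    def in_bounds(self, r: int, c: int) -> bool:
        return 0 <= r < self.height and 0 <= c < self.width

    def is_allowed(self, s: int) -> bool:
        r, c = self.to_rc(s)
        return bool(self.allowed[r, c])


def build_square_room(side: int = 10) -> GridEnvironment:
    """Open ``side x side`` room: every cell traversable, no rewards."""
    if side < 2:
        raise ValueError(f"room side must be >= 2, got {side}")
    return GridEnvironment(
        width=side,
        height=side,
        allowed=np.ones((side, side), bool),
        rewards=np.zeros((side, side)),
        name=f"square{side}",
    )


def load_environment(path: str | Path) -> GridEnvironment:
    """Read an environment from the JSON row-mask fixture format.

    ``rows`` is a list of strings, one character per cell: ``#`` wall,
    ``.`` traversable, any other character traversable with the reward value
    given for that character under ``rewards``.
    """
    spec = json.loads(Path(path).read_text())
    rows = spec["rows"]
    height, width = spec["height"], spec["width"]
    if len(rows) != height or any(len(r) != width for r in rows):
        raise ValueError(f"fixture rows do not match declared {height}x{width} shape")
    allowed = np.zeros((height, width), bool)
    rewards = np.zeros((height, width))
    reward_values = {k: float(v) for k, v in spec.get("rewards", {}).items()}
    for r, row in enumerate(rows):
        for c, ch in enumerate(row):
            if ch == "#":
                continue
            allowed[r, c] = True
            if ch != ".":
                rewards[r, c] = reward_values[ch]
    return GridEnvironment(
        width=width, height=height, allowed=allowed, rewards=rewards,
        name=spec.get("name", Path(path).stem),
    )


def save_environment(env: GridEnvironment, path: str | Path) -> None:
    """Write an environment in the same JSON row-mask format."""
    symbols: dict[float, str] = {}
    rows = []
    for r in range(env.height):
        chars = []
        for c in range(env.width):
            if not env.allowed[r, c]:
                chars.append("#")
            elif env.rewards[r, c] == 0:
                chars.append(".")
            else:
                v = float(env.rewards[r, c])
                if v not in symbols:
                    symbols[v] = chr(ord("A") + len(symbols))
                chars.append(symbols[v])
        rows.append("".join(chars))
    Path(path).write_text(json.dumps({
        "name": env.name,
        "width": env.width,
        "height": env.height,
        "rows": rows,
        "rewards": {sym: v for v, sym in symbols.items()},
    }, indent=1))


def build_alvernhe_maze() -> GridEnvironment:
    """The packaged 15x15 maze: 94 traversable of 225 cells.

    A central horizontal corridor carries a food tray (reward cell) at each
    end; six U-shaped side arms branch off the corridor as detours.
    """
    with resources.as_file(
        resources.files("cogmap.fixtures") / "alvernhe_maze.json"
    ) as p:
        return load_environment(p)


def successors(
    env: GridEnvironment, s: int, spec: NeighborhoodSpec = NeighborhoodSpec()
) -> np.ndarray:
    """Allowed direct successor states of ``s``, ascending flat indices.

    Walls and barriers are never successors; ``s`` itself is included iff
    ``spec.include_self``.
    """
    if not 0 <= s < env.n_cells:
        raise ValueError(f"state {s} outside the {env.height}x{env.width} lattice")
    if not env.is_allowed(s):
        raise ValueError(f"state {s} is a wall cell and has no successors")
    r, c = env.to_rc(s)
    out = [
        env.to_flat(r + dr, c + dc)
        for dr, dc in spec.offsets
        if env.in_bounds(r + dr, c + dc) and env.allowed[r + dr, c + dc]
    ]
    return np.array(sorted(out), dtype=int)


def environment_transition_matrix(
    env: GridEnvironment, spec: NeighborhoodSpec = NeighborhoodSpec()
) -> TransitionModel:
    """Uniform random-walk transition matrix over the full lattice.

    Row ``s`` is uniform over the allowed successors of ``s``; rows of wall
    cells are all zero, as are all columns into walls.
    """
    n = env.n_cells
    T = np.zeros((n, n))
    for s in env.allowed_states:
        nbrs = successors(env, int(s), spec)
        if nbrs.size:
            T[s, nbrs] = 1.0 / nbrs.size
    return TransitionModel(T)


def sample_state_pairs(
    env: GridEnvironment,
    spec: NeighborhoodSpec = NeighborhoodSpec(),
    n: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample ``n`` (input state, successor state) training pairs.

    The input state is uniform over allowed cells (walls are excluded as
    inputs) and the successor uniform over its allowed neighbors. Returns an
    ``(n, 2)`` integer array.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 pairs, got {n}")
    rng = np.random.default_rng(rng)
    states = env.allowed_states
    succ = {}
    for s in states:
        nb = successors(env, int(s), spec)
        if nb.size == 0:
            raise ValueError(f"cell {int(s)} has no successors; cannot sample pairs")
        succ[int(s)] = nb
    inputs = rng.choice(states, size=n)
    labels = np.array([succ[int(s)][rng.integers(len(succ[int(s)]))] for s in inputs])
    return np.column_stack([inputs, labels])
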