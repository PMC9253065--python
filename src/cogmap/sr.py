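"""Exact successor-representation mathematics.

The successor representation (SR) of a Markov transition matrix ``T`` is the
discounted expected future occupancy matrix

    M = sum_{t=0}^{h} gamma^t T^t,

where ``gamma`` is the discount factor and ``h`` the horizon (possibly
infinite, in which case ``M = (I - gamma T)^{-1}`` for ``gamma < 1``).
State values follow as ``V = M @ R`` for a per-state reward vector ``R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionModel",
    "SuccessorRepresentation",
    "ValueFunction",
    "successor_matrix",
    "value_function",
    "sr_partial_sum_oracle",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic one-step transition matrix over N discrete states.

    Rows of terminal states (e.g. wall cells kept in the lattice indexing, or
    words that never have a successor) are identically zero.
    """

    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError(f"transition matrix must be square, got {T.shape}")
        if np.any(T < -_ROW_SUM_TOL) or np.any(T > 1 + _ROW_SUM_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = T.sum(axis=1)
        ok = (np.abs(sums - 1.0) <= _ROW_SUM_TOL) | (np.abs(sums) <= _ROW_SUM_TOL)
        if not np.all(ok):
            bad = int(np.flatnonzero(~ok)[0])
            raise ValueError(
                f"row {bad} sums to {sums[bad]!r}; rows must sum to 1 (or 0 for "
                "terminal states)"
            )
        object.__setattr__(self, "T", T)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def terminal_states(self) -> np.ndarray:
        """Indices of all-zero rows."""
        return np.flatnonzero(self.T.sum(axis=1) <= _ROW_SUM_TOL)


@dataclass(frozen=True)
class SuccessorRepresentation:
    """Discounted expected-occupancy matrix with its defining parameters."""

    M: np.ndarray
    gamma: float
    horizon: float  # nonnegative integer, or math.inf

    @property
    def n_states(self) -> int:
        return self.M.shape[0]


@dataclass(frozen=True)
class ValueFunction:
    V: np.ndarray
    R: np.ndarray = field(repr=False)


def _check_discount(gamma: float, horizon: float) -> None:
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if math.isinf(horizon):
        if gamma >= 1.0:
            raise ValueError(
                "infinite-horizon SR diverges for gamma = 1; use gamma < 1 "
                "or a finite horizon"
            )
    elif horizon < 0 or horizon != int(horizon):
        raise ValueError(f"horizon must be a nonnegative integer or inf, got {horizon}")


def successor_matrix(
    model: TransitionModel | np.ndarray,
    gamma: float = 1.0,
    horizon: float = 10,
) -> SuccessorRepresentation:
    """Compute the SR ``M = sum_{t<=horizon} gamma^t T^t``.

    The finite-horizon sum is accumulated iteratively (one matrix product per
    term); the infinite-horizon case uses the closed form
    ``(I - gamma T)^{-1}`` and requires ``gamma < 1``.
    """
    T = model.T if isinstance(model, TransitionModel) else np.asarray(model, float)
    _check_discount(gamma, horizon)
    n = T.shape[0]
    if math.isinf(horizon):
        M = np.linalg.inv(np.eye(n) - gamma * T)
    else:
        M = np.eye(n)
        P = np.eye(n)
        for _ in range(int(horizon)):
            P = gamma * (P @ T)
            M += P
    return SuccessorRepresentation(M=M, gamma=gamma, horizon=horizon)


def value_function(
    sr: SuccessorRepresentation | np.ndarray, R: np.ndarray
) -> ValueFunction:
    """State values ``V = M @ R`` for reward vector ``R``."""
    M = sr.M if isinstance(sr, SuccessorRepresentation) else np.asarray(sr, float)
    R = np.asarray(R, dtype=float)
    if R.shape != (M.shape[0],):
        raise ValueError(f"reward vector has shape {R.shape}, expected ({M.shape[0]},)")
    return ValueFunction(V=M @ R, R=R)


def sr_partial_sum_oracle(
    model: TransitionModel | np.ndarray, gamma: float, horizon: int
) -> np.ndarray:
    """Brute-force SR reference: literal term-by-term sum of gamma^t T^t.

    Each term is recomputed independently with ``matrix_power``; this is an
    intentionally naive second code path used only to cross-check
    :func:`successor_matrix` in tests.
    """
    T = model.T if isinstance(model, TransitionModel) else np.asarray(model, float)
    n = T.shape[0]
    M = np.zeros((n, n))
    for t in range(int(horizon) + 1):
        M += gamma**t * np.linalg.matrix_power(T, t)
    return M
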