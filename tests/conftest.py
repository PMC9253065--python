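import numpy as np
import pytest

from cogmap.environments import (
    NeighborhoodSpec,
    build_alvernhe_maze,
    build_square_room,
    environment_transition_matrix,
)
from cogmap.grammar import build_grammar, word_transition_matrix


@pytest.fixture(scope="session")
def room10():
    return build_square_room(10)


@pytest.fixture(scope="session")
def moore():
    return NeighborhoodSpec(connectivity=8, include_self=True)


@pytest.fixture(scope="session")
def room10_T(room10, moore):
    return environment_transition_matrix(room10, moore)


@pytest.fixture(scope="session")
def maze():
    return build_alvernhe_maze()


@pytest.fixture(scope="session")
def grammar_fixture():
    return build_grammar()


@pytest.fixture(scope="session")
def language_T(grammar_fixture):
    vocab, rules = grammar_fixture
    return word_transition_matrix(vocab, rules)


@pytest.fixture(scope="session")
def ring8_T():
    """Uniform nearest-neighbor walk on an 8-state ring (no self moves)."""
    n = 8
    T = np.zeros((n, n))
    for i in range(n):
        T[i, (i - 1) % n] = T[i, (i + 1) % n] = 0.5
    return T
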