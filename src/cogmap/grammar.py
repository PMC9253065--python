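"""A 40-word artificial language with three construction rules.

The vocabulary has five word classes — adjectives (states 0-9), verbs
(10-19), nouns (20-29), pronouns (30-34) and question words (35-39) — and
word order is governed by three construction templates over classes:

    adjective -> noun
    pronoun -> verb -> adjective
    question -> pronoun -> verb

A transition between two words is allowed iff their classes are consecutive
in some rule; the concrete successor word is uniform within the successor
class. Nouns are rule-final only, so noun rows of the transition matrix are
zero and nouns never appear as training inputs. The word tokens are
synthetic ("adj00" .. "qw04"); sentences carry no meaning beyond their class
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .sr import TransitionModel

__all__ = [
    "WORD_CLASSES",
    "Vocabulary",
    "ConstructionRule",
    "build_grammar",
    "class_transitions",
    "word_transition_matrix",
    "sample_word_pairs",
    "export_language_graph",
]

WORD_CLASSES = ("adjective", "verb", "noun", "pronoun", "question")
_CLASS_SIZES = {"adjective": 10, "verb": 10, "noun": 10, "pronoun": 5, "question": 5}
_CLASS_PREFIX = {
    "adjective": "adj", "verb": "vrb", "noun": "nn",
    "pronoun": "prn", "question": "qw",
}


@dataclass(frozen=True)
class Vocabulary:
    words: tuple[str, ...]
    class_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.words) != 40:
            raise ValueError(f"vocabulary must hold 40 words, got {len(self.words)}")

    def index(self, word: str) -> int:
        return self.words.index(word)

    def class_indices(self, cls: str) -> np.ndarray:
        """Flat state indices of all words of class ``cls``."""
        return np.array([i for i, w in enumerate(self.words) if self.class_of[w] == cls])

    def class_of_state(self, s: int) -> str:
        return self.class_of[self.words[s]]

    @property
    def labels(self) -> np.ndarray:
        """Word-class label per state, aligned with ``words``."""
        return np.array([self.class_of[w] for w in self.words])


@dataclass(frozen=True)
class ConstructionRule:
    """An ordered template of word classes, e.g. (pronoun, verb, adjective)."""

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("a construction needs at least two class slots")
        unknown = set(self.sequence) - set(WORD_CLASSES)
        if unknown:
            raise ValueError(f"unknown word classes in rule: {sorted(unknown)}")

    @property
    def class_pairs(self) -> tuple[tuple[str, str], ...]:
        """Consecutive (class, successor class) pairs of the template."""
        return tuple(zip(self.sequence[:-1], self.sequence[1:]))


def build_grammar() -> tuple[Vocabulary, list[ConstructionRule]]:
    """The fixed 40-word vocabulary and the three construction rules."""
    words: list[str] = []
    class_of: dict[str, str] = {}
    for cls in WORD_CLASSES:
        for i in range(_CLASS_SIZES[cls]):
            w = f"{_CLASS_PREFIX[cls]}{i:02d}"
            words.append(w)
            class_of[w] = cls
    rules = [
        ConstructionRule(("adjective", "noun")),
        ConstructionRule(("pronoun", "verb", "adjective")),
        ConstructionRule(("question", "pronoun", "verb")),
    ]
    return Vocabulary(tuple(words), class_of), rules


def class_transitions(rules: Iterable[ConstructionRule]) -> set[tuple[str, str]]:
    """The set of allowed (class, successor class) transitions."""
    return {pair for rule in rules for pair in rule.class_pairs}


def word_transition_matrix(
    vocab: Vocabulary, rules: Iterable[ConstructionRule]
) -> TransitionModel:
    """Ground-truth word transition matrix.

    Row ``w`` is uniform over the words of the successor class of ``w``'s
    class; words whose class has no successor (nouns) get all-zero rows. No
    class has two distinct successor classes under the three rules.
    """
    n = len(vocab.words)
    T = np.zeros((n, n))
    succ_of: dict[str, set[str]] = {}
    for a, b in class_transitions(rules):
        succ_of.setdefault(a, set()).add(b)
    for s, w in enumerate(vocab.words):
        targets = succ_of.get(vocab.class_of[w], set())
        if not targets:
            continue
        cols = np.concatenate([vocab.class_indices(t) for t in sorted(targets)])
        T[s, cols] = 1.0 / cols.size
    return TransitionModel(T)


def sample_word_pairs(
    vocab: Vocabulary,
    rules: list[ConstructionRule],
    n: int = 5_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample ``n`` (input word, successor word) state pairs.

    A rule is drawn uniformly, then one of its consecutive class pairs
    uniformly, then both words uniformly within their classes. Nouns never
    occur as inputs (they are rule-final in every construction).
    """
    if n < 1:
        raise ValueError(f"need n >= 1 pairs, got {n}")
    rng = np.random.default_rng(rng)
    rule_pairs = [r.class_pairs for r in rules]
    idx = {cls: vocab.class_indices(cls) for cls in WORD_CLASSES}
    out = np.empty((n, 2), dtype=int)
    for i in range(n):
        pairs = rule_pairs[rng.integers(len(rule_pairs))]
        a, b = pairs[rng.integers(len(pairs))]
        out[i, 0] = idx[a][rng.integers(idx[a].size)]
        out[i, 1] = idx[b][rng.integers(idx[b].size)]
    return out


def export_language_graph(
    vocab: Vocabulary, model: TransitionModel, threshold: float = 1e-4
) -> nx.DiGraph:
    """Directed word graph with an edge wherever ``T[w, w'] >= threshold``.

    Nodes are words annotated with their class; edge weights are the
    transition probabilities. ``threshold`` prunes near-zero edges for
    readability when plotting.
    """
    if not 0.0 <= threshold:
        raise ValueError("threshold must be nonnegative")
    G = nx.DiGraph()
    for i, w in enumerate(vocab.words):
        G.add_node(w, word_class=vocab.class_of[w], state=i)
    rows, cols = np.nonzero(model.T >= threshold if threshold > 0 else model.T > 0)
    for i, j in zip(rows, cols):
        G.add_edge(vocab.words[i], vocab.words[j], weight=float(model.T[i, j]))
    return G
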