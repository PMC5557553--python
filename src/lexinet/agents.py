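"""Agents: Gaussian reactive-unit categorization plus an associative lexicon.

An agent's categorization system is a set of *categories*, each an adaptive
network of *reactive units*.  A unit is a Gaussian kernel centered on a
remembered stimulus ``m`` with an importance weight ``w_u``; its activation
for stimulus ``x`` is ``z_u(x) = exp(-||x - m||^2 / (2 sigma^2))`` and a
category responds with ``f_C(x) = sum_u w_u z_u(x)``.  Classification
assigns ``x`` to the category with the largest response, ties broken by
creation order.  With the default ``sigma = 1`` and LAB-scale distances the
kernels are extremely narrow: each unit effectively detects a single
stimulus and stimuli very close to it, and cross-stimulus activations
underflow to zero — accepted behavior, since units are meant to specialize.

The lexicon is a bidirectional association table between category ids and
shared word tokens with strengths clamped to [0, 1], updated in +/-0.1
steps by the game protocols.  ``NamingAgent`` keeps only such a lexicon,
keyed directly by discrete stimulus ids (no categorization layer).

Each agent also records the outcomes of its last 50 games; the fraction of
successes in that window is its *communicative success* (CS), which gates
the category-creation rule: above CS 0.95 a misclassified topic is absorbed
into its best-matching category, otherwise a fresh category is created.
"""

from __future__ import annotations

import itertools
import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReactiveUnit",
    "Category",
    "Lexicon",
    "WordFactory",
    "new_word",
    "Agent",
    "NamingAgent",
    "activation",
    "category_response",
    "HISTORY_WINDOW",
    "CS_THRESHOLD",
]

HISTORY_WINDOW = 50
CS_THRESHOLD = 0.95
DEFAULT_INITIAL_WEIGHT = 1.0
DEFAULT_FORGETTING_RATE = 0.01
ASSOCIATION_STEP = 0.1
INITIAL_ASSOCIATION = 0.5


@dataclass
class ReactiveUnit:
    center: np.ndarray
    weight: float = DEFAULT_INITIAL_WEIGHT

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.weight < 0:
            raise ValueError("unit weight must be non-negative")


@dataclass
class Category:
    """One adaptive network; ``id`` reflects creation order within an agent."""

    id: int
    units: list[ReactiveUnit] = field(default_factory=list)


def activation(unit: ReactiveUnit, x: np.ndarray, sigma: float = 1.0) -> float:
    """Gaussian activation ``exp(-||x - m||^2 / (2 sigma^2))``."""
    x = np.asarray(x, dtype=float)
    if x.shape != unit.center.shape:
        raise ValueError("stimulus and unit center dimensions differ")
    d2 = float(((x - unit.center) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def category_response(c: Category, x: np.ndarray, sigma: float = 1.0) -> float:
    """Adaptive-network output ``f_C(x) = sum_u w_u z_u(x)``."""
    return float(sum(u.weight * activation(u, x, sigma) for u in c.units))


class WordFactory:
    """Produces globally ordered, never-repeating word tokens.

    Token strings sort in creation order, so "earliest token" tie-breaks are
    plain lexicographic minima.
    """

    def __init__(self, start: int = 0) -> None:
        self._counter = itertools.count(start)

    def new_word(self) -> str:
        return f"w{next(self._counter):08d}"


_default_factory = WordFactory()


def new_word() -> str:
    """Draw a fresh token from the module-level word factory."""
    return _default_factory.new_word()


class Lexicon:
    """Bidirectional category <-> word association table, strengths in [0,1]."""

    def __init__(self) -> None:
        self._by_cat: dict[int, dict[str, float]] = {}
        self._by_word: dict[str, dict[int, float]] = {}

    def strength(self, cat_id: int, word: str) -> float:
        return self._by_cat.get(cat_id, {}).get(word, 0.0)

    def words_for(self, cat_id: int) -> dict[str, float]:
        return dict(self._by_cat.get(cat_id, {}))

    def categories_for(self, word: str) -> dict[int, float]:
        return dict(self._by_word.get(word, {}))

    def items(self):
        for cat_id, words in self._by_cat.items():
            for word, s in words.items():
                yield cat_id, word, s

    def update(self, cat_id: int, word: str, delta: float) -> float:
        """Add ``delta`` to the association, clamping into [0, 1].

        A missing pair counts as strength 0 before the update.
        """
        s = min(1.0, max(0.0, self.strength(cat_id, word) + delta))
        self._by_cat.setdefault(cat_id, {})[word] = s
        self._by_word.setdefault(word, {})[cat_id] = s
        return s

    def set(self, cat_id: int, word: str, strength: float) -> None:
        strength = min(1.0, max(0.0, strength))
        self._by_cat.setdefault(cat_id, {})[word] = strength
        self._by_word.setdefault(word, {})[cat_id] = strength

    def remove_category(self, cat_id: int) -> None:
        for word in self._by_cat.pop(cat_id, {}):
            self._by_word[word].pop(cat_id, None)
            if not self._by_word[word]:
                del self._by_word[word]

    def strongest_word(self, cat_id: int) -> str | None:
        """Word with the strongest association to ``cat_id``; ties go to the
        earliest-created token; None if the category names nothing."""
        words = self._by_cat.get(cat_id)
        if not words:
            return None
        best, best_s = None, -1.0
        for w in sorted(words):
            if words[w] > best_s:
                best, best_s = w, words[w]
        return best

    def strongest_category(self, word: str) -> int | None:
        cats = self._by_word.get(word)
        if not cats:
            return None
        best, best_s = None, -1.0
        for c in sorted(cats):
            if cats[c] > best_s:
                best, best_s = c, cats[c]
        return best

    def inhibit_other_categories(self, word: str, keep: int,
                                 delta: float = ASSOCIATION_STEP) -> None:
        """Lateral inhibition: weaken ``word``'s links to categories other
        than ``keep``.  Only existing associations are touched."""
        for c in list(self._by_word.get(word, {})):
            if c != keep:
                self.update(c, word, -delta)

    def inhibit_other_words(self, cat_id: int, keep: str,
                            delta: float = ASSOCIATION_STEP) -> None:
        for w in list(self._by_cat.get(cat_id, {})):
            if w != keep:
                self.update(cat_id, w, -delta)

    def to_triples(self) -> list[tuple[int, str, float]]:
        return sorted(self.items())

    @classmethod
    def from_triples(cls, triples) -> "Lexicon":
        lex = cls()
        for cat_id, word, s in triples:
            lex.set(int(cat_id), word, float(s))
        return lex


class Agent:
    """A grounded agent: categorization layer plus lexicon plus CS window."""

    def __init__(
        self,
        kernel_sigma: float = 1.0,
        learning_rate: float = 1.0,
        forgetting_rate: float = DEFAULT_FORGETTING_RATE,
        initial_weight: float = DEFAULT_INITIAL_WEIGHT,
        log_space: bool = False,
    ) -> None:
        if kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be positive")
        if learning_rate < 0 or forgetting_rate < 0:
            raise ValueError("rates must be non-negative")
        # log-space response comparison avoids kernel underflow for
        # numerical studies with narrow kernels; argmax is unchanged where
        # linear-space responses do not underflow
        self.log_space = bool(log_space)
        self.kernel_sigma = float(kernel_sigma)
        self.learning_rate = float(learning_rate)
        self.forgetting_rate = float(forgetting_rate)
        self.initial_weight = float(initial_weight)
        self.categories: list[Category] = []
        self.lexicon = Lexicon()
        self.history: deque[bool] = deque(maxlen=HISTORY_WINDOW)
        self._next_cat_id = 0
        # flattened unit views for vectorized classification
        self._flat_dirty = True
        self._centers: np.ndarray | None = None
        self._weights: np.ndarray | None = None
        self._unit_cat: np.ndarray | None = None

    # -- bookkeeping -------------------------------------------------------

    def _flatten(self) -> None:
        centers, weights, cats = [], [], []
        for c in self.categories:
            for u in c.units:
                centers.append(u.center)
                weights.append(u.weight)
                cats.append(c.id)
        self._centers = (np.asarray(centers, float) if centers
                         else np.empty((0, 3)))
        self._weights = np.asarray(weights, float)
        self._unit_cat = np.asarray(cats, dtype=int)
        self._flat_dirty = False

    def category_by_id(self, cat_id: int) -> Category:
        for c in self.categories:
            if c.id == cat_id:
                return c
        raise KeyError(f"no category with id {cat_id}")

    # -- categorization ----------------------------------------------------

    def responses(self, stimuli: np.ndarray) -> np.ndarray:
        """(n_categories, n_stimuli) matrix of adaptive-network outputs.

        Rows follow ``self.categories`` order (creation order).
        """
        stimuli = np.atleast_2d(np.asarray(stimuli, float))
        if self._flat_dirty:
            self._flatten()
        k = len(self.categories)
        if k == 0 or len(self._weights) == 0:
            fill = -np.inf if self.log_space else 0.0
            return np.full((k, len(stimuli)), fill)
        d2 = ((self._centers[:, None, :] - stimuli[None, :, :]) ** 2).sum(-1)
        order = [c.id for c in self.categories]
        if self.log_space:
            # log f_C = logsumexp_u (log w_u - d^2 / 2 sigma^2); units are
            # contiguous per category in flatten order
            with np.errstate(divide="ignore"):
                a = np.log(self._weights)[:, None] - d2 / (
                    2.0 * self.kernel_sigma**2)
            starts = np.flatnonzero(np.r_[True, np.diff(self._unit_cat) != 0])
            grouped = np.logaddexp.reduceat(a, starts, axis=0)
            resp = np.full((self._next_cat_id, len(stimuli)), -np.inf)
            resp[self._unit_cat[starts]] = grouped
            return resp[order]
        z = np.exp(-d2 / (2.0 * self.kernel_sigma**2))
        wz = self._weights[:, None] * z
        resp = np.zeros((self._next_cat_id, len(stimuli)))
        np.add.at(resp, self._unit_cat, wz)
        return resp[order]

    def classify(self, x: np.ndarray) -> int | None:
        """Category id with the largest response; None without categories.

        Ties (including the all-zero response of an unfamiliar stimulus)
        resolve to the earliest-created category.
        """
        if not self.categories:
            return None
        resp = self.responses(x)[:, 0]
        return self.categories[int(np.argmax(resp))].id

    def classify_many(self, stimuli: np.ndarray) -> list[int] | None:
        if not self.categories:
            return None
        resp = self.responses(stimuli)
        return [self.categories[int(i)].id for i in np.argmax(resp, axis=0)]

    def cs(self) -> float:
        """Fraction of successes over the trailing window; 0 with no games."""
        if not self.history:
            return 0.0
        return sum(self.history) / len(self.history)

    def record_outcome(self, success: bool) -> None:
        self.history.append(bool(success))

    # -- learning ----------------------------------------------------------

    def _create_category(self, topic: np.ndarray) -> Category:
        cat = Category(id=self._next_cat_id, units=[
            ReactiveUnit(center=np.array(topic, float),
                         weight=self.initial_weight)])
        self._next_cat_id += 1
        self.categories.append(cat)
        self._flat_dirty = True
        return cat

    def learn_topic(self, topic: np.ndarray) -> Category:
        """Category-update rule after a misclassification involving ``topic``.

        If the agent's (pre-game) CS exceeds 0.95 and a classification
        exists, the topic joins its best-matching category as a new unit;
        otherwise a fresh single-unit category is created.
        """
        if self.cs() > CS_THRESHOLD:
            cat_id = self.classify(topic)
            if cat_id is not None:
                cat = self.category_by_id(cat_id)
                cat.units.append(ReactiveUnit(
                    center=np.array(topic, float),
                    weight=self.initial_weight))
                self._flat_dirty = True
                return cat
        return self._create_category(topic)

    def reinforce_category(self, cat: Category | int,
                           topic: np.ndarray) -> None:
        """Strengthen every unit of ``cat`` by ``beta * z_u(topic)``."""
        if isinstance(cat, int):
            cat = self.category_by_id(cat)
        if cat not in self.categories:
            raise ValueError("category does not belong to this agent")
        for u in cat.units:
            u.weight += self.learning_rate * activation(
                u, topic, self.kernel_sigma)
        if not self._flat_dirty and self._weights is not None:
            # flat view stays aligned: units of one category are contiguous
            # in flatten order, so refresh them by mask
            mask = self._unit_cat == cat.id
            self._weights[mask] = [u.weight for u in cat.units]

    def decay_units(self) -> None:
        """Forgetting: scale every unit weight by (1 - forgetting_rate)."""
        f = 1.0 - self.forgetting_rate
        for c in self.categories:
            for u in c.units:
                u.weight *= f
        if not self._flat_dirty and self._weights is not None:
            self._weights *= f
        # flat view stays valid: only weights scaled

    def prune_units(self, min_weight: float = 1e-12) -> int:
        """Optional garbage collection for long runs: drop units whose
        weight decayed to ``min_weight`` or below, and categories (with
        their lexicon rows) left without units.  Returns units removed.
        Never called by the game protocols."""
        removed = 0
        for c in self.categories:
            kept = [u for u in c.units if u.weight > min_weight]
            removed += len(c.units) - len(kept)
            c.units = kept
        dead = [c.id for c in self.categories if not c.units]
        if dead:
            self.categories = [c for c in self.categories if c.units]
            for cat_id in dead:
                self.lexicon.remove_category(cat_id)
        self._flat_dirty = True
        return removed

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kernel_sigma": self.kernel_sigma,
            "learning_rate": self.learning_rate,
            "forgetting_rate": self.forgetting_rate,
            "initial_weight": self.initial_weight,
            "log_space": self.log_space,
            "next_cat_id": self._next_cat_id,
            "categories": [
                {"id": c.id,
                 "units": [{"center": [float(v) for v in u.center],
                            "weight": float(u.weight)} for u in c.units]}
                for c in self.categories
            ],
            "lexicon": [[c, w, s] for c, w, s in self.lexicon.to_triples()],
            "history": [bool(h) for h in self.history],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Agent":
        agent = cls(kernel_sigma=d["kernel_sigma"],
                    learning_rate=d["learning_rate"],
                    forgetting_rate=d["forgetting_rate"],
                    initial_weight=d["initial_weight"],
                    log_space=d.get("log_space", False))
        for cd in d["categories"]:
            agent.categories.append(Category(
                id=int(cd["id"]),
                units=[ReactiveUnit(center=np.asarray(u["center"], float),
                                    weight=float(u["weight"]))
                       for u in cd["units"]]))
        agent._next_cat_id = int(d["next_cat_id"])
        agent.lexicon = Lexicon.from_triples(d["lexicon"])
        agent.history.extend(bool(h) for h in d["history"])
        agent._flat_dirty = True
        return agent

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "Agent":
        return cls.from_dict(json.loads(s))


class NamingAgent:
    """Lexical layer only: word <-> discrete-stimulus associations."""

    def __init__(self) -> None:
        self._by_stim: dict[str, dict[str, float]] = {}
        self._by_word: dict[str, dict[str, float]] = {}
        self.history: deque[bool] = deque(maxlen=HISTORY_WINDOW)

    def strength(self, stimulus: str, word: str) -> float:
        return self._by_stim.get(stimulus, {}).get(word, 0.0)

    def knows_word(self, word: str) -> bool:
        return bool(self._by_word.get(word))

    def update(self, stimulus: str, word: str, delta: float) -> None:
        s = min(1.0, max(0.0, self.strength(stimulus, word) + delta))
        self._by_stim.setdefault(stimulus, {})[word] = s
        self._by_word.setdefault(word, {})[stimulus] = s

    def set(self, stimulus: str, word: str, strength: float) -> None:
        strength = min(1.0, max(0.0, strength))
        self._by_stim.setdefault(stimulus, {})[word] = strength
        self._by_word.setdefault(word, {})[stimulus] = strength

    def strongest_word(self, stimulus: str) -> str | None:
        words = self._by_stim.get(stimulus)
        if not words:
            return None
        best, best_s = None, -1.0
        for w in sorted(words):
            if words[w] > best_s:
                best, best_s = w, words[w]
        return best

    def point(self, word: str, context_stimuli) -> int:
        """Index of the context stimulus most strongly tied to ``word``;
        all-zero associations resolve to the lowest index."""
        strengths = [self.strength(s, word) for s in context_stimuli]
        return int(np.argmax(strengths))

    def inhibit_other_stimuli(self, word: str, keep: str,
                              delta: float = ASSOCIATION_STEP) -> None:
        for s in list(self._by_word.get(word, {})):
            if s != keep:
                self.update(s, word, -delta)

    def inhibit_other_words(self, stimulus: str, keep: str,
                            delta: float = ASSOCIATION_STEP) -> None:
        for w in list(self._by_stim.get(stimulus, {})):
            if w != keep:
                self.update(stimulus, w, -delta)

    def cs(self) -> float:
        if not self.history:
            return 0.0
        return sum(self.history) / len(self.history)

    def record_outcome(self, success: bool) -> None:
        self.history.append(bool(success))

    def to_dict(self) -> dict:
        return {
            "lexicon": sorted((s, w, v) for s, words in self._by_stim.items()
                              for w, v in words.items()),
            "history": [bool(h) for h in self.history],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NamingAgent":
        agent = cls()
        for s, w, v in d["lexicon"]:
            agent.set(s, w, float(v))
        agent.history.extend(bool(h) for h in d["history"])
        return agent

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NamingAgent":
        return cls.from_dict(json.loads(s))
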