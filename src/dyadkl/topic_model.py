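"""Lexicon-based topic distributions and support alignment.

Text is mapped to a probability vector over named topic categories by counting
lexicon-word hits: each category owns a word set, a token may hit several
categories (as in Empath-style lexicons), and raw hit counts are normalised to
a distribution.  Categories with zero hits are excluded from the support.

Because two finite texts rarely populate the same categories, divergences are
computed after :func:`align_support`: either restrict both distributions to
their common support and renormalise (default — divergences are then taken on
the mutual support of the two distributions), or smooth over the union of
supports with a pseudo-count.

An Empath adapter with the same interface is available in
:mod:`dyadkl.empath_adapter` for environments where that package is installed;
the bundled counter above is the transparent, reproducible default.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import DyadInteraction, Utterance, tokenize

__all__ = [
    "Lexicon",
    "TopicDistribution",
    "EmptyDistributionError",
    "DisjointSupportError",
    "topic_distribution",
    "character_distribution",
    "dyad_distribution",
    "align_support",
]

_SUM_TOL = 1e-9


class EmptyDistributionError(ValueError):
    """No token of the text hit any lexicon category."""


class DisjointSupportError(ValueError):
    """Two distributions share no support category."""


class Lexicon:
    """Ordered topic categories, each owning a set of lowercase words."""

    def __init__(self, words: Mapping[str, Iterable[str]],
                 categories: Sequence[str] | None = None):
        self.categories: tuple[str, ...] = tuple(
            categories if categories is not None else words.keys()
        )
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate category names")
        self.words: dict[str, frozenset] = {}
        for cat in self.categories:
            ws = frozenset(w.lower() for w in words[cat])
            if not ws:
                raise ValueError(f"category {cat!r} has no words")
            self.words[cat] = ws
        # token -> indices of every category containing it (multi-hit allowed)
        index: dict[str, list[int]] = {}
        for ci, cat in enumerate(self.categories):
            for w in self.words[cat]:
                index.setdefault(w, []).append(ci)
        self._index = {w: tuple(cs) for w, cs in index.items()}

    def __len__(self) -> int:
        return len(self.categories)

    def category_hits(self, token: str) -> tuple[int, ...]:
        return self._index.get(token, ())

    def word_lists(self) -> dict[str, tuple[str, ...]]:
        """Deterministically ordered word tuples per category (for sampling)."""
        return {cat: tuple(sorted(ws)) for cat, ws in self.words.items()}

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(data)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({c: sorted(self.words[c]) for c in self.categories},
                      fh, indent=1)


@dataclass(frozen=True, eq=False)
class TopicDistribution:
    """A probability vector over named topic categories.

    ``counts`` preserves the raw hit counts when the distribution came from
    text, so that pseudo-count smoothing can operate on the original masses.
    ``normalized`` is False only for the restricted-without-renormalisation
    variant of support alignment.
    """

    categories: tuple[str, ...]
    probs: np.ndarray
    counts: np.ndarray | None = None
    normalized: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if len(self.categories) != self.probs.shape[0]:
            raise ValueError("categories and probs length mismatch")
        if np.any(self.probs < 0):
            raise ValueError("negative probability")
        total = float(self.probs.sum())
        if self.normalized:
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"probabilities sum to {total}, not 1")
        elif not (0 < total <= 1 + _SUM_TOL):
            raise ValueError(f"restricted mass {total} outside (0, 1]")
        if not np.any(self.probs > 0):
            raise ValueError("distribution with no positive entry")

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(c for c, p in zip(self.categories, self.probs) if p > 0)

    def prob_of(self, category: str) -> float:
        try:
            return float(self.probs[self.categories.index(category)])
        except ValueError:
            return 0.0

    def allclose(self, other: "TopicDistribution", atol: float = 1e-12) -> bool:
        return (self.categories == other.categories
                and np.allclose(self.probs, other.probs, atol=atol))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for c, p in zip(self.categories, self.probs):
                fh.write(f"{c}\t{p:.12g}\n")


def topic_distribution(text: str, lexicon: Lexicon) -> TopicDistribution:
    """Count lexicon hits per category in ``text`` and normalise.

    A token contributes one raw count to every category containing it.
    Categories with zero hits are dropped from the support.  Raises
    :class:`EmptyDistributionError` when no token hits any category.
    """
    tokens = tokenize(text)
    hits: Counter = Counter()
    for tok in tokens:
        for ci in lexicon.category_hits(tok):
            hits[ci] += 1
    if not hits:
        raise EmptyDistributionError(
            f"no lexicon hit in text of {len(tokens)} words"
        )
    indices = sorted(hits)
    counts = np.array([hits[i] for i in indices], dtype=float)
    cats = tuple(lexicon.categories[i] for i in indices)
    return TopicDistribution(cats, counts / counts.sum(), counts=counts)


def character_distribution(
    utterances: Iterable[Utterance], speaker: str, lexicon: Lexicon
) -> TopicDistribution:
    """Topic distribution of one character over a slice of utterances.

    The slice is typically everything the character said across all the
    interactions she has been involved in; her utterance texts are
    concatenated before counting, which is equivalent to summing per-utterance
    hit counts.
    """
    texts = [u.text for u in utterances if u.speaker == speaker]
    if not texts:
        raise ValueError(f"speaker {speaker!r} has no utterances in this slice")
    return topic_distribution(" ".join(texts), lexicon)


def dyad_distribution(interaction: DyadInteraction,
                      lexicon: Lexicon) -> TopicDistribution:
    """Joint topic distribution of both parties' text within one interaction."""
    return topic_distribution(
        " ".join(u.text for u in interaction.utterances), lexicon
    )


def _restrict(dist: TopicDistribution, cats: Sequence[str],
              renormalize: bool) -> TopicDistribution:
    lookup = {c: i for i, c in enumerate(dist.categories)}
    vec = np.array([dist.probs[lookup[c]] if c in lookup else 0.0 for c in cats])
    if renormalize:
        return TopicDistribution(tuple(cats), vec / vec.sum())
    return TopicDistribution(tuple(cats), vec, normalized=False)


def align_support(
    P: TopicDistribution,
    Q: TopicDistribution,
    mode: str = "intersection",
    alpha: float = 0.5,
    renormalize: bool = True,
) -> tuple[TopicDistribution, TopicDistribution]:
    """Place two distributions on one identical, ordered category list.

    ``intersection`` (default) restricts both to their common support and
    renormalises each, so divergence is taken over the categories both texts
    actually populate.  ``union_smoothed`` takes the union of supports, adds a
    pseudo-count ``alpha`` to every category's raw mass (hit counts when
    available, probabilities otherwise) and renormalises.  Output categories
    are sorted, making the operation symmetric in structure.
    """
    if mode == "intersection":
        common = sorted(set(P.support) & set(Q.support))
        if not common:
            raise DisjointSupportError(
                f"no common support between {len(P.support)}- and "
                f"{len(Q.support)}-category distributions"
            )
        return (_restrict(P, common, renormalize),
                _restrict(Q, common, renormalize))
    if mode == "union_smoothed":
        union = sorted(set(P.categories) | set(Q.categories))
        out = []
        for dist in (P, Q):
            mass = dist.counts if dist.counts is not None else dist.probs
            lookup = {c: i for i, c in enumerate(dist.categories)}
            vec = np.array(
                [float(mass[lookup[c]]) if c in lookup else 0.0 for c in union]
            ) + alpha
            out.append(TopicDistribution(tuple(union), vec / vec.sum()))
        return out[0], out[1]
    raise ValueError(f"unknown alignment mode {mode!r}")
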