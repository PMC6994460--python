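"""Synthetic script corpora with known dyadic topic structure.

The generator instantiates the statistical model the analysis assumes, with
ground truth attached, so that the whole pipeline — extraction, topic
distributions, divergence features, balancing, evaluation — can be exercised
and its recovery behaviour measured.

Generative model
----------------
Each character owns an individual topic prior drawn from a symmetric
Dirichlet over ``n_topics`` categories.  A dyad (main G, partner C) produces
text in one of two regimes:

* non-significant: each party speaks from her own prior; the main
  contributes a ``mixture_weight`` share of the words, so the dyad's joint
  distribution is the mixture  GC = w*G + (1-w)*C  — nothing emerges that is
  not already in the individuals.
* significant: the interaction carries an *emergent* component E (a fresh
  Dirichlet draw, or a boosted random topic subset in ``topic_shift`` mode):
  both parties speak from  (1-delta)*prior + delta*E  in equal shares, so
  GC = (1-delta)*(G+C)/2 + delta*E  is not a mixture of the individuals.

Interaction lengths (total words) follow class-specific log-normal laws.
With ``confound_lengths`` on (the default, mirroring real scripts),
significant interactions are much longer than non-significant ones, which
deliberately entangles length with the class label; switching it off draws
both classes from the significant-class law, equalising lengths.

Words are sampled topic-first, then uniformly within the topic's word list;
lines alternate between the two speakers.  All randomness descends from one
seed through ``numpy.random.SeedSequence`` spawning, so sub-streams are
stable under refactoring.

The neutral-text control replaces every utterance with a same-word-count
slice of a neutral token stream (random offsets), preserving speakers,
ordering and word counts exactly — any separation that survives is driven by
length, not content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import (
    NON_SIGNIFICANT,
    SIGNIFICANT,
    Corpus,
    SignificanceRegistry,
    Utterance,
    tokenize,
    word_count,
)
from .topic_model import Lexicon

__all__ = [
    "SyntheticConfig",
    "SyntheticConfigError",
    "InsufficientNeutralTextError",
    "GroundTruth",
    "generate_lexicon",
    "generate_corpus",
    "neutral_token_stream",
    "replace_with_neutral_text",
]


class SyntheticConfigError(ValueError):
    """Invalid generator configuration; the message lists every violation."""


class InsufficientNeutralTextError(ValueError):
    """The neutral source is shorter than the longest utterance demands."""


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic script corpus.

    Defaults emulate the real-series conditions the pipeline targets: four
    main characters with (4, 2, 3, 4) significant partners — 13 significant
    dyads in all — and 25 non-significant partners each (100 dyads), sparse
    individual priors over 194 topics, a strong emergent component in
    significant dyads, and heavily length-confounded classes (significant
    interactions several times longer, log-normally spread).
    """

    seed: int
    n_topics: int = 194
    words_per_topic: int = 20
    n_mains: int = 4
    #: per-main (n_significant, n_nonsignificant); a single pair is
    #: broadcast to every main.
    partners_per_main: Sequence[tuple[int, int]] | tuple[int, int] = (
        (4, 25), (2, 25), (3, 25), (4, 25),
    )
    concentration: float = 0.5
    emergence_delta: float = 0.8
    mixture_weight: float = 0.5
    #: (meanlog, sdlog) of total interaction words per class.
    length_law: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            SIGNIFICANT: (8.0, 0.6),
            NON_SIGNIFICANT: (5.8, 1.0),
        }
    )
    confound_lengths: bool = True
    words_per_line: float = 9.0
    emergent_mode: str = "dirichlet"
    topic_shift_fraction: float = 0.05

    def per_main_partners(self) -> list[tuple[int, int]]:
        ppm = self.partners_per_main
        if (len(ppm) == 2 and all(isinstance(v, (int, np.integer)) for v in ppm)):
            return [tuple(ppm)] * self.n_mains  # type: ignore[list-item]
        return [tuple(p) for p in ppm]

    def validate(self) -> None:
        errors: list[str] = []
        if self.seed is None:
            errors.append("seed is mandatory")
        if self.n_topics < 1:
            errors.append("n_topics must be >= 1")
        if self.words_per_topic < 1:
            errors.append("words_per_topic must be >= 1")
        if self.n_mains < 0:
            errors.append("n_mains must be >= 0")
        try:
            ppm = self.per_main_partners()
            if len(ppm) != self.n_mains:
                errors.append(
                    f"partners_per_main has {len(ppm)} entries for "
                    f"{self.n_mains} mains"
                )
            if any(s < 0 or n < 0 for s, n in ppm):
                errors.append("partner counts must be >= 0")
        except (TypeError, ValueError):
            errors.append("partners_per_main must be (s, n) or a list of pairs")
        if not 0.0 <= self.emergence_delta <= 1.0:
            errors.append("emergence_delta must lie in [0, 1]")
        if not 0.0 <= self.mixture_weight <= 1.0:
            errors.append("mixture_weight must lie in [0, 1]")
        if self.concentration <= 0:
            errors.append("concentration must be positive")
        for cls in (SIGNIFICANT, NON_SIGNIFICANT):
            if cls not in self.length_law:
                errors.append(f"length_law missing class {cls!r}")
            else:
                _, sd = self.length_law[cls]
                if sd < 0:
                    errors.append(f"length_law[{cls!r}] sdlog must be >= 0")
        if self.words_per_line < 1:
            errors.append("words_per_line must be >= 1")
        if self.emergent_mode not in ("dirichlet", "topic_shift"):
            errors.append(f"unknown emergent_mode {self.emergent_mode!r}")
        if errors:
            raise SyntheticConfigError("; ".join(errors))


@dataclass
class GroundTruth:
    """True generative quantities returned alongside a synthetic corpus."""

    registry: SignificanceRegistry
    labels: dict[tuple[str, str], str]
    priors: dict[str, np.ndarray]
    gc_true: dict[tuple[str, str], np.ndarray]
    emergent: dict[tuple[str, str], np.ndarray]


def generate_lexicon(n_topics: int, words_per_topic: int,
                     seed: int = 0) -> Lexicon:
    """Disjoint synthetic word sets per category, deterministic under seed.

    Produces exactly ``n_topics * words_per_topic`` distinct words; the
    assignment of words to categories is shuffled by the seed.
    """
    if n_topics < 1 or words_per_topic < 1:
        raise ValueError("n_topics and words_per_topic must be >= 1")
    total = n_topics * words_per_topic
    width = len(str(total - 1))
    vocab = [f"w{idx:0{width}d}" for idx in range(total)]
    rng = np.random.default_rng(seed)
    rng.shuffle(vocab)
    words = {
        f"topic{ci:03d}": vocab[ci * words_per_topic:(ci + 1) * words_per_topic]
        for ci in range(n_topics)
    }
    return Lexicon(words)


def _word_matrix(lexicon: Lexicon) -> np.ndarray | list[np.ndarray]:
    lists = [np.array(ws) for ws in lexicon.word_lists().values()]
    sizes = {len(ws) for ws in lists}
    if len(sizes) == 1:
        return np.stack(lists)
    return lists


def _sample_words(dist: np.ndarray, n: int, words, rng: np.random.Generator
                  ) -> list[str]:
    topics = rng.choice(len(dist), size=n, p=dist)
    if isinstance(words, np.ndarray):
        idx = rng.integers(0, words.shape[1], size=n)
        return list(words[topics, idx])
    return [words[t][rng.integers(0, len(words[t]))] for t in topics]


def _chunk_lines(tokens: list[str], mean_len: float,
                 rng: np.random.Generator) -> list[str]:
    lines = []
    i = 0
    while i < len(tokens):
        length = 1 + rng.poisson(max(mean_len - 1.0, 0.0))
        lines.append(" ".join(tokens[i:i + length]))
        i += length
    return lines


def _emergent_component(prior_alpha: np.ndarray, g: np.ndarray, c: np.ndarray,
                        cfg: SyntheticConfig,
                        rng: np.random.Generator) -> np.ndarray:
    if cfg.emergent_mode == "dirichlet":
        return rng.dirichlet(prior_alpha)
    # topic_shift: concentrate mass on a small random topic subset
    k = len(g)
    n_shift = max(1, int(round(cfg.topic_shift_fraction * k)))
    chosen = rng.choice(k, size=n_shift, replace=False)
    e = np.full(k, 1e-12)
    e[chosen] = rng.dirichlet(np.full(n_shift, 1.0))
    return e / e.sum()


def generate_corpus(config: SyntheticConfig,
                    lexicon: Lexicon) -> tuple[Corpus, GroundTruth]:
    """Generate a script corpus realising the configured dyadic model.

    Every dyad occupies its own episode (season 1) with alternating-speaker
    lines, so sliding-window extraction recovers exactly the configured
    dyads.  Returns the corpus and the ground truth (labels, per-character
    priors, per-dyad true joint distributions and emergent components).
    """
    config.validate()
    if len(lexicon) != config.n_topics:
        raise SyntheticConfigError(
            f"lexicon has {len(lexicon)} categories, config expects "
            f"{config.n_topics}"
        )
    root = np.random.SeedSequence(config.seed)
    rng_priors, rng_dyads, rng_text = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    words = _word_matrix(lexicon)
    alpha = np.full(config.n_topics, config.concentration)

    utterances: list[Utterance] = []
    labels: dict[tuple[str, str], str] = {}
    priors: dict[str, np.ndarray] = {}
    gc_true: dict[tuple[str, str], np.ndarray] = {}
    emergent: dict[tuple[str, str], np.ndarray] = {}
    registry_map: dict[str, list[str]] = {}

    episode = 0
    for m, (n_sig, n_non) in enumerate(config.per_main_partners(), start=1):
        main = f"Main{m}"
        priors[main] = rng_priors.dirichlet(alpha)
        registry_map[main] = [f"M{m}S{j}" for j in range(1, n_sig + 1)]
        partner_specs = (
            [(f"M{m}S{j}", SIGNIFICANT) for j in range(1, n_sig + 1)]
            + [(f"M{m}N{j}", NON_SIGNIFICANT) for j in range(1, n_non + 1)]
        )
        for partner, cls in partner_specs:
            priors[partner] = rng_priors.dirichlet(alpha)
            g, c = priors[main], priors[partner]
            if cls == SIGNIFICANT:
                e = _emergent_component(alpha, g, c, config, rng_dyads)
                delta = config.emergence_delta
                dist_main = (1 - delta) * g + delta * e
                dist_partner = (1 - delta) * c + delta * e
                share = 0.5
                truth = (1 - delta) * 0.5 * (g + c) + delta * e
                emergent[(main, partner)] = e
            else:
                dist_main, dist_partner = g, c
                share = config.mixture_weight
                truth = share * g + (1 - share) * c
            labels[(main, partner)] = cls
            gc_true[(main, partner)] = truth

            law_class = cls if config.confound_lengths else SIGNIFICANT
            meanlog, sdlog = config.length_law[law_class]
            total = max(2, int(round(rng_dyads.lognormal(meanlog, sdlog))))
            n_main = min(max(1, int(round(share * total))), total - 1)
            n_partner = total - n_main

            lines_main = _chunk_lines(
                _sample_words(dist_main, n_main, words, rng_text),
                config.words_per_line, rng_text)
            lines_partner = _chunk_lines(
                _sample_words(dist_partner, n_partner, words, rng_text),
                config.words_per_line, rng_text)

            episode += 1
            line_index = 0
            a, b = list(lines_main), list(lines_partner)
            turn_main = True
            while a or b:
                if turn_main and a:
                    text, speaker = a.pop(0), main
                elif not turn_main and b:
                    text, speaker = b.pop(0), partner
                elif a:
                    text, speaker = a.pop(0), main
                else:
                    text, speaker = b.pop(0), partner
                utterances.append(
                    Utterance(1, episode, line_index, speaker, text))
                line_index += 1
                turn_main = not turn_main

    truth = GroundTruth(
        registry=SignificanceRegistry(registry_map),
        labels=labels,
        priors=priors,
        gc_true=gc_true,
        emergent=emergent,
    )
    return Corpus(utterances), truth


def neutral_token_stream(lexicon: Lexicon, n_words: int,
                         seed: int = 0) -> list[str]:
    """A content-free token stream: uniform category, then uniform word.

    Plays the role of the replacement text in the length-confound control;
    sampling from the lexicon guarantees every slice still hits topic
    categories, unlike an arbitrary external text.
    """
    rng = np.random.default_rng(seed)
    words = _word_matrix(lexicon)
    uniform = np.full(len(lexicon), 1.0 / len(lexicon))
    return _sample_words(uniform, n_words, words, rng)


def replace_with_neutral_text(
    corpus: Corpus,
    neutral_source: str | Sequence[str],
    seed: int = 0,
) -> Corpus:
    """Replace every utterance with an equally long slice of neutral text.

    ``neutral_source`` is a token sequence or a raw string (tokenised with
    the package tokenizer).  Each utterance receives a contiguous slice of
    the source at a random offset, with exactly its original word count;
    speakers, ordering and per-utterance word counts are preserved, so the
    interaction structure survives while topical content is erased.
    """
    tokens = (list(neutral_source) if not isinstance(neutral_source, str)
              else tokenize(neutral_source))
    demands = [word_count(u.text) for u in corpus]
    max_demand = max(demands, default=0)
    if max_demand > len(tokens):
        raise InsufficientNeutralTextError(
            f"neutral source has {len(tokens)} tokens but an utterance "
            f"needs {max_demand}"
        )
    rng = np.random.default_rng(seed)
    replaced = []
    for u, need in zip(corpus, demands):
        if need == 0:
            text = ""
        else:
            offset = int(rng.integers(0, len(tokens) - need + 1))
            text = " ".join(tokens[offset:offset + need])
        replaced.append(Utterance(u.season, u.episode, u.line_index,
                                  u.speaker, text))
    return Corpus(replaced, skipped_rows=corpus.skipped_rows)
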