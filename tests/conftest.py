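import numpy as np
import pytest

from dyadkl.corpus_io import Corpus, DyadInteraction, Utterance
from dyadkl.topic_model import Lexicon, TopicDistribution


@pytest.fixture
def toy_lexicon() -> Lexicon:
    return Lexicon({"sport": {"ball", "goal"}, "food": {"pizza"}})


@pytest.fixture
def three_cat_lexicon() -> Lexicon:
    """Disjoint one-word categories so hit counts equal word counts."""
    return Lexicon({"s": {"sa"}, "t": {"tb"}, "u": {"uc"}})


def make_dist(probs, cats=None) -> TopicDistribution:
    probs = np.asarray(probs, dtype=float)
    if cats is None:
        cats = tuple(f"c{i:03d}" for i in range(len(probs)))
    return TopicDistribution(tuple(cats), probs)


def random_dist(rng: np.random.Generator, k: int) -> TopicDistribution:
    """A strictly positive random distribution on k shared categories."""
    p = rng.dirichlet(np.full(k, 0.7)) + 1e-12
    return make_dist(p / p.sum())


def episode_corpus(speakers, texts=None, season=1, episode=1) -> Corpus:
    """One-episode corpus from a list of speaker names (and optional texts)."""
    if texts is None:
        texts = [f"word{i}" for i in range(len(speakers))]
    return Corpus([
        Utterance(season, episode, i, s, t)
        for i, (s, t) in enumerate(zip(speakers, texts))
    ])


def make_interaction(main, partner, words_partner, words_main=0,
                     label=None, season=1, episode=1) -> DyadInteraction:
    """A minimal labelled interaction with prescribed word counts."""
    text = " ".join(["w"] * words_partner)
    utt = [Utterance(season, episode, 0, partner, text)]
    if words_main:
        utt.append(Utterance(season, episode, 1, main,
                             " ".join(["w"] * words_main)))
    return DyadInteraction(main=main, partner=partner, utterances=utt,
                           words_main=words_main, words_partner=words_partner,
                           seasons={season}, label=label)
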