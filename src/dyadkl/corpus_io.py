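"""Read speaker-attributed script tables and extract dyadic interactions.

A script table is a CSV with one row per spoken line: the speaker's name, the
transcribed text, and (optionally) season / episode identifiers and a running
line index.  From such a table this module extracts *dyadic interactions* — the
joint verbal activity of an unordered pair of speakers — using a sliding window
of length two over consecutive lines within an episode: whenever two adjacent
lines have two distinct speakers, both lines are attributed to that pair.
Interactions can then be volume-filtered (speakers who produce fewer than
``min_words`` words in a season are too thin to characterise distributionally)
and labelled against a registry of significant partners.

Word counting everywhere in the package goes through :func:`tokenize`:
words are maximal runs of alphanumeric characters after lowercasing.
"""

from __future__ import annotations

import json
import re
from collections import OrderedDict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "tokenize",
    "word_count",
    "normalize_speaker",
    "Utterance",
    "Corpus",
    "DyadInteraction",
    "SignificanceRegistry",
    "DEFAULT_SIGNIFICANT_PARTNERS",
    "ScriptConfigError",
    "read_script_table",
    "write_script_table",
    "read_aliases",
    "extract_dyad_interactions",
    "apply_min_word_filter",
    "label_interactions",
    "write_interactions_manifest",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_WS_RE = re.compile(r"\s+")

SIGNIFICANT = "significant"
NON_SIGNIFICANT = "non_significant"


def tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and return maximal alphanumeric runs.

    This single tokenizer governs the ``min_words`` volume filter, the word
    counts reported per dyad, and topic counting, so that all word accounting
    in the package is mutually consistent.
    """
    return _TOKEN_RE.findall(text.lower())


def word_count(text: str) -> int:
    """Number of tokens in ``text`` under the package tokenizer."""
    return len(tokenize(text))


def normalize_speaker(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Trim and collapse whitespace; map through the alias table if given.

    Alias keys are matched case-insensitively (casefold); the canonical form
    stored in the alias table is returned verbatim, so display capitalisation
    is preserved.
    """
    name = _WS_RE.sub(" ", name.strip())
    if aliases:
        canon = aliases.get(name.casefold())
        if canon is not None:
            return canon
    return name


@dataclass(frozen=True)
class Utterance:
    """One spoken line: who said what, and where in the series."""

    season: str | int
    episode: str | int
    line_index: int
    speaker: str
    text: str

    @property
    def uid(self) -> tuple:
        """Identity of the line within the corpus (season, episode, index)."""
        return (self.season, self.episode, self.line_index)


@dataclass
class Corpus:
    """An ordered collection of utterances grouped by (season, episode).

    Utterances must be grouped by episode with strictly increasing
    ``line_index`` within each episode; :func:`read_script_table` produces
    this ordering from row order when no index column is present.
    """

    utterances: list[Utterance]
    skipped_rows: int = 0

    def __post_init__(self) -> None:
        last: dict[tuple, int] = {}
        for u in self.utterances:
            if not u.speaker:
                raise ValueError("utterance with empty speaker name")
            key = (u.season, u.episode)
            if key in last and u.line_index <= last[key]:
                raise ValueError(
                    f"line_index not strictly increasing in episode {key}: "
                    f"{u.line_index} after {last[key]}"
                )
            last[key] = u.line_index

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self) -> Iterator[Utterance]:
        return iter(self.utterances)

    @property
    def speakers(self) -> set[str]:
        return {u.speaker for u in self.utterances}

    def episodes(self) -> "OrderedDict[tuple, list[Utterance]]":
        """Utterances grouped by (season, episode), preserving corpus order."""
        out: OrderedDict[tuple, list[Utterance]] = OrderedDict()
        for u in self.utterances:
            out.setdefault((u.season, u.episode), []).append(u)
        return out


@dataclass
class DyadInteraction:
    """The aggregated verbal activity of one unordered speaker pair.

    ``main`` / ``partner`` are role names: before labelling the assignment is
    alphabetical; :func:`label_interactions` reorders so that the designated
    main character occupies ``main``.
    """

    main: str
    partner: str
    utterances: list[Utterance]
    words_main: int
    words_partner: int
    seasons: set
    label: str | None = None

    def __post_init__(self) -> None:
        if self.main == self.partner:
            raise ValueError(f"dyad with identical speakers: {self.main!r}")
        if self.words_main < 0 or self.words_partner < 0:
            raise ValueError("negative word count")
        pair = {self.main, self.partner}
        for u in self.utterances:
            if u.speaker not in pair:
                raise ValueError(
                    f"utterance by {u.speaker!r} in dyad ({self.main}, {self.partner})"
                )

    @property
    def pair(self) -> frozenset:
        return frozenset((self.main, self.partner))

    @property
    def total_words(self) -> int:
        return self.words_main + self.words_partner

    def swapped(self) -> "DyadInteraction":
        """Return the same interaction with the two roles exchanged."""
        return replace(
            self,
            main=self.partner,
            partner=self.main,
            words_main=self.words_partner,
            words_partner=self.words_main,
        )


#: Significant romantic partners of the four main characters.  Public
#: transcripts credit Mr. Big as "Big"; map other spellings via an alias file.
DEFAULT_SIGNIFICANT_PARTNERS: Mapping[str, tuple[str, ...]] = {
    "Carrie": ("Big", "Aidan", "Jack", "Aleksandr"),
    "Charlotte": ("Trey", "Harry"),
    "Miranda": ("Skipper", "Robert", "Steve"),
    "Samantha": ("James", "Maria", "Richard", "Smith"),
}


class SignificanceRegistry(Mapping[str, frozenset]):
    """Mapping from main character to the set of her significant partners."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset] = {
            m: frozenset(ps) for m, ps in mapping.items()
        }
        mains_cf = {m.casefold() for m in self._map}
        for m, ps in self._map.items():
            for p in ps:
                if p.casefold() in mains_cf:
                    raise ValueError(
                        f"partner {p!r} of {m!r} is also a main character"
                    )

    @classmethod
    def default(cls) -> "SignificanceRegistry":
        return cls(DEFAULT_SIGNIFICANT_PARTNERS)

    @classmethod
    def from_json(cls, path: str | Path) -> "SignificanceRegistry":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({m: sorted(ps) for m, ps in self._map.items()}, fh, indent=2)

    def __getitem__(self, main: str) -> frozenset:
        return self._map[main]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    @property
    def mains(self) -> frozenset:
        return frozenset(self._map)

    def pairs(self) -> list[tuple[str, str]]:
        return [(m, p) for m, ps in sorted(self._map.items()) for p in sorted(ps)]

    @property
    def n_pairs(self) -> int:
        return sum(len(ps) for ps in self._map.values())

    def is_main(self, name: str) -> bool:
        return name.casefold() in {m.casefold() for m in self._map}

    def is_significant(self, main: str, partner: str) -> bool:
        for m, ps in self._map.items():
            if m.casefold() == main.casefold():
                return partner.casefold() in {p.casefold() for p in ps}
        return False


class ScriptConfigError(ValueError):
    """A declared column is missing from the script table."""


def read_aliases(path: str | Path) -> dict[str, str]:
    """Read a two-column (variant, canonical) CSV into a casefolded map."""
    frame = pd.read_csv(path, header=None, names=["variant", "canonical"],
                        dtype=str, keep_default_na=False)
    out: dict[str, str] = {}
    for variant, canonical in frame.itertuples(index=False):
        if variant.casefold() == "variant" and canonical.casefold() == "canonical":
            continue  # tolerate a header row
        out[_WS_RE.sub(" ", variant.strip()).casefold()] = canonical.strip()
    return out


def read_script_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    aliases: Mapping[str, str] | None = None,
    delimiter: str = ",",
    encoding: str = "utf-8",
    default_season: str | int = 1,
    default_episode: str | int = 1,
) -> Corpus:
    """Read a script CSV into a :class:`Corpus`.

    ``column_map`` maps the logical fields ``speaker`` and ``text`` (required)
    and optionally ``season``, ``episode``, ``line_index`` to column names in
    the file.  When no map is given, columns with exactly those names are used
    if present.  Season/episode may instead be supplied per file through
    ``default_season`` / ``default_episode`` (e.g. when encoded in filenames).

    Rows whose speaker field is empty after normalization are skipped and
    counted in :attr:`Corpus.skipped_rows`; rows with empty text are retained
    with the empty string.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, encoding=encoding, dtype=str,
                            keep_default_na=False)
    except OSError as exc:
        raise IOError(f"cannot read script table {path}: {exc}") from exc

    if column_map is not None:
        for logical, column in column_map.items():
            if column not in frame.columns:
                raise ScriptConfigError(
                    f"column {column!r} (mapped from {logical!r}) "
                    f"not present in {path}"
                )
        cmap = dict(column_map)
    else:
        cmap = {k: k for k in ("speaker", "text", "season", "episode", "line_index")
                if k in frame.columns}
    for required in ("speaker", "text"):
        if required not in cmap:
            raise ScriptConfigError(f"no column mapped for required field {required!r}")

    utterances: list[Utterance] = []
    skipped = 0
    counters: dict[tuple, int] = {}
    for row in frame.itertuples(index=False):
        rowd = dict(zip(frame.columns, row))
        speaker = normalize_speaker(str(rowd[cmap["speaker"]]), aliases)
        if not speaker:
            skipped += 1
            continue
        season = rowd[cmap["season"]] if "season" in cmap else default_season
        episode = rowd[cmap["episode"]] if "episode" in cmap else default_episode
        key = (season, episode)
        if "line_index" in cmap:
            idx = int(rowd[cmap["line_index"]])
        else:
            idx = counters.get(key, -1) + 1
        counters[key] = idx
        utterances.append(Utterance(season, episode, idx, speaker,
                                    str(rowd[cmap["text"]])))
    return Corpus(utterances, skipped_rows=skipped)


def write_script_table(corpus: Corpus, path: str | Path,
                       delimiter: str = ",") -> None:
    """Write a corpus back to the canonical five-column script CSV."""
    frame = pd.DataFrame(
        [(u.season, u.episode, u.line_index, u.speaker, u.text)
         for u in corpus],
        columns=["season", "episode", "line_index", "speaker", "text"],
    )
    frame.to_csv(path, sep=delimiter, index=False)


def extract_dyad_interactions(
    corpus: Corpus, granularity: str = "series"
) -> list[DyadInteraction]:
    """Extract dyadic interactions with a length-two sliding window.

    Within each episode, every window of two consecutive utterances with two
    distinct speakers assigns *both* utterances to that unordered pair.  An
    utterance shared by two windows of the same pair (A, B, A patterns) is
    counted once.  All windows of the same pair are aggregated into a single
    :class:`DyadInteraction` — across the whole series when ``granularity`` is
    ``"series"`` (default), or one interaction per (season, pair) when it is
    ``"season"``.  Role assignment is alphabetical at this stage.
    """
    if granularity not in ("series", "season"):
        raise ValueError(f"unknown granularity {granularity!r}")
    buckets: "OrderedDict[tuple, OrderedDict[tuple, Utterance]]" = OrderedDict()
    for (season, _episode), utts in corpus.episodes().items():
        for u, v in zip(utts, utts[1:]):
            if u.speaker == v.speaker:
                continue
            pair = tuple(sorted((u.speaker, v.speaker)))
            key = (season, pair) if granularity == "season" else pair
            bucket = buckets.setdefault(key, OrderedDict())
            for w in (u, v):
                bucket.setdefault(w.uid, w)

    interactions = []
    for key, bucket in buckets.items():
        pair = key[1] if granularity == "season" else key
        a, b = pair
        utts = list(bucket.values())
        wa = sum(word_count(u.text) for u in utts if u.speaker == a)
        wb = sum(word_count(u.text) for u in utts if u.speaker == b)
        interactions.append(
            DyadInteraction(main=a, partner=b, utterances=utts,
                            words_main=wa, words_partner=wb,
                            seasons={u.season for u in utts})
        )
    return interactions


def apply_min_word_filter(
    interactions: Sequence[DyadInteraction],
    corpus: Corpus,
    min_words: int = 100,
    mode: str = "season_total",
) -> list[DyadInteraction]:
    """Drop interactions whose speakers produced too few words.

    In ``season_total`` mode (default), an interaction is removed when either
    speaker's season-total word count — over *all* their utterances in the
    corpus, for any season the interaction spans — is below ``min_words``.  In
    ``per_interaction`` mode the interaction's own per-speaker word counts are
    thresholded instead.  A total of exactly ``min_words`` is kept.
    """
    if min_words < 0:
        raise ValueError("min_words must be >= 0")
    if mode == "per_interaction":
        return [i for i in interactions
                if i.words_main >= min_words and i.words_partner >= min_words]
    if mode != "season_total":
        raise ValueError(f"unknown filter mode {mode!r}")

    totals: dict[tuple, int] = {}
    for u in corpus:
        key = (u.speaker, u.season)
        totals[key] = totals.get(key, 0) + word_count(u.text)

    kept = []
    for i in interactions:
        ok = all(
            totals.get((speaker, season), 0) >= min_words
            for speaker in (i.main, i.partner)
            for season in i.seasons
        )
        if ok:
            kept.append(i)
    return kept


def label_interactions(
    interactions: Sequence[DyadInteraction],
    registry: SignificanceRegistry,
    mains: Iterable[str] | None = None,
) -> tuple[list[DyadInteraction], int]:
    """Label each interaction significant / non-significant; drop the rest.

    An interaction involving a main character and one of her registered
    partners is ``significant``; a main with anyone else is
    ``non_significant`` (including main–main pairs, which the registry
    guarantees are never significant); interactions with no main character
    are excluded.  Returns the labelled interactions (with the main character
    in the ``main`` role) and the number excluded.
    """
    mains_cf = {m.casefold() for m in (mains if mains is not None else registry.mains)}
    labelled: list[DyadInteraction] = []
    excluded = 0
    for i in interactions:
        a_main = i.main.casefold() in mains_cf
        b_main = i.partner.casefold() in mains_cf
        if not a_main and not b_main:
            excluded += 1
            continue
        oriented = i if a_main else i.swapped()
        label = (
            SIGNIFICANT
            if registry.is_significant(oriented.main, oriented.partner)
            else NON_SIGNIFICANT
        )
        labelled.append(replace(oriented, label=label))
    return labelled, excluded


def write_interactions_manifest(
    interactions: Sequence[DyadInteraction], path: str | Path
) -> None:
    """Write one JSON object per dyad (JSON lines) for downstream audit."""
    with open(path, "w", encoding="utf-8") as fh:
        for i in interactions:
            fh.write(json.dumps({
                "main": i.main,
                "partner": i.partner,
                "label": i.label,
                "words_main": i.words_main,
                "words_partner": i.words_partner,
                "seasons": sorted(map(str, i.seasons)),
            }) + "\n")
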