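"""Relative-entropy interaction features and perspective-taking scores.

For a dyad we form three distributions: G, the main character's topic
distribution over everything she says across her interactions; C, the same
for the partner; and GC, the joint distribution of the text both produce
within their mutual interaction.  Relative entropy (Kullback-Leibler
divergence, in bits)

    D_KL(P || Q) = sum_x P(x) * log2(P(x) / Q(x))

measures the coding price of approximating P through Q.  Four divergences
characterise the dyad — D(GC||G), D(GC||C), D(C||G), D(G||C) — and from the
two three-step paths around the G/C/GC triangle we derive the signed
perspective-taking scores

    Persp_G = D(GC||C) + D(C||G) - D(GC||G)
    Persp_C = D(GC||G) + D(G||C) - D(GC||C)

and the redundancy

    rho(G, C) = 1 / | D(GC||G) + D(G||C) - (D(GC||C) + D(C||G)) |

which is large when the two parties' divergence paths to the joint activity
converge.  Each divergence is computed on its own pairwise-aligned support
(see :func:`dyadkl.topic_model.align_support`); a global three-way common
support is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import DyadInteraction
from .topic_model import (
    DisjointSupportError,
    EmptyDistributionError,
    Lexicon,
    TopicDistribution,
    align_support,
    dyad_distribution,
)

__all__ = [
    "SupportMismatchError",
    "AbsoluteContinuityError",
    "kl_divergence",
    "dyad_divergences",
    "perspective_scores",
    "redundancy",
    "DyadFeatures",
    "FeatureExtractor",
    "assemble_features",
    "feature_table",
    "write_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "main", "partner", "label", "total_words",
    "d_gc_g", "d_gc_c", "d_c_g", "d_g_c",
    "persp_g", "persp_c", "rho",
)

_IDENTITY_TOL = 1e-9


class SupportMismatchError(ValueError):
    """kl_divergence called on distributions with different supports."""


class AbsoluteContinuityError(ValueError):
    """Q assigns zero mass where P is positive: D(P||Q) is infinite."""


def kl_divergence(P: TopicDistribution, Q: TopicDistribution) -> float:
    """D_KL(P || Q) in bits over an identical ordered support.

    Both arguments must already be aligned (same category tuple).  Terms with
    P(x) = 0 contribute nothing; Q must be strictly positive wherever P is.
    Floating-point round-off can drive the sum a hair below zero, so the
    result is clamped to >= 0.
    """
    if P.categories != Q.categories:
        raise SupportMismatchError(
            "distributions are not aligned; apply align_support first"
        )
    p, q = P.probs, Q.probs
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise AbsoluteContinuityError(
            "Q has zero mass on part of P's support; D_KL is infinite"
        )
    val = float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))
    return max(val, 0.0)


def _aligned_kl(P: TopicDistribution, Q: TopicDistribution,
                mode: str, alpha: float) -> float:
    Pa, Qa = align_support(P, Q, mode=mode, alpha=alpha)
    return kl_divergence(Pa, Qa)


def dyad_divergences(
    G: TopicDistribution,
    C: TopicDistribution,
    GC: TopicDistribution,
    mode: str = "intersection",
    alpha: float = 0.5,
    global_support: bool = False,
) -> dict[str, float]:
    """The four interaction divergences, each on pairwise-aligned supports.

    With ``global_support=True`` all four are instead computed on the common
    support of G, C and GC simultaneously (sensitivity-analysis variant).
    """
    if global_support:
        common = sorted(set(G.support) & set(C.support) & set(GC.support))
        if not common:
            raise DisjointSupportError("G, C and GC share no support category")
        from .topic_model import _restrict

        Gr, Cr, GCr = (_restrict(d, common, True) for d in (G, C, GC))
        return {
            "d_gc_g": kl_divergence(GCr, Gr),
            "d_gc_c": kl_divergence(GCr, Cr),
            "d_c_g": kl_divergence(Cr, Gr),
            "d_g_c": kl_divergence(Gr, Cr),
        }
    return {
        "d_gc_g": _aligned_kl(GC, G, mode, alpha),
        "d_gc_c": _aligned_kl(GC, C, mode, alpha),
        "d_c_g": _aligned_kl(C, G, mode, alpha),
        "d_g_c": _aligned_kl(G, C, mode, alpha),
    }


def perspective_scores(
    G: TopicDistribution,
    C: TopicDistribution,
    GC: TopicDistribution,
    mode: str = "intersection",
    alpha: float = 0.5,
) -> tuple[float, float]:
    """(Persp_G, Persp_C): signed path differences around the G/C/GC triangle.

    Persp_G compares the C-mediated path to the joint activity with the direct
    one, quantifying how well the main character can see GC through the
    partner's constraints; Persp_C is the mirror image.  Both may be negative.
    By construction Persp_G + Persp_C = D(G||C) + D(C||G).
    """
    d = dyad_divergences(G, C, GC, mode=mode, alpha=alpha)
    persp_g = d["d_gc_c"] + d["d_c_g"] - d["d_gc_g"]
    persp_c = d["d_gc_g"] + d["d_g_c"] - d["d_gc_c"]
    return persp_g, persp_c


def redundancy(
    G: TopicDistribution,
    C: TopicDistribution,
    GC: TopicDistribution,
    epsilon: float = 1e-9,
    mode: str = "intersection",
    alpha: float = 0.5,
) -> tuple[float, bool]:
    """Redundancy rho(G, C) and whether the epsilon floor was hit.

    rho is the reciprocal absolute difference between the two divergence
    paths to GC; it diverges when the paths agree exactly, so the difference
    is floored at ``epsilon`` and the cap is flagged rather than raised, so
    batch extraction never aborts on a degenerate dyad.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = dyad_divergences(G, C, GC, mode=mode, alpha=alpha)
    inner = d["d_gc_g"] + d["d_g_c"] - (d["d_gc_c"] + d["d_c_g"])
    capped = abs(inner) < epsilon
    return 1.0 / max(abs(inner), epsilon), capped


@dataclass
class DyadFeatures:
    """The seven relative-entropy features plus length and label for one dyad."""

    main: str
    partner: str
    label: str | None
    total_words: int
    d_gc_g: float
    d_gc_c: float
    d_c_g: float
    d_g_c: float
    persp_g: float
    persp_c: float
    rho: float
    rho_capped: bool = False

    def __post_init__(self) -> None:
        for name in ("d_gc_g", "d_gc_c", "d_c_g", "d_g_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        identity_gap = abs(
            (self.persp_g + self.persp_c) - (self.d_g_c + self.d_c_g)
        )
        if identity_gap > _IDENTITY_TOL:
            raise ValueError(
                f"perspective-sum identity violated by {identity_gap:.3g}"
            )


class FeatureExtractor:
    """Compute :class:`DyadFeatures` for every dyad of a labelled collection.

    The main and partner global distributions (G, C) are built from each
    speaker's unique utterances across *all* interactions in the collection;
    an utterance attributed to two dyads is counted once.  With
    ``exclude_focal=True``, G and C omit the focal interaction's own
    utterances (leave-one-out variant).
    """

    def __init__(
        self,
        interactions: Sequence[DyadInteraction],
        lexicon: Lexicon,
        *,
        mode: str = "intersection",
        alpha: float = 0.5,
        epsilon: float = 1e-9,
        exclude_focal: bool = False,
    ):
        self.interactions = list(interactions)
        self.lexicon = lexicon
        self.mode = mode
        self.alpha = alpha
        self.epsilon = epsilon
        self.exclude_focal = exclude_focal
        # speaker -> uid -> text, deduplicated across interactions
        self._texts: dict[str, dict[tuple, str]] = {}
        for i in self.interactions:
            for u in i.utterances:
                self._texts.setdefault(u.speaker, {})[u.uid] = u.text
        self._global_cache: dict[str, TopicDistribution] = {}

    def character_global(
        self, speaker: str, exclude: DyadInteraction | None = None
    ) -> TopicDistribution:
        from .topic_model import topic_distribution

        if speaker not in self._texts:
            raise ValueError(f"speaker {speaker!r} appears in no interaction")
        if exclude is None and speaker in self._global_cache:
            return self._global_cache[speaker]
        texts = self._texts[speaker]
        if exclude is not None:
            drop = {u.uid for u in exclude.utterances}
            texts = {uid: t for uid, t in texts.items() if uid not in drop}
            if not texts:
                raise EmptyDistributionError(
                    f"{speaker!r} has no text outside the focal interaction"
                )
        dist = topic_distribution(" ".join(texts.values()), self.lexicon)
        if exclude is None:
            self._global_cache[speaker] = dist
        return dist

    def features_for(self, interaction: DyadInteraction) -> DyadFeatures:
        focal = interaction if self.exclude_focal else None
        try:
            G = self.character_global(interaction.main, exclude=focal)
            C = self.character_global(interaction.partner, exclude=focal)
            GC = dyad_distribution(interaction, self.lexicon)
            d = dyad_divergences(G, C, GC, mode=self.mode, alpha=self.alpha)
            persp_g, persp_c = perspective_scores(G, C, GC, mode=self.mode,
                                                  alpha=self.alpha)
            rho, capped = redundancy(G, C, GC, epsilon=self.epsilon,
                                     mode=self.mode, alpha=self.alpha)
        except (EmptyDistributionError, DisjointSupportError) as exc:
            raise type(exc)(
                f"dyad ({interaction.main}, {interaction.partner}): {exc}"
            ) from exc
        return DyadFeatures(
            main=interaction.main,
            partner=interaction.partner,
            label=interaction.label,
            total_words=interaction.total_words,
            persp_g=persp_g,
            persp_c=persp_c,
            rho=rho,
            rho_capped=capped,
            **d,
        )

    def table(self) -> pd.DataFrame:
        rows = [self.features_for(i) for i in self.interactions]
        frame = pd.DataFrame([vars(r) for r in rows])
        return frame[list(FEATURE_COLUMNS) + ["rho_capped"]]


def assemble_features(
    interaction: DyadInteraction,
    interactions: Sequence[DyadInteraction],
    lexicon: Lexicon,
    **kwargs,
) -> DyadFeatures:
    """One-shot feature computation for a single dyad within its collection."""
    return FeatureExtractor(interactions, lexicon, **kwargs).features_for(interaction)


def feature_table(
    interactions: Sequence[DyadInteraction], lexicon: Lexicon, **kwargs
) -> pd.DataFrame:
    """Feature rows for every interaction in the collection."""
    return FeatureExtractor(interactions, lexicon, **kwargs).table()


def write_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical 11-column TSV feature table."""
    frame[list(FEATURE_COLUMNS)].to_csv(path, sep="\t", index=False)
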