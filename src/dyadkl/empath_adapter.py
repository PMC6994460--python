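"""Optional Empath backend behind the topic-distribution interface.

Empath's 194 categories are built from embedding-expanded seed lexicons and
are not reproducible from first principles, so the package default is the
transparent counter in :mod:`dyadkl.topic_model`.  When the ``empath``
package is installed, this adapter exposes its analyzer through the same
:class:`~dyadkl.topic_model.TopicDistribution` surface.
"""

from __future__ import annotations

import numpy as np

from .corpus_io import word_count
from .topic_model import EmptyDistributionError, TopicDistribution

__all__ = ["empath_topic_distribution"]


def empath_topic_distribution(text: str, analyzer=None) -> TopicDistribution:
    """Topic distribution of ``text`` from Empath raw category counts.

    ``analyzer`` is an ``empath.Empath`` instance (constructed on demand when
    omitted).  Zero-hit categories are dropped and counts normalised, exactly
    as the bundled counter does.
    """
    if analyzer is None:
        try:
            from empath import Empath
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the 'empath' package is not installed; "
                "install dyadkl[empath] or pass an analyzer"
            ) from exc
        analyzer = Empath()
    raw = analyzer.analyze(text, normalize=False) or {}
    cats = tuple(sorted(c for c, v in raw.items() if v > 0))
    if not cats:
        raise EmptyDistributionError(
            f"no Empath hit in text of {word_count(text)} words"
        )
    counts = np.array([raw[c] for c in cats], dtype=float)
    return TopicDistribution(cats, counts / counts.sum(), counts=counts)
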