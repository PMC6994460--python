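"""Length-matched merging of non-significant partners.

Interaction length is a strong, trivial cue for relationship significance:
people talk far more with a spouse than with a cashier, and longer texts also
mechanically change the support of lexicon-based topic distributions.  To test
the relative-entropy features on their own merits, the non-significant
partners of each main character are merged into pseudo-characters whose total
interaction lengths roughly match the significant interactions, producing a
matched control group.

The matching is greedy first-crossing: the significant interactions define
length targets (in total words, in order); non-significant partners are
consumed in order, accumulating into a group until its total first reaches the
current target; targets cycle until every partner is assigned.  The trailing
group may be under-filled and is kept, flagged when it reaches less than half
its target.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import NON_SIGNIFICANT, SIGNIFICANT, DyadInteraction

__all__ = [
    "NoSignificantInteractionError",
    "MergeGroup",
    "MergePlan",
    "merge_nonsignificant_partners",
    "balance_interactions",
]


class NoSignificantInteractionError(ValueError):
    """A main character has no significant interaction to define targets."""


@dataclass
class MergeGroup:
    """One merged pseudo-character: which partners, against which target."""

    merged_name: str
    target_partner: str
    target_length: int
    members: list[str]
    achieved_length: int
    underfilled: bool

    def __post_init__(self) -> None:
        if self.achieved_length < 0:
            raise ValueError("negative achieved_length")


@dataclass
class MergePlan:
    """Audit record of one main character's merge."""

    main: str
    order: str
    groups: list[MergeGroup]
    leftover: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            dup = seen & set(g.members)
            if dup:
                raise ValueError(f"partners assigned twice: {sorted(dup)}")
            seen |= set(g.members)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "main": self.main,
                "order": self.order,
                "groups": [vars(g) for g in self.groups],
                "leftover": self.leftover,
            }, fh, indent=2)


def _merge_group(main: str, members: Sequence[DyadInteraction],
                 merged_name: str) -> DyadInteraction:
    utterances = []
    for m in members:
        for u in m.utterances:
            utterances.append(
                u if u.speaker == main else replace(u, speaker=merged_name)
            )
    return DyadInteraction(
        main=main,
        partner=merged_name,
        utterances=utterances,
        words_main=sum(m.words_main for m in members),
        words_partner=sum(m.words_partner for m in members),
        seasons=set().union(*(m.seasons for m in members)),
        label=NON_SIGNIFICANT,
    )


def merge_nonsignificant_partners(
    main: str,
    interactions: Sequence[DyadInteraction],
    order: str = "script",
) -> tuple[MergePlan, list[DyadInteraction]]:
    """Merge one main character's non-significant partners into length-matched
    pseudo-characters.

    ``order`` is the consumption order of the non-significant partners:
    ``"script"`` (order of first appearance, default) or
    ``"descending_length"``.  Total word count is conserved: the merged
    interactions hold exactly the words of the partners they consumed.
    """
    if order not in ("script", "descending_length"):
        raise ValueError(f"unknown order {order!r}")
    mine = [i for i in interactions if i.main == main]
    sig = [i for i in mine if i.label == SIGNIFICANT]
    if not sig:
        raise NoSignificantInteractionError(
            f"{main!r} has no significant interaction; no length targets"
        )
    nonsig = [i for i in mine if i.label == NON_SIGNIFICANT]
    if order == "descending_length":
        nonsig = sorted(nonsig, key=lambda i: -i.total_words)

    targets = [(i.partner, i.total_words) for i in sig]
    queue = deque(nonsig)
    groups: list[MergeGroup] = []
    merged: list[DyadInteraction] = []
    t = 0
    while queue:
        target_partner, target_len = targets[t % len(targets)]
        t += 1
        members: list[DyadInteraction] = []
        achieved = 0
        while queue and achieved < target_len:
            nxt = queue.popleft()
            members.append(nxt)
            achieved += nxt.total_words
        merged_name = f"N*{len(groups) + 1} ({main})"
        groups.append(MergeGroup(
            merged_name=merged_name,
            target_partner=target_partner,
            target_length=target_len,
            members=[m.partner for m in members],
            achieved_length=achieved,
            underfilled=achieved < 0.5 * target_len,
        ))
        merged.append(_merge_group(main, members, merged_name))
    return MergePlan(main=main, order=order, groups=groups, leftover=[]), merged


def balance_interactions(
    interactions: Sequence[DyadInteraction],
    mains: Iterable[str] | None = None,
    order: str = "script",
) -> tuple[dict[str, MergePlan], list[DyadInteraction]]:
    """Apply the merge per main character and return the balanced collection.

    The result holds every significant interaction unchanged plus the merged
    non-significant pseudo-characters, in main-character order.
    """
    if mains is None:
        mains = sorted({i.main for i in interactions})
    plans: dict[str, MergePlan] = {}
    balanced: list[DyadInteraction] = []
    for main in mains:
        plan, merged = merge_nonsignificant_partners(main, interactions, order)
        plans[main] = plan
        balanced.extend(i for i in interactions
                        if i.main == main and i.label == SIGNIFICANT)
        balanced.extend(merged)
    return plans, balanced
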