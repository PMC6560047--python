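"""Two overlapping ring-structured associative memories and their pair taxonomy.

Seven abstract stimuli are arranged on a ring; each stimulus is associated
with its two ring neighbors, giving seven undirected links per memory. A
second, context-dependent memory uses the same stimuli but exchanges the
ring positions of two of them, so four links differ between the memories
while three are shared. Every unordered stimulus pair is classified, per
context, into one of four categories from which all downstream univariate
contrasts and model dissimilarity matrices are built:

- ``associated_both``      — direct neighbors in both memories,
- ``associated_current_only`` — neighbors in the cued memory only,
- ``hidden``               — not neighbors in the cued memory but neighbors
                             in the alternative memory (the interference
                             condition),
- ``unassociated_both``    — neighbors in neither memory (the control
                             condition).

Pairs containing a stimulus whose ring position changed between the two
memories are flagged *unstable*: these are the trials on which the two
memories make conflicting relational predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Tuple

import pandas as pd

CONTEXTS = ("memory1", "memory2")

Pair = Tuple[int, int]


def canonical_pair(i: int, j: int) -> Pair:
    """Unordered pair as (min, max); presentation order is a trial attribute."""
    return (i, j) if i <= j else (j, i)


class PairCategory(str, Enum):
    ASSOCIATED_BOTH = "associated_both"
    ASSOCIATED_CURRENT_ONLY = "associated_current_only"
    HIDDEN = "hidden"
    UNASSOCIATED_BOTH = "unassociated_both"


@dataclass(frozen=True)
class RingStructure:
    """A cyclic arrangement of stimuli defining one memory's associations."""

    order: Tuple[int, ...]
    context: str

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ring order must contain distinct stimuli")
        if len(self.order) < 3:
            raise ValueError("a ring needs at least 3 stimuli")

    @property
    def stimuli(self) -> frozenset:
        return frozenset(self.order)

    @property
    def n(self) -> int:
        return len(self.order)

    @property
    def links(self) -> frozenset:
        n = self.n
        return frozenset(
            canonical_pair(self.order[k], self.order[(k + 1) % n]) for k in range(n)
        )

    def position(self, stimulus: int) -> int:
        try:
            return self.order.index(stimulus)
        except ValueError:
            raise KeyError(f"stimulus {stimulus} not in ring") from None

    def neighbors(self, stimulus: int) -> frozenset:
        k = self.position(stimulus)
        n = self.n
        return frozenset({self.order[(k - 1) % n], self.order[(k + 1) % n]})


def build_memory_rings(
    base_order: Iterable[int], swap: Pair
) -> Tuple[RingStructure, RingStructure]:
    """Build the two memories: base ring and the ring with ``swap`` exchanged.

    ``swap`` names the two stimuli whose ring *positions* are exchanged in
    the second memory; for a 7-ring this leaves 3 links shared and 4 links
    different between the memories.
    """
    order = tuple(base_order)
    if len(set(order)) != len(order):
        raise ValueError("base_order must be a permutation of distinct stimuli")
    a, b = swap
    if a == b:
        raise ValueError("swap stimuli must be distinct")
    if a not in order or b not in order:
        raise ValueError("swap stimuli must be members of the ring")
    ia, ib = order.index(a), order.index(b)
    swapped = list(order)
    swapped[ia], swapped[ib] = swapped[ib], swapped[ia]
    return (
        RingStructure(order=order, context=CONTEXTS[0]),
        RingStructure(order=tuple(swapped), context=CONTEXTS[1]),
    )


def ring_distance(ring: RingStructure, i: int, j: int) -> int:
    """Shortest path length between two stimuli along the ring (0..n//2)."""
    d = abs(ring.position(i) - ring.position(j))
    return min(d, ring.n - d)


def is_unstable_pair(pair: Pair, swap: Pair) -> bool:
    """True iff the pair contains a stimulus whose ring position was swapped."""
    return pair[0] in swap or pair[1] in swap


@dataclass
class LinkTaxonomy:
    """Per-context classification of all unordered non-repeating pairs.

    ``categories[context][pair]`` maps each canonical pair to its
    :class:`PairCategory`; ``unstable`` is the set of pairs containing a
    swapped stimulus. Repeating pairs (i, i) are deliberately outside the
    taxonomy — they are modeled as a separate nuisance class downstream.
    """

    ring1: RingStructure
    ring2: RingStructure
    categories: dict = field(repr=False)
    unstable: frozenset = frozenset()
    swapped: Tuple[int, ...] = ()

    @property
    def stimuli(self) -> Tuple[int, ...]:
        return tuple(sorted(self.ring1.stimuli))

    @property
    def all_pairs(self) -> Tuple[Pair, ...]:
        return tuple(combinations(self.stimuli, 2))

    def ring(self, context: str) -> RingStructure:
        if context == self.ring1.context:
            return self.ring1
        if context == self.ring2.context:
            return self.ring2
        raise KeyError(f"unknown context {context!r}")

    def other_ring(self, context: str) -> RingStructure:
        return self.ring2 if context == self.ring1.context else self.ring1

    def category_of(self, pair: Pair, context: str) -> PairCategory:
        return self.categories[context][canonical_pair(*pair)]

    def pairs_in(self, category: PairCategory, context: str) -> frozenset:
        return frozenset(
            p for p, c in self.categories[context].items() if c == category
        )

    def stable_pairs(self) -> frozenset:
        return frozenset(p for p in self.all_pairs if p not in self.unstable)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair in self.all_pairs:
            rows.append(
                {
                    "pair": f"{pair[0]}-{pair[1]}",
                    "category_memory1": self.categories[CONTEXTS[0]][pair].value,
                    "category_memory2": self.categories[CONTEXTS[1]][pair].value,
                    "unstable": pair in self.unstable,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def link_taxonomy(ring1: RingStructure, ring2: RingStructure) -> LinkTaxonomy:
    """Classify all 21 unordered pairs per context and flag unstable pairs.

    The rings must contain the same stimuli and be positionally aligned
    (ring2 built from ring1's sequence with some positions exchanged); the
    swapped stimuli are read off as the positions where the two order
    sequences differ.
    """
    if ring1.stimuli != ring2.stimuli:
        raise ValueError("rings must share the same stimulus set")
    links1, links2 = ring1.links, ring2.links
    swapped = tuple(
        s1 for s1, s2 in zip(ring1.order, ring2.order) if s1 != s2
    )
    categories = {}
    for context, own, other in (
        (ring1.context, links1, links2),
        (ring2.context, links2, links1),
    ):
        mapping = {}
        for pair in combinations(sorted(ring1.stimuli), 2):
            in_own, in_other = pair in own, pair in other
            if in_own and in_other:
                cat = PairCategory.ASSOCIATED_BOTH
            elif in_own:
                cat = PairCategory.ASSOCIATED_CURRENT_ONLY
            elif in_other:
                cat = PairCategory.HIDDEN
            else:
                cat = PairCategory.UNASSOCIATED_BOTH
            mapping[pair] = cat
        categories[context] = mapping
    unstable = frozenset(
        p
        for p in combinations(sorted(ring1.stimuli), 2)
        if p[0] in swapped or p[1] in swapped
    )
    return LinkTaxonomy(
        ring1=ring1,
        ring2=ring2,
        categories=categories,
        unstable=unstable,
        swapped=swapped,
    )
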