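"""Pairwise event costs between orthoblocks: split, duplication, deletion.

Each cost counts events of one type needed to explain the difference
between two orthoblocks, as a proxy for evolutionary distance:

* split cost      c_s(O, O') = | |Rel(O,O')| − |Rel(O',O)| |
* duplication     c_u(O, O') = |Dif(O,O')| + |Dif(O',O)|
* deletion        c_d(O, O') = |Gene(O) △ Gene(O')|

When one side is the reference operon R (a single block, no duplicated
genes) and the other side uses only genes of R, each cost collapses to a
closed form: c_s = |O| − 1, c_u = |Dup(O)|, c_d = |Gene(R)| − |Gene(O)|.
The general pairwise forms are canonical; the ``*_ref`` forms exist for
speed and are cross-validated against them in the test suite.

All costs are symmetric non-negative integers; events are weighted equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .model import (
    BlockLike,
    Orthoblock,
    ReferenceOperon,
    as_orthoblock,
    dif,
    dup_set,
    gene_set,
    rel,
)

Mode = Literal["with_duplication", "deletion_split_only"]

WITH_DUPLICATION: Mode = "with_duplication"
DELETION_SPLIT_ONLY: Mode = "deletion_split_only"


@dataclass(frozen=True)
class EventCosts:
    """Decomposed event counts for one orthoblock/reference comparison.

    ``total`` follows ``mode``: deletion + split + duplication when
    duplications are included, deletion + split otherwise (duplication is
    still reported either way — it is counted but never optimized over).
    """

    deletion: int
    split: int
    duplication: int
    mode: Mode = WITH_DUPLICATION

    def __post_init__(self):
        for name in ("deletion", "split", "duplication"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} cost must be a non-negative integer, got {v!r}")
        if self.mode not in (WITH_DUPLICATION, DELETION_SPLIT_ONLY):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def total(self) -> int:
        if self.mode == WITH_DUPLICATION:
            return self.deletion + self.split + self.duplication
        return self.deletion + self.split


# ---------------------------------------------------------------------------
# general pairwise forms (symmetric)

def split_cost(o: BlockLike, o_prime: BlockLike) -> int:
    """Absolute difference in the number of relevant gene blocks."""
    return abs(len(rel(o, o_prime)) - len(rel(o_prime, o)))


def duplication_cost(o: BlockLike, o_prime: BlockLike) -> int:
    """|Dif(o, o')| + |Dif(o', o)|."""
    return len(dif(o, o_prime)) + len(dif(o_prime, o))


def deletion_cost(o: BlockLike, o_prime: BlockLike) -> int:
    """Cardinality of the symmetric difference of the two gene sets."""
    return len(gene_set(o) ^ gene_set(o_prime))


# ---------------------------------------------------------------------------
# reference-simplified closed forms

def _require_subset(r: ReferenceOperon, o: BlockLike, what: str) -> None:
    extra = sorted(gene_set(o) - r.gene_set())
    if extra:
        raise ValueError(
            f"{what} requires Gene(O) ⊆ Gene(R); genes outside the reference "
            f"universe: {', '.join(extra)}"
        )


def split_cost_ref(r: ReferenceOperon, o: Orthoblock) -> int:
    """Simplified split cost against the reference: number of blocks minus one.

    An empty orthoblock costs 0 splits by convention, matching the general
    form (both Rel collections are then empty).
    """
    _require_subset(r, o, "split_cost_ref")
    o = as_orthoblock(o)
    return max(len(o.blocks) - 1, 0)


def duplication_cost_ref(r: ReferenceOperon, o: Orthoblock) -> int:
    """Simplified duplication cost against the reference: |Dup(O)|."""
    if dup_set(r):
        raise ValueError(
            "duplication_cost_ref requires Dup(R) = ∅ (the reference block has no duplicates)"
        )
    _require_subset(r, o, "duplication_cost_ref")
    return len(dup_set(o))


def deletion_cost_ref(r: ReferenceOperon, o: Orthoblock) -> int:
    """Simplified deletion cost against the reference: |Gene(R)| − |Gene(O)|."""
    _require_subset(r, o, "deletion_cost_ref")
    return len(r.gene_set()) - len(gene_set(o))


def total_cost(r: ReferenceOperon, o: Orthoblock, mode: Mode = WITH_DUPLICATION) -> EventCosts:
    """Combined event cost of an orthoblock against the reference operon.

    Components come from the reference-simplified forms; ``mode`` selects
    whether duplications enter the total.
    """
    o = as_orthoblock(o)
    return EventCosts(
        deletion=deletion_cost_ref(r, o),
        split=split_cost_ref(r, o),
        duplication=duplication_cost_ref(r, o),
        mode=mode,
    )
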