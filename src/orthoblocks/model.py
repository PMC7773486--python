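"""Multiset data model for gene blocks and orthoblocks.

A *gene block* is a non-empty multiset of gene identifiers drawn from the
gene set of a reference operon; a gene present more than once in a block is
a *duplicated* gene.  An *orthoblock* is the (possibly empty) collection of
gene blocks found in one target genome that are homologous to the reference
operon.  All event costs are defined in terms of four set-valued operators
on these objects:

``gene_set(x)``
    genes present at least once.
``dup_set(x)``
    genes present at least twice in some block.
``rel(o, o')``
    the blocks of ``o`` restricted to genes present in ``o'`` (empty
    restrictions are dropped) — the *relevant* gene blocks.
``dif(o, o')``
    genes duplicated in ``o`` that occur in ``o'`` but are not duplicated
    there.

Blocks compare as multisets; the left-to-right gene order seen on input is
retained for display only and never affects any operator or cost.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

logger = logging.getLogger("orthoblocks")

#: gene identifiers are bare tokens; comparison is exact, case-sensitive
TOKEN_RE = re.compile(r"[A-Za-z0-9_.-]+\Z")


def _check_token(tok: str) -> str:
    if not isinstance(tok, str) or not TOKEN_RE.match(tok):
        raise ValueError(f"invalid gene identifier {tok!r}: tokens must match [A-Za-z0-9_.-]+")
    return tok


class GeneBlock:
    """A non-empty multiset of gene identifiers with per-gene multiplicity.

    Parameters
    ----------
    genes:
        Gene occurrences in chromosomal order; a gene listed twice has
        multiplicity two.  Equality is multiset equality — order is kept
        only for round-tripping input files.
    """

    __slots__ = ("_order", "_counts")

    def __init__(self, genes: Iterable[str]):
        order = tuple(_check_token(g) for g in genes)
        if not order:
            raise ValueError("a gene block must contain at least one gene")
        counts = Counter(order)
        for g, lam in counts.items():
            if lam > 2:
                logger.warning(
                    "gene %r occurs %d times in block %s; blocks are expected to carry "
                    "at most one extra copy per gene (it still counts once toward Dup)",
                    g, lam, ",".join(order),
                )
        self._order = order
        self._counts = dict(counts)

    @classmethod
    def from_multiplicities(cls, multiplicities: Mapping[str, int]) -> "GeneBlock":
        """Build a block from a gene → multiplicity map (order: sorted genes, copies adjacent)."""
        occ: list[str] = []
        for g in sorted(multiplicities):
            lam = multiplicities[g]
            if lam < 1:
                raise ValueError(f"multiplicity of {g!r} must be >= 1, got {lam}")
            occ.extend([g] * lam)
        return cls(occ)

    @property
    def multiplicities(self) -> dict[str, int]:
        return dict(self._counts)

    @property
    def display_order(self) -> tuple[str, ...]:
        return self._order

    @property
    def size(self) -> int:
        """Size(B) = sum of multiplicities."""
        return len(self._order)

    def gene_set(self) -> frozenset[str]:
        """Gene(B) = genes with multiplicity >= 1."""
        return frozenset(self._counts)

    def dup_set(self) -> frozenset[str]:
        """Dup(B) = genes with multiplicity >= 2."""
        return frozenset(g for g, lam in self._counts.items() if lam >= 2)

    def restrict(self, genes: Iterable[str]) -> "GeneBlock | None":
        """Return B ∩ genes keeping multiplicities, or None if nothing survives."""
        keep = set(genes)
        surviving = [g for g in self._order if g in keep]
        return GeneBlock(surviving) if surviving else None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneBlock):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"GeneBlock({','.join(self._order)})"


@dataclass
class Orthoblock:
    """A collection of gene blocks belonging to one genome.

    May be empty (the orthoblock was lost entirely).  ``well_formed`` is
    reported, not enforced: solver output may legitimately consist of
    singleton blocks only.
    """

    genome_id: str = "genome"
    blocks: list[GeneBlock] = field(default_factory=list)

    @property
    def well_formed(self) -> bool:
        """True if empty or at least one block has size >= 2."""
        return not self.blocks or any(b.size >= 2 for b in self.blocks)

    def gene_set(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.blocks:
            out |= b.gene_set()
        return frozenset(out)

    def dup_set(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.blocks:
            out |= b.dup_set()
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ReferenceOperon:
    """An ordered set of unique gene identifiers: the gene universe G and reference block R."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        _check_token(self.name)
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError(f"reference operon {self.name!r} has no genes")
        seen = Counter(self.genes)
        dups = sorted(g for g, k in seen.items() if k > 1)
        if dups:
            raise ValueError(
                f"reference operon {self.name!r} lists duplicate genes: {', '.join(dups)}"
            )
        for g in self.genes:
            _check_token(g)

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def as_block(self) -> GeneBlock:
        return GeneBlock(self.genes)

    def as_orthoblock(self) -> Orthoblock:
        """The reference viewed as a single-block orthoblock (no duplicated genes)."""
        return Orthoblock(genome_id=self.name, blocks=[self.as_block()])

    def __len__(self) -> int:
        return len(self.genes)


BlockLike = GeneBlock | Orthoblock | ReferenceOperon


def as_orthoblock(x: BlockLike) -> Orthoblock:
    """Coerce a block or reference operon to a one-block orthoblock (identity on orthoblocks)."""
    if isinstance(x, Orthoblock):
        return x
    if isinstance(x, ReferenceOperon):
        return x.as_orthoblock()
    if isinstance(x, GeneBlock):
        return Orthoblock(blocks=[x])
    raise TypeError(f"expected GeneBlock, Orthoblock or ReferenceOperon, got {type(x).__name__}")


def gene_set(x: BlockLike) -> frozenset[str]:
    """Gene(x): genes present at least once (union over blocks for an orthoblock)."""
    return x.gene_set()


def dup_set(x: BlockLike) -> frozenset[str]:
    """Dup(x): genes present at least twice in some block (union over blocks)."""
    if isinstance(x, ReferenceOperon):
        return frozenset()
    return x.dup_set()


def rel(o: BlockLike, o_prime: BlockLike) -> list[GeneBlock]:
    """Relevant gene blocks of ``o`` with respect to ``o_prime``.

    Each block of ``o`` is restricted to the genes of ``o_prime`` (keeping
    multiplicities of the surviving genes); blocks whose restriction is
    empty are dropped.  Returned as a list: two distinct input blocks with
    identical restrictions count twice, since the split cost counts block
    instances.
    """
    shared = gene_set(o_prime)
    out: list[GeneBlock] = []
    for b in as_orthoblock(o).blocks:
        r = b.restrict(shared)
        if r is not None:
            out.append(r)
    return out


def dif(o: BlockLike, o_prime: BlockLike) -> frozenset[str]:
    """Dif(o, o') = (Dup(o) ∩ Gene(o')) \\ Dup(o')."""
    return (dup_set(o) & gene_set(o_prime)) - dup_set(o_prime)
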