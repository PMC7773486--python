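"""Simulate orthoblock evolution with known event counts.

Starting from the reference operon as a single block, the generator applies
a fixed order of events — deletions of distinct genes, then tandem
duplications (λ: 1 → 2) of distinct surviving genes, then splits at
distinct boundaries of the resulting gene order — so that the event counts
requested in the configuration are exactly the event costs recovered by
the cost functions on the output.  Distinctness plus this ordering is the
minimal generative model under which the costs count events exactly: a
second deletion of the same gene or a split at an already-cut boundary
would be invisible to the multiset model.  Splits are never placed between
a gene and its tandem copy, so each duplication stays within one block.

A companion generator builds solver test beds: the blocks of one simulated
true orthoblock plus a configurable number of decoy candidates (random
non-empty subsets of the reference gene set with geometric-ish sizes).
Everything is driven by one seeded pseudo-random stream, so a seed fully
determines the output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .costs import WITH_DUPLICATION, EventCosts
from .model import GeneBlock, Orthoblock, ReferenceOperon
from .solvers import Candidate, RGBInstance


@dataclass(frozen=True)
class SimulationConfig:
    """Event counts and seed for one simulated orthoblock.

    ``n_deletions`` must leave at least one gene, and ``n_splits`` at most
    the number of internal boundaries between distinct surviving genes
    (``n_genes − n_deletions − 1``).
    """

    n_genes: int
    n_deletions: int = 0
    n_splits: int = 0
    n_duplications: int = 0
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {self.n_genes}")
        for name in ("n_deletions", "n_splits", "n_duplications", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_deletions >= self.n_genes:
            raise ValueError(
                f"n_deletions={self.n_deletions} must be < n_genes={self.n_genes} "
                "(at least one gene must survive)"
            )
        surviving = self.n_genes - self.n_deletions
        if self.n_splits > surviving - 1:
            raise ValueError(
                f"n_splits={self.n_splits} exceeds the {surviving - 1} internal "
                f"boundaries left after {self.n_deletions} deletions"
            )
        if self.n_duplications > surviving:
            raise ValueError(
                f"n_duplications={self.n_duplications} exceeds the {surviving} surviving genes"
            )


def reference_from_config(config: SimulationConfig, name: str = "sim") -> ReferenceOperon:
    """A generic reference operon g1..gN matching the configured gene count."""
    return ReferenceOperon(name=name, genes=tuple(f"g{i}" for i in range(1, config.n_genes + 1)))


def _check_reference(reference: ReferenceOperon, config: SimulationConfig) -> None:
    if len(reference) != config.n_genes:
        raise ValueError(
            f"reference operon has {len(reference)} genes but the configuration "
            f"says n_genes={config.n_genes}"
        )


def _simulate(
    reference: ReferenceOperon, config: SimulationConfig, rng: random.Random
) -> tuple[Orthoblock, EventCosts]:
    genes = list(reference.genes)
    deleted = set(rng.sample(genes, config.n_deletions))
    surviving = [g for g in genes if g not in deleted]
    duplicated = set(rng.sample(surviving, config.n_duplications))

    # lay out the surviving gene order, tandem copies adjacent
    order: list[str] = []
    for g in surviving:
        order.append(g)
        if g in duplicated:
            order.append(g)

    # cut only between distinct neighbours: a tandem pair is never separated
    boundaries = [i for i in range(1, len(order)) if order[i - 1] != order[i]]
    cuts = sorted(rng.sample(boundaries, config.n_splits))

    blocks: list[Orthoblock] = []
    segments = []
    prev = 0
    for cut in cuts + [len(order)]:
        segments.append(order[prev:cut])
        prev = cut
    blocks = [GeneBlock(seg) for seg in segments]
    ortho = Orthoblock(genome_id=f"sim_seed{config.seed}", blocks=blocks)
    truth = EventCosts(
        deletion=config.n_deletions,
        split=config.n_splits,
        duplication=config.n_duplications,
        mode=WITH_DUPLICATION,
    )
    return ortho, truth


def simulate_orthoblock(
    reference: ReferenceOperon, config: SimulationConfig
) -> tuple[Orthoblock, EventCosts]:
    """Apply the configured events to the reference; return the orthoblock and ground truth.

    The returned :class:`EventCosts` equal, by construction, the costs the
    cost functions recover from the output.
    """
    _check_reference(reference, config)
    rng = random.Random(config.seed)
    return _simulate(reference, config, rng)


def _decoy(rng: random.Random, genes: list[str]) -> frozenset[str]:
    size = 1
    while size < len(genes) and rng.random() < 0.5:
        size += 1
    return frozenset(rng.sample(genes, size))


def simulate_instance(
    reference: ReferenceOperon, config: SimulationConfig
) -> tuple[RGBInstance, EventCosts]:
    """Build an RGB instance: one simulated true orthoblock plus decoy candidates.

    Decoy candidates are random non-empty subsets of the reference gene set
    (block form: genes in reference order, no duplications).  The true
    blocks come first and keep their source blocks; decoys follow.
    """
    _check_reference(reference, config)
    rng = random.Random(config.seed)
    ortho, truth = _simulate(reference, config, rng)
    genes = list(reference.genes)
    candidates = [
        Candidate(index=i, genes=b.gene_set(), block=b)
        for i, b in enumerate(ortho.blocks)
    ]
    for k in range(config.n_decoys):
        decoy = _decoy(rng, genes)
        block = GeneBlock([g for g in genes if g in decoy])
        candidates.append(
            Candidate(index=len(ortho.blocks) + k, genes=decoy, block=block)
        )
    instance = RGBInstance(universe=reference.gene_set(), candidates=tuple(candidates))
    return instance, truth
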