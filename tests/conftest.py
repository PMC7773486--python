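import random

import pytest
from hypothesis import settings

import orthoblocks as ob

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def block(genes):
    """GeneBlock from an occurrence string/iterable, e.g. block('abb')."""
    return ob.GeneBlock(list(genes))


def ortho(*parts, genome_id="g"):
    """Orthoblock from occurrence strings, e.g. ortho('ab', 'def')."""
    return ob.Orthoblock(genome_id=genome_id, blocks=[block(p) for p in parts])


@pytest.fixture
def ref7():
    """Seven-gene reference operon R = (a,b,c,d,e,f,g)."""
    return ob.ReferenceOperon("ref7", tuple("abcdefg"))


@pytest.fixture
def ref5():
    """Five-gene reference operon R = (a,b,c,d,e)."""
    return ob.ReferenceOperon("ref5", tuple("abcde"))


def random_instance(rng: random.Random, max_genes=12, max_candidates=10,
                    cover_universe=False) -> ob.RGBInstance:
    """A random RGB instance: |S| <= max_genes, |C| <= max_candidates.

    Candidate sizes are skewed small so covers are non-trivial; with
    ``cover_universe`` the union of candidates is patched to equal S.
    """
    n = rng.randint(3, max_genes)
    genes = [f"g{i}" for i in range(n)]
    m = rng.randint(1, max_candidates)
    sets = []
    for _ in range(m):
        size = rng.randint(1, max(2, n // 2))
        sets.append(frozenset(rng.sample(genes, size)))
    if cover_universe:
        covered = set().union(*sets)
        for g in set(genes) - covered:
            i = rng.randrange(m)
            sets[i] = sets[i] | {g}
    return ob.RGBInstance.from_sets(genes, sets)


def random_reference_and_orthoblock(rng: random.Random, max_genes=10):
    """A random (reference, orthoblock) pair satisfying the closed-form preconditions.

    The orthoblock's genes are a (possibly empty) subset of the reference's,
    partitioned into contiguous blocks with multiplicities in {1, 2}.
    """
    n = rng.randint(2, max_genes)
    genes = [f"g{i}" for i in range(n)]
    reference = ob.ReferenceOperon("r", tuple(genes))
    k = rng.randint(0, n)
    chosen = sorted(rng.sample(genes, k), key=genes.index)
    if not chosen:
        return reference, ob.Orthoblock(genome_id="t", blocks=[])
    n_blocks = rng.randint(1, len(chosen))
    cuts = sorted(rng.sample(range(1, len(chosen)), n_blocks - 1)) if n_blocks > 1 else []
    blocks = []
    prev = 0
    for cut in cuts + [len(chosen)]:
        occ = []
        for g in chosen[prev:cut]:
            occ.append(g)
            if rng.random() < 0.3:
                occ.append(g)  # tandem duplicate
        blocks.append(ob.GeneBlock(occ))
        prev = cut
    return reference, ob.Orthoblock(genome_id="t", blocks=blocks)
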