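"""Solvers for the Relevant-Gene-Block (RGB) problem.

Given the reference gene set S and a collection C of candidate gene sets
(one per candidate block in the target genome, each a subset of S), the
RGB problem asks for a sub-collection C' minimizing

    f(S, C') = |S| − |∪C'| + |C'|

i.e. deletions (|S| − |∪C'|) plus blocks (|C'|); the biological split cost
is |C'| − 1, so f exceeds the deletion+split cost by the constant 1
whenever C' is non-empty.  Both numbers are reported on every solution.

The problem is NP-hard and APX-hard by reduction from Minimum Set Cover
(MSC), and conversely an RGB optimum has the cost of a minimum set cover.
Three solvers are provided:

``greedy_rgb``
    polynomial-time greedy cover of ∪C; guarantees
    f(S, C') ≤ (1 + ln |S|) · f(S, C_opt).
``ilp_rgb``
    exact: solves minimum set cover of ∪C as a 0/1 integer program
    (minimize Σ x_i subject to Σ_{i : g ∈ c_i} x_i ≥ 1 for every g ∈ ∪C)
    and adds the constant deletion term |S \\ ∪C|, which yields the RGB
    optimum.  Backends: ``milp`` (HiGHS via :func:`scipy.optimize.milp`)
    or ``exhaustive``.
``brute_force_rgb``
    exhaustive enumeration of all sub-collections; the testing oracle.

Duplication events are outside the optimization: candidate blocks are
projected to their gene sets, and the duplication count of the selected
blocks is recomputed afterwards for reporting only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np

from .costs import (
    DELETION_SPLIT_ONLY,
    WITH_DUPLICATION,
    EventCosts,
    Mode,
)
from .model import GeneBlock, Orthoblock, ReferenceOperon

logger = logging.getLogger("orthoblocks")

#: 2^20 subsets keep the exhaustive oracle well under a second
BRUTE_FORCE_LIMIT = 20
#: guard for the exhaustive minimum-set-cover backend
EXHAUSTIVE_COVER_LIMIT = 25

GREEDY = "greedy"
ILP = "ilp"
BRUTE_FORCE = "brute_force"


@dataclass(frozen=True)
class Candidate:
    """One candidate block: its projected gene set, stable input index, and source block."""

    index: int
    genes: frozenset[str]
    block: GeneBlock | None = None


@dataclass(frozen=True)
class RGBInstance:
    """An RGB problem instance <S, C>."""

    universe: frozenset[str]
    candidates: tuple[Candidate, ...]

    def __post_init__(self):
        seen: set[int] = set()
        for c in self.candidates:
            if not c.genes:
                raise ValueError(f"candidate {c.index} is empty; candidates must be non-empty")
            if not c.genes <= self.universe:
                extra = sorted(c.genes - self.universe)
                raise ValueError(
                    f"candidate {c.index} contains genes outside the reference gene set: "
                    f"{', '.join(extra)}"
                )
            if c.index in seen:
                raise ValueError(f"duplicate candidate index {c.index}")
            seen.add(c.index)

    @classmethod
    def from_sets(cls, universe: Iterable[str], sets: Iterable[Iterable[str]]) -> "RGBInstance":
        return cls(
            universe=frozenset(universe),
            candidates=tuple(
                Candidate(index=i, genes=frozenset(s)) for i, s in enumerate(sets)
            ),
        )

    @classmethod
    def from_orthoblock(cls, reference: ReferenceOperon, candidates: Orthoblock) -> "RGBInstance":
        """Project candidate blocks to gene sets (duplications drop out here)."""
        return cls(
            universe=reference.gene_set(),
            candidates=tuple(
                Candidate(index=i, genes=b.gene_set(), block=b)
                for i, b in enumerate(candidates.blocks)
            ),
        )

    @property
    def coverable(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.candidates:
            out |= c.genes
        return frozenset(out)

    def objective(self, selected: Iterable[int]) -> int:
        """f(S, C') = |S| − |∪C'| + |C'| for the given candidate indices."""
        idx = list(selected)
        by_index = {c.index: c for c in self.candidates}
        union: set[str] = set()
        for i in idx:
            union |= by_index[i].genes
        return len(self.universe) - len(union) + len(idx)


@dataclass(frozen=True)
class RGBSolution:
    """A selected sub-collection C' with its objective and decomposed event costs.

    ``objective_f`` is f(S, C'); ``costs`` carries the biological counts
    (deletion = |S| − |∪C'|, split = max(|C'| − 1, 0), duplication of the
    selected source blocks, reported but never optimized).  For non-empty
    selections objective_f = deletion + split + 1.
    """

    instance: RGBInstance
    selected: tuple[int, ...]
    objective_f: int
    uncoverable: int
    costs: EventCosts
    solver: str

    @property
    def selected_candidates(self) -> tuple[Candidate, ...]:
        by_index = {c.index: c for c in self.instance.candidates}
        return tuple(by_index[i] for i in self.selected)

    @property
    def selected_blocks(self) -> list[GeneBlock]:
        return [c.block for c in self.selected_candidates if c.block is not None]

    def to_orthoblock(self, genome_id: str = "solution") -> Orthoblock:
        return Orthoblock(genome_id=genome_id, blocks=self.selected_blocks)


def _selection_costs(instance: RGBInstance, selected: Sequence[int], mode: Mode) -> EventCosts:
    by_index = {c.index: c for c in instance.candidates}
    union: set[str] = set()
    dup: set[str] = set()
    for i in selected:
        c = by_index[i]
        union |= c.genes
        if c.block is not None:
            dup |= c.block.dup_set()
    return EventCosts(
        deletion=len(instance.universe) - len(union),
        split=max(len(selected) - 1, 0),
        duplication=len(dup),
        mode=mode,
    )


def _finish(
    instance: RGBInstance, selected: Sequence[int], solver: str, mode: Mode
) -> RGBSolution:
    selected = tuple(sorted(selected))
    costs = _selection_costs(instance, selected, mode)
    sol = RGBSolution(
        instance=instance,
        selected=selected,
        objective_f=instance.objective(selected),
        uncoverable=len(instance.universe - instance.coverable),
        costs=costs,
        solver=solver,
    )
    if sol.selected and not sol.to_orthoblock().well_formed:
        logger.warning(
            "optimal selection consists solely of singleton blocks; the resulting "
            "orthoblock is not well-formed (no block of size >= 2)"
        )
    return sol


# ---------------------------------------------------------------------------
# greedy

def greedy_rgb(instance: RGBInstance, mode: Mode = DELETION_SPLIT_ONLY) -> RGBSolution:
    """Greedy (1 + ln n)-approximation.

    Repeatedly selects the candidate covering the most still-uncovered
    genes of ∪C until everything coverable is covered.  Ties go to the
    lowest input index, making the selection deterministic.
    """
    if not instance.candidates:
        logger.warning("greedy solver called with an empty candidate collection")
        return _finish(instance, (), GREEDY, mode)
    remaining = set(instance.coverable)
    available = list(instance.candidates)
    chosen: list[int] = []
    while remaining:
        best = max(available, key=lambda c: (len(c.genes & remaining), -c.index))
        gain = len(best.genes & remaining)
        assert gain > 0, "uncovered genes remain but no candidate covers them"
        chosen.append(best.index)
        remaining -= best.genes
        available.remove(best)
    return _finish(instance, chosen, GREEDY, mode)


def greedy_bound(n_genes: int) -> float:
    """The proven approximation factor 1 + ln n for a reference of n genes."""
    return 1.0 + math.log(n_genes)


# ---------------------------------------------------------------------------
# brute force (oracle)

def brute_force_rgb(
    instance: RGBInstance,
    mode: Mode = DELETION_SPLIT_ONLY,
    max_candidates: int = BRUTE_FORCE_LIMIT,
) -> RGBSolution:
    """Enumerate all 2^|C| sub-collections and return one minimizing f.

    Ties are broken toward a non-empty selection, then by fewer sets, then
    by lexicographic index order.  Refuses instances with more than
    ``max_candidates`` candidates.
    """
    m = len(instance.candidates)
    if m > max_candidates:
        raise ValueError(
            f"brute force enumeration refused: {m} candidates exceeds the "
            f"limit of {max_candidates}"
        )
    best_key: tuple | None = None
    best: tuple[int, ...] = ()
    for size in range(m + 1):
        for combo in itertools.combinations(instance.candidates, size):
            union: set[str] = set()
            for c in combo:
                union |= c.genes
            f = len(instance.universe) - len(union) + size
            idx = tuple(c.index for c in combo)
            key = (f, size == 0, size, idx)
            if best_key is None or key < best_key:
                best_key = key
                best = idx
    return _finish(instance, best, BRUTE_FORCE, mode)


# ---------------------------------------------------------------------------
# exact: minimum set cover of ∪C + constant deletion term

def _min_cover_milp(instance: RGBInstance) -> tuple[int, ...]:
    from scipy.optimize import Bounds, LinearConstraint, milp

    elements = sorted(instance.coverable)
    m = len(instance.candidates)
    a = np.zeros((len(elements), m))
    for j, c in enumerate(instance.candidates):
        for i, g in enumerate(elements):
            if g in c.genes:
                a[i, j] = 1.0
    res = milp(
        c=np.ones(m),
        constraints=LinearConstraint(a, lb=np.ones(len(elements)), ub=np.inf),
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"integer-program backend failed: {res.message}")
    return tuple(
        instance.candidates[j].index for j in range(m) if res.x[j] > 0.5
    )


def _min_cover_exhaustive(instance: RGBInstance) -> tuple[int, ...]:
    m = len(instance.candidates)
    if m > EXHAUSTIVE_COVER_LIMIT:
        raise ValueError(
            f"exhaustive cover enumeration refused: {m} candidates exceeds the "
            f"limit of {EXHAUSTIVE_COVER_LIMIT}"
        )
    target = instance.coverable
    for size in range(m + 1):
        for combo in itertools.combinations(instance.candidates, size):
            union: set[str] = set()
            for c in combo:
                union |= c.genes
            if union == target:
                return tuple(c.index for c in combo)
    raise AssertionError("C always covers ∪C; unreachable")


def ilp_rgb(
    instance: RGBInstance,
    backend: str = "auto",
    mode: Mode = DELETION_SPLIT_ONLY,
) -> RGBSolution:
    """Exact RGB solver.

    Finds a minimum-cardinality cover C* of ∪C; the RGB objective is then
    |S \\ ∪C| + |C*|, which equals the true RGB optimum (the deletion term
    for genes no candidate carries is a constant).  ``backend`` is ``milp``
    (0/1 integer program solved by HiGHS), ``exhaustive``, or ``auto``
    (milp, falling back to exhaustive if the toolkit is unavailable).
    """
    if not instance.candidates:
        logger.warning("exact solver called with an empty candidate collection")
        return _finish(instance, (), ILP, mode)
    if backend == "auto":
        try:
            selected = _min_cover_milp(instance)
        except ImportError:  # pragma: no cover - scipy is a hard dependency
            selected = _min_cover_exhaustive(instance)
    elif backend == "milp":
        selected = _min_cover_milp(instance)
    elif backend == "exhaustive":
        selected = _min_cover_exhaustive(instance)
    else:
        raise ValueError(f"unknown backend {backend!r}: expected milp, exhaustive or auto")
    return _finish(instance, selected, ILP, mode)


# ---------------------------------------------------------------------------
# MSC reconstruction and oracle

def msc_from_rgb(
    candidates: Sequence[frozenset[str] | set[str]],
    selected: Iterable[int],
) -> list[int]:
    """Rebuild a set-cover solution of ∪C from an RGB solution C'.

    Starting from C1 = C', every remaining candidate contributing exactly
    one uncovered element is added (each such addition leaves f unchanged).
    When C' is RGB-optimal, the result is a minimum set cover of ∪C of
    equal cost.  Returns candidate indices in input order.
    """
    chosen = sorted(set(selected))
    covered: set[str] = set()
    for i in chosen:
        covered |= set(candidates[i])
    out = list(chosen)
    for i, c in enumerate(candidates):
        if i in set(chosen):
            continue
        if len(set(c) - covered) == 1:
            out.append(i)
            covered |= set(c)
    return sorted(out)


def brute_force_msc(
    universe: Iterable[str], candidates: Sequence[frozenset[str] | set[str]]
) -> list[int]:
    """Minimum set cover by increasing-size enumeration (testing oracle).

    Raises ValueError if the candidates cannot cover the universe.
    """
    target = set(universe)
    pool: set[str] = set()
    for c in candidates:
        pool |= set(c)
    if not target <= pool:
        missing = sorted(target - pool)
        raise ValueError(f"universe not coverable; missing elements: {', '.join(missing)}")
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(range(len(candidates)), size):
            union: set[str] = set()
            for i in combo:
                union |= set(candidates[i])
            if target <= union:
                return list(combo)
    raise AssertionError("unreachable: full collection covers the universe")


# ---------------------------------------------------------------------------
# genome-level front door

METHODS = {
    GREEDY: greedy_rgb,
    ILP: ilp_rgb,
    "exact": ilp_rgb,
    BRUTE_FORCE: brute_force_rgb,
}


def solve_genome(
    reference: ReferenceOperon,
    candidates: Orthoblock,
    method: str = GREEDY,
    mode: Mode = WITH_DUPLICATION,
) -> RGBSolution:
    """Select the orthoblock of one genome minimizing deletion + split events.

    Candidate blocks are projected to gene sets, the chosen solver runs on
    the projected instance, and the selected gene sets are mapped back to
    their source blocks; the duplication count of the selection is computed
    and reported alongside (it does not enter the optimization).
    """
    try:
        solver = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}: expected one of {', '.join(sorted(METHODS))}"
        ) from None
    instance = RGBInstance.from_orthoblock(reference, candidates)
    return solver(instance, mode=mode)
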