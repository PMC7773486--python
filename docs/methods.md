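# Methods

## The event-based model

The package models orthoblock evolution as counts of three discrete event
types relative to a reference operon: deletions (gene loss), splits (a
block breaking into pieces) and duplications (a gene gaining a tandem
copy). A gene block is strictly a multiset over the reference gene set
`G`: chromosomal gene order is retained only for display and round-tripping
input files, because every cost is a function of set/multiset operators
(`Gene`, `Dup`, `Rel`, `Dif`) and is therefore order-invariant. Genes with
no ortholog in the reference operon cannot appear in a block; mapping
candidate genes onto `G` is upstream of this package (any
ortholog-detection pipeline), and inputs carrying unmapped genes are
rejected at parse time unless the caller opts into filtering them.

Two readings of the model were genuinely open and are fixed here:

* `Rel(O, O')` is treated as a *collection* of blocks, not a deduplicated
  set: two distinct blocks whose restrictions coincide still count as two
  toward the split cost, since that cost counts block instances. No worked
  example distinguishes the two readings; this one keeps
  `c_s(R, O) = |O| − 1` exact for every orthoblock over `Gene(R)`.
* An orthoblock is *well-formed* when it is empty or contains at least one
  block of size ≥ 2. This is validated and reported (a logged warning),
  never enforced: solvers may legitimately return singleton-only
  selections, and none of the optimization problems encode the constraint.
* Multiplicities above 2 are accepted with a warning; a gene counts at most
  once toward `Dup` regardless of copy number.

Degenerate input convention: for an empty orthoblock the general formulas
give `c_s = 0` (both `Rel` collections are empty) and `c_d = |Gene(R)|`;
the closed form `|O| − 1` is defined as 0 at `|O| = 0` so the two routes
agree everywhere. The general pairwise forms are canonical; the closed
forms are algebraic simplifications valid when `Gene(O) ⊆ Gene(R)` and the
reference carries no duplicates, and the suite checks the equality on
randomized inputs rather than trusting the derivation.

All events are weighted equally and costs are integers throughout; no
rate-based or branch-length-aware weighting is attempted.

## Solvers

Selecting candidates minimizes `f(S, C') = |S| − |∪C'| + |C'|` (the
deletion + split cost plus the constant 1 for non-empty selections; both
numbers appear on every solution). The problem is equivalent in cost to
Minimum Set Cover, hence NP-hard and APX-hard, which fixes the design:

* **Greedy**: repeatedly take the candidate covering the most
  still-uncovered genes of `∪C`; guaranteed within `1 + ln |S|` of the
  optimum. Ties go to the lowest input index, so the output is a
  deterministic function of the instance.
* **Exact**: the optimum decomposes as `|S ∖ ∪C|` (genes no candidate
  carries — a constant) plus a minimum set cover of `∪C`. The cover is
  solved as the standard 0/1 program (minimize `Σ x_i` subject to
  `Σ_{i: g ∈ c_i} x_i ≥ 1` for all `g ∈ ∪C`) with the HiGHS branch-and-cut
  backend shipped in `scipy.optimize.milp`; an exhaustive backend (at most
  25 candidates) gives a toolkit-independent cross-check and both must
  agree with the brute-force oracle.
* **Brute force**: enumerates all `2^|C|` sub-collections, refusing beyond
  20 candidates (~10⁶ subsets, well under a second). Ties are broken
  toward a non-empty selection, then fewer sets, then lexicographic index
  order. It exists as the testing oracle and is never the default.

Duplication events cannot be optimized in this framework — the selection
step sees only projected gene sets — so the duplication count of the chosen
blocks is recomputed afterwards and reported alongside. Candidates with
identical gene sets are kept distinct (stable indices); no optimal
selection contains both, since the second copy adds 1 to `f` and covers
nothing.

The set-cover reconstruction procedure (start from an RGB selection, add
every remaining candidate contributing exactly one uncovered element) is
implemented with the guard read as a set-difference *cardinality* test,
the only reading under which each addition leaves `f` unchanged and an
optimal selection grows into a minimum cover of `∪C`.

## Simulator

The generator applies a configured number of events to the reference in a
fixed order — deletions of distinct genes, tandem duplications (λ: 1 → 2)
of distinct surviving genes, then splits at distinct boundaries between
neighbouring *distinct* genes — and returns the orthoblock with its ground
truth. The ordering and distinctness rules are the minimal conditions
under which the cost functions count the planted events exactly (two
deletions of one gene, or a second cut at the same boundary, would be
invisible to the multiset model); the suite asserts exact recovery across
100 random configurations. Splits never separate a tandem pair, keeping
each duplication inside one block. Solver test beds add decoy candidates:
random non-empty subsets of `G` with geometrically distributed sizes
(p = 0.5, capped at `|G|`), emulating the spurious partial hits an
ortholog-mapping step produces. One seeded `random.Random` stream drives
each simulation, so a seed determines the output byte-for-byte.

What the simulator does *not* emulate: evolution along a phylogeny (events
are applied star-like from the reference), gene gain from outside the
operon, fusion with foreign blocks, and ortholog-mapping errors other than
random decoys. Passing tests therefore establish the combinatorial
correctness of costs and solvers under the model's own assumptions, not
the fidelity of any upstream annotation pipeline on real genomes.

## Problem sizes and defaults

Default study conditions mirror realistic operon scales: references of
5–13 genes (the range covering most experimentally verified *E. coli*
operons used as gold standards), candidate pools of up to ~10 blocks per
genome, and a handful of decoys. Randomized checks use 200 instances
(|S| ≤ 12, |C| ≤ 10) for solver equivalence and the approximation bound,
100 for set-cover equivalence and simulator recovery, and 500 for the
closed-form identities — sizes at which the exhaustive oracle is exact and
the whole suite runs in seconds. The CLI `benchmark` subcommand reports
wall-clock times informationally only; they are hardware-dependent and
nothing asserts on them.

## Known limitations

* Duplications are reported, never optimized; handling them inside the
  selection step would need a different objective.
* The model abstracts away strand, intergenic distance and gene order
  within blocks; two blocks with the same gene content are
  indistinguishable.
* Input blocks must already be expressed over the reference gene set;
  there is no GenBank/GFF ingestion or operon prediction.
* The empirical comparison against heuristic block-building pipelines on
  curated bacterial datasets is out of scope; validation here is by
  oracle equivalence and simulation.
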