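"""Tests for the greedy, integer-program and brute-force RGB solvers.

The brute-force enumerator is the oracle: the exact solver must match it
everywhere, the greedy solver must stay within the 1 + ln n factor, and
set-cover reconstruction from an optimal selection must yield a minimum
cover of the coverable genes.
"""

import math
import random

import pytest

import orthoblocks as ob

from conftest import block, ortho, random_instance


def inst(universe, *sets):
    return ob.RGBInstance.from_sets(universe, [frozenset(s) for s in sets])


class TestInstance:
    def test_empty_candidate_rejected(self):
        with pytest.raises(ValueError, match="must be non-empty"):
            inst("abc", "ab", "")

    def test_foreign_gene_rejected(self):
        with pytest.raises(ValueError, match="outside the reference gene set: z"):
            inst("abc", "az")

    def test_objective_definition(self):
        i = inst("abcde", "ab", "bc")
        assert i.objective([]) == 5
        assert i.objective([0]) == 5 - 2 + 1
        assert i.objective([0, 1]) == 5 - 3 + 2

    def test_from_orthoblock_projects_duplications_away(self, ref5):
        i = ob.RGBInstance.from_orthoblock(ref5, ortho("abb", "cd"))
        assert i.candidates[0].genes == {"a", "b"}
        assert i.candidates[0].block == block("abb")


class TestGreedy:
    def test_split_example_selects_both_blocks(self, ref7):
        i = ob.RGBInstance.from_orthoblock(ref7, ortho("ab", "def"))
        sol = ob.greedy_rgb(i)
        assert sol.selected == (0, 1)
        assert sol.costs.deletion == 2 and sol.costs.split == 1
        assert sol.objective_f == 4

    def test_single_covering_set(self):
        sol = ob.greedy_rgb(inst("abc", "abc"))
        assert sol.selected == (0,)
        assert sol.objective_f == 1

    def test_prefers_large_sets_over_fragments(self):
        i = inst("abcdef", "abcd", "ab", "cd", "ef", "e", "f")
        sol = ob.greedy_rgb(i)
        assert sol.selected == (0, 3)
        assert sol.objective_f == 2

    def test_tie_broken_by_lowest_index(self):
        i = inst("abcd", "ab", "cd", "ba")
        sol = ob.greedy_rgb(i)
        assert sol.selected == (0, 1)

    def test_empty_collection_degenerate(self):
        sol = ob.greedy_rgb(inst("abcd"))
        assert sol.selected == ()
        assert sol.objective_f == 4
        assert sol.uncoverable == 4

    def test_every_selection_covers_the_coverable(self):
        rng = random.Random(7)
        for _ in range(50):
            i = random_instance(rng)
            sol = ob.greedy_rgb(i)
            covered = frozenset().union(*(c.genes for c in sol.selected_candidates)) \
                if sol.selected else frozenset()
            assert covered == i.coverable


class TestBruteForce:
    def test_duplicate_sets_never_both_selected(self):
        # selecting a second copy of {a,b} adds 1 to f without covering anything
        i = inst("abcde", "ab", "ab", "c")
        sol = ob.brute_force_rgb(i)
        assert sol.objective_f == 4  # f(∅) = 5 is worse
        assert not {0, 1} <= set(sol.selected)

    def test_empty_collection(self):
        sol = ob.brute_force_rgb(inst("abcde"))
        assert sol.selected == ()
        assert sol.objective_f == 5

    def test_objective_equals_deletion_plus_split_plus_one(self, ref7):
        i = ob.RGBInstance.from_orthoblock(ref7, ortho("ab", "def"))
        sol = ob.brute_force_rgb(i)
        assert sol.objective_f == 4
        assert sol.objective_f == sol.costs.deletion + sol.costs.split + 1

    def test_non_empty_preferred_on_objective_tie(self):
        # f(∅) = 1 = f({a}) on a one-gene universe; ties go to the non-empty cover
        sol = ob.brute_force_rgb(inst("a", "a"))
        assert sol.selected == (0,)

    def test_size_guard(self):
        sets = [{f"g{i}"} for i in range(21)]
        i = ob.RGBInstance.from_sets({f"g{i}" for i in range(21)}, sets)
        with pytest.raises(ValueError, match="exceeds the limit"):
            ob.brute_force_rgb(i)


class TestExactSolver:
    def test_split_example(self, ref7):
        i = ob.RGBInstance.from_orthoblock(ref7, ortho("ab", "def"))
        sol = ob.ilp_rgb(i)
        assert len(sol.selected) == 2
        assert sol.objective_f == 4  # uncovered {c,g} + cover of size 2

    def test_single_covering_set(self):
        sol = ob.ilp_rgb(inst("abc", "abc"))
        assert sol.selected == (0,)
        assert sol.objective_f == 1

    @pytest.mark.parametrize("backend", ["milp", "exhaustive"])
    def test_backends_agree_with_oracle(self, backend):
        rng = random.Random(11)
        for _ in range(30):
            i = random_instance(rng, max_genes=10, max_candidates=8)
            assert ob.ilp_rgb(i, backend=backend).objective_f == \
                ob.brute_force_rgb(i).objective_f

    def test_unknown_backend(self):
        with pytest.raises(ValueError, match="unknown backend"):
            ob.ilp_rgb(inst("ab", "ab"), backend="quantum")


class TestMSCReconstruction:
    def test_adds_sets_contributing_exactly_one(self):
        c = [frozenset("ab"), frozenset("c")]
        assert ob.msc_from_rgb(c, [0]) == [0, 1]

    def test_covering_selection_unchanged(self):
        c = [frozenset("ab"), frozenset("a")]
        assert ob.msc_from_rgb(c, [0]) == [0]

    def test_sets_contributing_two_not_added(self):
        c = [frozenset("ab"), frozenset("cd")]
        assert ob.msc_from_rgb(c, [0]) == [0]

    def test_reconstruction_from_rgb_optimum_is_minimum_cover(self):
        rng = random.Random(13)
        for _ in range(40):
            i = random_instance(rng, max_genes=10, max_candidates=8)
            sets = [c.genes for c in i.candidates]
            opt = ob.brute_force_rgb(i)
            c1 = ob.msc_from_rgb(sets, opt.selected)
            covered = frozenset().union(*(sets[j] for j in c1)) if c1 else frozenset()
            assert covered == i.coverable
            assert len(c1) == len(ob.brute_force_msc(i.coverable, sets))

    def test_msc_oracle_uncoverable(self):
        with pytest.raises(ValueError, match="missing elements: b"):
            ob.brute_force_msc("ab", [frozenset("a")])


class TestSolveGenome:
    def test_split_example_end_to_end(self, ref7):
        sol = ob.solve_genome(ref7, ortho("ab", "def"), method="exact")
        assert [b.display_order for b in sol.selected_blocks] == [("a", "b"), ("d", "e", "f")]
        c = sol.costs
        assert (c.deletion, c.split, c.duplication) == (2, 1, 0)

    def test_empty_candidates_convention(self, ref7):
        sol = ob.solve_genome(ref7, ob.Orthoblock(genome_id="t"))
        assert sol.costs.deletion == 7 and sol.costs.split == 0

    def test_duplication_reported_not_optimized(self, ref5):
        sol = ob.solve_genome(ref5, ortho("abb"), method="greedy")
        c = sol.costs
        assert (c.deletion, c.split, c.duplication) == (3, 0, 1)
        assert c.total == 4

    def test_unknown_method(self, ref5):
        with pytest.raises(ValueError, match="unknown method"):
            ob.solve_genome(ref5, ortho("ab"), method="magic")

    def test_singleton_only_selection_warns(self, ref5, caplog):
        with caplog.at_level("WARNING", logger="orthoblocks"):
            ob.solve_genome(ref5, ortho("a", "b"), method="greedy")
        assert "not well-formed" in caplog.text


# -- cross-solver properties ------------------------------------------------

class TestSolverProperties:
    def test_optimum_decomposes_into_uncoverable_plus_min_cover(self):
        """f(S, C_opt) = |S \\ ∪C| + (minimum cover size of ∪C) on every instance."""
        rng = random.Random(17)
        for _ in range(60):
            i = random_instance(rng, max_genes=10, max_candidates=8)
            opt = ob.brute_force_rgb(i)
            sets = [c.genes for c in i.candidates]
            cover = ob.brute_force_msc(i.coverable, sets) if i.coverable else []
            assert opt.objective_f == len(i.universe - i.coverable) + len(cover)

    def test_determinism(self):
        rng = random.Random(19)
        for _ in range(10):
            i = random_instance(rng)
            for solver in (ob.greedy_rgb, ob.ilp_rgb, ob.brute_force_rgb):
                assert solver(i).selected == solver(i).selected

    def test_adding_a_candidate_never_hurts(self):
        rng = random.Random(23)
        for _ in range(40):
            i = random_instance(rng, max_genes=10, max_candidates=7)
            before = ob.brute_force_rgb(i).objective_f
            extra_genes = rng.sample(sorted(i.universe), rng.randint(1, len(i.universe)))
            grown = ob.RGBInstance.from_sets(
                i.universe, [c.genes for c in i.candidates] + [frozenset(extra_genes)]
            )
            assert ob.brute_force_rgb(grown).objective_f <= before

    def test_greedy_ratio_bounded(self):
        rng = random.Random(29)
        worst = 1.0
        for _ in range(60):
            i = random_instance(rng)
            g = ob.greedy_rgb(i).objective_f
            opt = ob.brute_force_rgb(i).objective_f
            worst = max(worst, g / opt)
            assert g <= ob.greedy_bound(len(i.universe)) * opt
        assert worst >= 1.0
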