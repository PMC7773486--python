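"""Score the three event types between a reference operon and target orthoblocks.

Builds the textbook seven- and five-gene cases and prints each cost via the
general pairwise formula and via its reference-simplified closed form.
"""

import orthoblocks as ob

# a genome where the operon survived as two separate blocks, missing c and g
ref7 = ob.ReferenceOperon("ref7", tuple("abcdefg"))
split_case = ob.Orthoblock(genome_id="A", blocks=[ob.GeneBlock("ab"), ob.GeneBlock("def")])
print("split cost   :", ob.split_cost(ref7, split_case),
      "(closed form:", ob.split_cost_ref(ref7, split_case), ")")

# a genome carrying tandem duplicates of b and c
ref5 = ob.ReferenceOperon("ref5", tuple("abcde"))
dup_case = ob.Orthoblock(genome_id="B", blocks=[ob.GeneBlock("abbcc")])
print("duplication  :", ob.duplication_cost(ref5, dup_case),
      "(closed form:", ob.duplication_cost_ref(ref5, dup_case), ")")

# a genome that lost c and e
del_case = ob.Orthoblock(genome_id="C", blocks=[ob.GeneBlock("abd")])
print("deletion     :", ob.deletion_cost(ref5, del_case),
      "(closed form:", ob.deletion_cost_ref(ref5, del_case), ")")

# combined: the split case lost 2 genes and broke once -> total 3 events
costs = ob.total_cost(ref7, split_case)
print("combined     :", costs, "-> total", costs.total, "events")
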