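"""Select the minimum-cost orthoblock from a pool of candidate blocks.

The candidate pool mixes the two genuine fragments of the operon with
smaller overlapping fragments; the solver must pick the sub-collection
minimizing deletion + split events against the reference.  Greedy and the
exact integer program are compared.
"""

import orthoblocks as ob

reference = ob.ReferenceOperon("atp_like", tuple("abcdefg"))
candidates = ob.Orthoblock(
    genome_id="target",
    blocks=[
        ob.GeneBlock("ab"),      # genuine fragment
        ob.GeneBlock("def"),     # genuine fragment
        ob.GeneBlock("a"),       # redundant singleton
        ob.GeneBlock("de"),      # redundant sub-fragment
    ],
)

for method in ("greedy", "exact"):
    sol = ob.solve_genome(reference, candidates, method=method)
    chosen = " | ".join(ob.format_block(b) for b in sol.selected_blocks)
    print(f"{method:>6}: selected [{chosen}]  "
          f"deletion={sol.costs.deletion} split={sol.costs.split} "
          f"duplication={sol.costs.duplication}  f={sol.objective_f}")

# both methods keep only the two genuine fragments: 2 genes (c, g) are
# missing (deletions) and the operon is in 2 pieces (1 split); f = 2 + 1 + 1
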